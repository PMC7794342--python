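"""Event-driven Monte Carlo: transmission rates, stationarity, observables."""

import numpy as np
import pytest
from scipy import stats

from burstnet import distributions as D
from burstnet import edge_state as ES
from burstnet import netgen as NG
from burstnet import simulate as S


# ---------------------------------------------------------------------------
# model objects and transmission rates
# ---------------------------------------------------------------------------

def test_dynamics_model_validation():
    with pytest.raises(ValueError):
        S.DynamicsModel("RT", 2e-4)  # missing phi
    with pytest.raises(ValueError):
        S.DynamicsModel("RT", 2e-4, phi=0.1, lam=0.5)  # extraneous parameter
    with pytest.raises(ValueError):
        S.DynamicsModel.relative_threshold(0.1, 0.0)  # p must be positive
    with pytest.raises(ValueError):
        S.MemoryKernel("boxcar", 1.0)


@pytest.mark.parametrize(
    "model,m,k,expect",
    [
        (S.DynamicsModel.relative_threshold(0.3, 2e-4), 3, 12, 2e-4),  # 3 < 3.6
        (S.DynamicsModel.relative_threshold(0.3, 2e-4), 4, 12, 1.0),
        (S.DynamicsModel.relative_threshold(0.3, 2e-4), 0, 0, 2e-4),  # isolated
        (S.DynamicsModel.relative_threshold(0.15, 2e-4), 3, 20, 1.0),  # exact hit
        (S.DynamicsModel.absolute_threshold(3, 2e-4), 3, 9, 1.0),
        (S.DynamicsModel.absolute_threshold(3, 2e-4), 2, 9, 2e-4),
        (S.DynamicsModel.si(0.02, 2e-4), 3, 10, 0.06),
        (S.DynamicsModel.si(0.02, 2e-4), 0, 10, 2e-4),
    ],
)
def test_transmission_rate_table(model, m, k, expect):
    assert S.transmission_rate(model, m, k) == pytest.approx(expect)


def test_transmission_rate_monotone_in_influence():
    """For AT and SI, more infected influence never lowers F."""
    m = np.arange(0, 12)
    for model in (S.DynamicsModel.absolute_threshold(4, 1e-3), S.DynamicsModel.si(0.05, 1e-3)):
        f = S.transmission_rate(model, m, np.full_like(m, 12))
        assert np.all(np.diff(f) >= 0)


def test_transmission_rate_rt_extremes():
    """phi -> 0+ fires on any infected influence; phi = 1 needs all of it."""
    lo = S.DynamicsModel.relative_threshold(1e-9, 2e-4)
    hi = S.DynamicsModel.relative_threshold(1.0, 2e-4)
    assert S.transmission_rate(lo, 1, 10) == 1.0
    assert S.transmission_rate(hi, 9, 10) == 2e-4
    assert S.transmission_rate(hi, 10, 10) == 1.0


def test_transmission_rate_rejects_invalid():
    model = S.DynamicsModel.si(0.02, 2e-4)
    with pytest.raises(ValueError):
        S.transmission_rate(model, -1, 3)
    with pytest.raises(ValueError):
        S.transmission_rate(model, 5, 3)


# ---------------------------------------------------------------------------
# edge states and stationary initialization
# ---------------------------------------------------------------------------

def test_edge_state_at_window_count():
    ker = S.MemoryKernel("step", 2.5)
    assert S.edge_state_at([0.0, 1.0, 3.0], 3.0, ker) == 2  # events at 1 and 3
    assert S.edge_state_at([], 3.0, ker) == 0
    assert S.edge_state_at([5.0], 3.0, ker) == 0  # future events don't count


def test_edge_state_time_average_matches_mean_state(weibull_sd2):
    """Ergodic check on one long edge: the time-averaged state is eta/<tau>."""
    rng = np.random.default_rng(42)
    t_end = 4000.0
    events = np.cumsum(weibull_sd2.sample(12_000, seed=rng))
    events = events[events < t_end]
    ker = S.MemoryKernel("step", 1.5)
    obs = np.linspace(100.0, t_end, 2000)
    idx_hi = np.searchsorted(events, obs, side="right")
    idx_lo = np.searchsorted(events, obs - ker.eta, side="right")
    j_bar = float(np.mean(idx_hi - idx_lo))
    # the state process decorrelates on the eta time scale: ~t_end/eta
    # effective samples with per-sample sd ~ sqrt variance of Poisson proxy
    se = 3.0 / np.sqrt(t_end / ker.eta)
    assert abs(j_bar - 1.5) <= 3 * se


def test_stationary_states_poisson_chi_square(exp_dist):
    states = S.stationary_states(100_000, exp_dist, S.MemoryKernel("step", 1.0), seed=3)
    obs = np.bincount(states, minlength=9)[:9]
    expect = stats.poisson(1.0).pmf(np.arange(9)) * len(states)
    keep = expect > 5
    res = stats.chisquare(obs[keep], expect[keep] * obs[keep].sum() / expect[keep].sum())
    assert res.pvalue > 0.01


def test_stationary_states_match_spectrum(weibull_sd2):
    """General psi: the state histogram matches E_j within 3 SE per bin."""
    n_edges = 60_000
    sp = ES.spectrum(weibull_sd2, 1.0, 10)
    states = S.stationary_states(n_edges, weibull_sd2, S.MemoryKernel("step", 1.0), seed=5)
    freq = np.bincount(states, minlength=10)[:10] / n_edges
    se = np.sqrt(sp.E * (1 - sp.E) / n_edges)
    assert np.all(np.abs(freq - sp.E) <= 3 * se + 5e-4)


def test_stationary_states_vanishing_memory(exp_dist):
    states = S.stationary_states(5_000, exp_dist, S.MemoryKernel("step", 1e-9), seed=7)
    assert states.max() == 0


def test_init_stationary_first_event_times(small_net, weibull_sd2):
    ker = S.MemoryKernel("step", 1.0)
    t0 = S.init_stationary(small_net, weibull_sd2, ker, seed=9)
    assert len(t0) == small_net.n_edges
    assert np.all(t0 >= -ker.eta)


def test_exponential_kernel_state_mean(exp_dist):
    """Exponential kernel with Poisson edges: remembered events are thinned
    Poisson with mean eta/<tau>."""
    states = S.stationary_states(
        40_000, exp_dist, S.MemoryKernel("exponential", 2.0), seed=11
    )
    se = np.sqrt(2.0 / 40_000)
    assert abs(states.mean() - 2.0) <= 3 * se


# ---------------------------------------------------------------------------
# cascades
# ---------------------------------------------------------------------------

def test_noise_only_arithmetic():
    assert S.noise_only_time(0.4, 2e-4) == pytest.approx(-np.log(0.6) / 2e-4)


def test_run_cascade_deterministic(small_net, exp_dist):
    model = S.DynamicsModel.relative_threshold(0.15, 2e-3)
    ker = S.MemoryKernel("step", 1.0)
    t1 = S.run_cascade(small_net, exp_dist, ker, model, rho_c=0.1, seed=13)
    t2 = S.run_cascade(small_net, exp_dist, ker, model, rho_c=0.1, seed=13)
    np.testing.assert_array_equal(t1.times, t2.times)
    np.testing.assert_array_equal(t1.noise_flags, t2.noise_flags)


def test_run_cascade_reaches_high_density(small_net, exp_dist):
    """With p > 0 and no recovery, any density is eventually reached."""
    model = S.DynamicsModel.relative_threshold(0.15, 2e-3)
    traj = S.run_cascade(
        small_net, exp_dist, S.MemoryKernel("step", 1.0), model,
        rho_c=0.9, horizon=1e5, seed=17,
    )
    assert traj.reached
    assert np.all(np.diff(traj.rho) > 0)
    assert np.all(traj.rho_tilde <= traj.rho + 1e-12)


def test_annealed_limit_noise_only():
    """eta -> 0: the network plays no role and rho(t) = 1 - e^{-pt}."""
    p = 2e-3
    dm = NG.DegreeModel.lognormal(7.0, 2.0)
    model = S.DynamicsModel.relative_threshold(0.15, p)
    ker = S.MemoryKernel("step", 1e-6)
    d = D.exponential(1.0)
    grid = np.linspace(0.0, S.noise_only_time(0.4, p), 60)
    curves, rf, tf = [], [], []
    for cs in np.random.SeedSequence(23).spawn(6):
        k1, k2, k3 = cs.spawn(3)
        net = NG.wire(NG.sample_degrees(dm, 2000, seed=k1), seed=k2)
        traj = S.run_cascade(net, d, ker, model, rho_c=0.4, seed=k3)
        curves.append(traj.rho_at(grid))
        rf.append(traj.rho_f)
        tf.append(traj.t_f)
    dev = np.abs(np.mean(curves, axis=0) - (1 - np.exp(-p * grid))).max()
    assert dev <= 0.02
    assert np.mean(rf) == pytest.approx(1.0, abs=0.05)
    assert np.mean(tf) == pytest.approx(1.0, abs=0.05)


def test_rho_f_and_t_f_nearly_proportional(small_net):
    """The two diffusion measures track each other closely."""
    model = S.DynamicsModel.relative_threshold(0.15, 2e-4)
    ker = S.MemoryKernel("step", 1.0)
    d = D.from_moments("weibull", 1.0, 8.0)
    traj = S.run_cascade(small_net, d, ker, model, rho_c=0.4, seed=29)
    assert abs(traj.rho_f - traj.t_f) < 0.05


def test_counted_noise_channel_close_to_analytic(small_net, exp_dist):
    """The per-infection channel counter tracks Eq.-style rho_tilde/rho."""
    model = S.DynamicsModel.relative_threshold(0.15, 2e-4)
    ker = S.MemoryKernel("step", 1.0)
    traj = S.run_cascade(small_net, exp_dist, ker, model, rho_c=0.4, seed=31)
    assert traj.rho_f == pytest.approx(traj.rho_f_counted, abs=0.05)


def test_observables_flagged_when_not_reached(small_net, exp_dist):
    model = S.DynamicsModel.relative_threshold(0.99, 1e-5)
    traj = S.run_cascade(
        small_net, exp_dist, S.MemoryKernel("step", 1.0), model,
        rho_c=0.4, horizon=50.0, seed=37,
    )
    assert not traj.reached
    with pytest.raises(ValueError):
        S.observables(traj)


def test_observables_match_trajectory_properties(small_net, exp_dist):
    model = S.DynamicsModel.relative_threshold(0.15, 2e-3)
    traj = S.run_cascade(
        small_net, exp_dist, S.MemoryKernel("step", 1.0), model, rho_c=0.3, seed=41
    )
    rho_f, t_f = S.observables(traj)
    assert rho_f == pytest.approx(traj.rho_f)
    assert t_f == pytest.approx(traj.t_f)


def test_edge_dynamics_independent_of_node_states(small_net, exp_dist):
    """Infections do not perturb the edge process: the time-averaged mean
    edge state stays eta/<tau> even while the cascade runs."""
    model = S.DynamicsModel.relative_threshold(0.15, 2e-3)
    ker = S.MemoryKernel("step", 1.0)
    traj = S.run_cascade(small_net, exp_dist, ker, model, rho_c=0.4, seed=43)
    # states0 snapshot is the stationary marginal at t=0
    freq = np.bincount(traj.states0, minlength=6)[:6] / small_net.n_edges
    expect = stats.poisson(1.0).pmf(np.arange(6))
    se = np.sqrt(expect * (1 - expect) / small_net.n_edges)
    assert np.all(np.abs(freq - expect) <= 4 * se + 1e-3)
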