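"""Interevent-time laws: moment construction, transforms, residuals, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from burstnet import distributions as D

TWO_PARAM = ["weibull", "gamma", "lognormal"]


# ---------------------------------------------------------------------------
# moment-based construction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("family", TWO_PARAM)
@pytest.mark.parametrize("sd", [0.5, 1.0, 15.0, 80.0, 1300.0])
def test_from_moments_reproduces_moments(family, sd):
    d = D.from_moments(family, 1.0, sd)
    frozen = d._frozen
    assert abs(frozen.mean() - 1.0) <= 1e-8
    assert abs(frozen.std() - sd) / sd <= 1e-7


def test_weibull_unit_cv_is_exponential():
    """Weibull and gamma with sd = mean = 1 reduce to the unit exponential."""
    t = np.linspace(0.0, 8.0, 33)
    for family in ("weibull", "gamma"):
        d = D.from_moments(family, 1.0, 1.0)
        np.testing.assert_allclose(d.density(t), np.exp(-t), atol=1e-10)
        np.testing.assert_allclose(d.survival(t), np.exp(-t), atol=1e-10)


def test_gamma_moment_identities():
    d = D.from_moments("gamma", 1.0, 15.0)
    assert d.native_params["shape"] == pytest.approx(1 / 225)
    assert d.native_params["scale"] == pytest.approx(225.0)


def test_lognormal_moment_identities():
    d = D.from_moments("lognormal", 1.0, 1300.0)
    assert d.native_params["sigma"] ** 2 == pytest.approx(np.log(1 + 1300.0**2))


def test_exponential_requires_unit_cv():
    with pytest.raises(D.InfeasibleMomentsError):
        D.from_moments("exponential", 1.0, 2.0)


def test_generalized_gamma_needs_three_moments():
    with pytest.raises(D.InfeasibleMomentsError):
        D.from_moments("generalized_gamma", 1.0, 2.0)


@given(
    family=st.sampled_from(TWO_PARAM),
    log_cv=st.floats(-1.5, 3.0),
)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_moment_round_trip_property(family, log_cv):
    sd = 10.0**log_cv
    d = D.from_moments(family, 1.0, sd)
    assert abs(d._frozen.mean() - 1.0) <= 1e-7
    assert abs(d._frozen.std() - sd) / sd <= 1e-6


# ---------------------------------------------------------------------------
# generalized gamma by skewness
# ---------------------------------------------------------------------------

def test_gg_exponential_special_case():
    """(mean, sd, skewness) = (1, 1, 2) is the exponential: gamma shape 1."""
    d = D.generalized_gamma_from_skewness(1.0, 1.0, 2.0)
    assert d.native_params["a"] * d.native_params["c"] == pytest.approx(1.0, abs=1e-6)
    t = np.linspace(0, 5, 21)
    np.testing.assert_allclose(d.density(t), np.exp(-t), atol=1e-6)


@pytest.mark.parametrize("sigma", [0.7, 2.0, 5.0])
def test_gg_recovers_gamma(sigma):
    """Targeting the gamma's skewness 2 sigma recovers gamma parameters."""
    d = D.generalized_gamma_from_skewness(1.0, sigma, 2.0 * sigma)
    assert d.native_params["c"] == pytest.approx(1.0, abs=1e-6)
    assert d.native_params["a"] == pytest.approx(1.0 / sigma**2, rel=1e-5)


@pytest.mark.parametrize("sigma", [0.7, 2.0, 5.0])
def test_gg_recovers_weibull(sigma):
    """Targeting the Weibull's skewness recovers Weibull (a = 1)."""
    w = D.from_moments("weibull", 1.0, sigma)
    d = D.generalized_gamma_from_skewness(1.0, sigma, w.skewness)
    assert d.native_params["a"] == pytest.approx(1.0, abs=1e-5)
    assert d.native_params["c"] == pytest.approx(w.native_params["shape"], rel=1e-5)


@pytest.mark.parametrize("sigma", [1.0, 3.0])
def test_gg_identity_on_moment_triple(sigma):
    for skew in (2.2 * sigma, 3.0 * sigma):
        d = D.generalized_gamma_from_skewness(1.0, sigma, skew)
        assert d._frozen.mean() == pytest.approx(1.0, abs=1e-6)
        assert d._frozen.std() == pytest.approx(sigma, rel=1e-6)
        assert d._frozen.stats(moments="s") == pytest.approx(skew, rel=1e-5)


def test_gg_flags_near_lognormal_target():
    cv = 2.0
    ln_skew = (cv**2 + 3) * cv
    with pytest.raises(D.InfeasibleMomentsError, match="lognormal"):
        D.generalized_gamma_from_skewness(1.0, cv, ln_skew)


def test_gg_rejects_too_small_skewness():
    with pytest.raises(D.InfeasibleMomentsError):
        D.generalized_gamma_from_skewness(1.0, 2.0, 0.1)


# ---------------------------------------------------------------------------
# pointwise laws and transforms
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "dist",
    [
        D.exponential(1.0),
        D.from_moments("weibull", 1.0, 2.0),
        D.from_moments("gamma", 1.0, 2.0),
        D.from_moments("lognormal", 1.0, 3.0),
        D.generalized_gamma_from_skewness(1.0, 2.0, 5.0),
    ],
    ids=lambda d: d.family,
)
def test_normalization_and_survival_integral(dist):
    """psi integrates to 1; the survival integrates to the mean."""
    norm, _ = integrate.quad(dist.density, 0, np.inf, limit=400)
    assert abs(norm - 1.0) <= 1e-8
    mean, _ = integrate.quad(dist.survival, 0, np.inf, limit=400)
    assert abs(mean - dist.mean) / dist.mean <= 1e-6
    assert dist.survival(0.0) == pytest.approx(1.0)
    t = np.logspace(-3, 2, 40)
    s = dist.survival(t)
    assert np.all(np.diff(s) <= 1e-15)


def test_density_domain_error():
    with pytest.raises(ValueError):
        D.exponential(1.0).density(-0.5)


def test_exponential_survival_value():
    assert D.exponential(1.0).survival(1.0) == pytest.approx(np.exp(-1), abs=1e-12)


@pytest.mark.parametrize(
    "dist",
    [
        D.from_moments("weibull", 1.0, 2.0),
        D.from_moments("gamma", 1.0, 2.0),
        D.from_moments("lognormal", 1.0, 3.0),
        D.generalized_gamma_from_skewness(1.0, 2.0, 5.0),
    ],
    ids=lambda d: d.family,
)
def test_laplace_against_quadrature(dist):
    assert dist.laplace(0.0) == pytest.approx(1.0, abs=1e-9)
    for s in (0.3, 1.7):
        ref, _ = integrate.quad(
            lambda t: np.exp(-s * t) * dist.density(t), 0, np.inf, limit=400
        )
        assert dist.laplace(s) == pytest.approx(ref, rel=1e-7, abs=1e-9)


def test_gamma_laplace_closed_form():
    d = D.from_moments("gamma", 1.0, 2.0)
    a, th = d.native_params["shape"], d.native_params["scale"]
    for s in (0.0, 0.5, 3.0):
        assert d.laplace(s) == pytest.approx((1 + th * s) ** (-a), rel=1e-12)


def test_laplace_domain_error():
    with pytest.raises(ValueError):
        D.exponential(1.0).laplace(-1.0)


# ---------------------------------------------------------------------------
# residual law
# ---------------------------------------------------------------------------

def test_exponential_residual_is_memoryless():
    d = D.exponential(1.0)
    t = np.linspace(0, 5, 21)
    np.testing.assert_allclose(d.residual_density(t), np.exp(-t), atol=1e-12)


@pytest.mark.parametrize(
    "dist",
    [
        D.from_moments("weibull", 1.0, 2.0),
        D.from_moments("gamma", 1.0, 0.5),
        D.from_moments("lognormal", 1.0, 3.0),
    ],
    ids=lambda d: d.family,
)
def test_residual_normalization_and_mean(dist):
    """Residual density integrates to 1 with mean <tau>(1 + cv^2)/2."""
    norm, _ = integrate.quad(dist.residual_density, 0, np.inf, limit=400)
    assert norm == pytest.approx(1.0, abs=1e-7)
    mean, _ = integrate.quad(
        lambda t: t * dist.residual_density(t), 0, np.inf, limit=400
    )
    expect = dist.mean * (1 + dist.cv**2) / 2
    assert mean == pytest.approx(expect, rel=1e-6)


def test_residual_survival_matches_quadrature():
    d = D.from_moments("weibull", 1.0, 2.0)
    for t0 in (0.0, 0.7, 4.0):
        ref, _ = integrate.quad(d.survival, t0, np.inf, limit=400)
        assert d.residual_survival(t0) == pytest.approx(ref / d.mean, rel=1e-8)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _censored_ks(samples, cdf, floor=1e-250):
    """KS against the conditional law above `floor`.

    Strongly singular laws (gamma with tiny shape) hold substantial true
    mass below the smallest positive double; samples there are clamped, so
    the comparison conditions both sides on tau > floor.
    """
    kept = samples[samples > floor]
    c0 = cdf(floor)
    return stats.kstest(kept, lambda x: (cdf(x) - c0) / (1 - c0))


@pytest.mark.parametrize("family", TWO_PARAM)
@pytest.mark.parametrize("sd", [0.5, 1.0, 15.0, 80.0, 1300.0])
def test_sampler_ks_against_closed_form(family, sd):
    d = D.from_moments(family, 1.0, sd)
    x = d.sample(10_000, seed=7)
    res = _censored_ks(x, d._frozen.cdf)
    assert res.pvalue > 0.01, (family, sd, res)


def test_sampler_deterministic_given_seed():
    d = D.from_moments("weibull", 1.0, 2.0)
    np.testing.assert_array_equal(d.sample(500, seed=3), d.sample(500, seed=3))
    assert not np.array_equal(d.sample(500, seed=3), d.sample(500, seed=4))


def test_sampler_mean_exponential():
    x = D.exponential(1.0).sample(100_000, seed=11)
    assert abs(x.mean() - 1.0) <= 3 / np.sqrt(100_000)


def test_residual_sampler_mean():
    """Residual mean (1 + cv^2)/2 recovered by the residual sampler."""
    d = D.from_moments("weibull", 1.0, 2.0)
    x = d.sample(100_000, seed=13, which="residual")
    expect = (1 + 4) / 2
    assert x.mean() == pytest.approx(expect, rel=0.05)


def test_residual_sampler_ks():
    d = D.from_moments("gamma", 1.0, 0.8)
    x = d.sample(10_000, seed=17, which="residual")
    cdf = lambda t: 1.0 - d.residual_survival(t)
    assert stats.kstest(x, cdf).pvalue > 0.01


def test_sampling_grid_reproduces_nodes():
    grid = D.from_moments("weibull", 1.0, 2.0)._interevent_grid
    np.testing.assert_allclose(
        grid.interpolate_time(grid.levels), grid.times, rtol=1e-9
    )
    assert np.all(np.diff(grid.times) > 0)
    assert grid.floor <= 1e-12


def test_sample_rejects_bad_arguments():
    d = D.exponential(1.0)
    with pytest.raises(ValueError):
        d.sample(0, seed=1)
    with pytest.raises(ValueError):
        d.sample(10, seed=1, which="nonsense")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "dist",
    [
        D.from_moments("gamma", 1.0, 2.0),
        D.generalized_gamma_from_skewness(1.0, 2.0, 5.0),
    ],
    ids=lambda d: d.family,
)
def test_config_round_trip(dist):
    clone = D.InteventDistribution.from_config(dist.to_config())
    assert clone.family == dist.family
    for key, val in dist.native_params.items():
        assert clone.native_params[key] == pytest.approx(val, rel=1e-9)
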