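"""Event-driven Monte Carlo of cascades on renewal-process temporal networks.

Each static edge carries an independent stationary renewal process; an event
raises the edge state by one and is forgotten either after a fixed delay eta
(step memory kernel) or after an Exp(eta) lifetime (exponential kernel).
Node dynamics are binary-state, non-recovering, driven by the transmission
rate F of the chosen contagion model (relative threshold RT, absolute
threshold AT, or SI) evaluated on the node's current infected influence m.w
and total influence k.w, plus background noise at rate p.

The simulation merges a deterministic time-ordered queue of edge events and
memory expiries with exponential waiting times to node infection.  Between
structural events every F is constant, so infections can be scheduled
exactly: a single aggregate infection clock at the total rate R is resampled
whenever any rate changes (memorylessness makes this exact), and the firing
node is then selected proportionally to its rate.  Edge streams are realised
lazily out to the horizon, so heavy-tailed interevent draws never require
unbounded pregeneration.

Runs start from the stationary edge process: time is wound back to
t = -eta, one residual time is drawn per edge, and the network warms up so
that at t = 0 (when node dynamics start) the edge states follow their
stationary law E_j.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .distributions import InteventDistribution
from .netgen import StaticNetwork

__all__ = [
    "MemoryKernel",
    "DynamicsModel",
    "Trajectory",
    "transmission_rate",
    "init_stationary",
    "edge_state_at",
    "stationary_states",
    "run_cascade",
    "observables",
    "noise_only_time",
]

_RT, _AT, _SI = 0, 1, 2
#: Slack when testing m.w >= phi k.w in floats (phi k.w can carry one-ulp
#: noise, e.g. 0.15 * 20 > 3 in binary).
_THRESH_TOL = 1e-9


@dataclass(frozen=True)
class MemoryKernel:
    """How long past events contribute to interaction strength."""

    kind: str = "step"
    eta: float = 1.0

    def __post_init__(self):
        if self.kind not in ("step", "exponential"):
            raise ValueError("kernel kind must be 'step' or 'exponential'")
        if not self.eta > 0:
            raise ValueError("eta > 0 required")


@dataclass(frozen=True)
class DynamicsModel:
    """Contagion model: transmission rate F as a function of (m.w, k.w).

    RT: F = 1 if m.w >= phi k.w (and k.w > 0), else p.
    AT: F = 1 if m.w >= M_phi, else p.
    SI: F = max(p, lam m.w).
    """

    kind: str
    p: float
    phi: float | None = None
    M_phi: int | None = None
    lam: float | None = None

    def __post_init__(self):
        if self.kind not in ("RT", "AT", "SI"):
            raise ValueError("model kind must be RT, AT or SI")
        if not self.p > 0:
            raise ValueError("noise rate p must be positive")
        need = {"RT": "phi", "AT": "M_phi", "SI": "lam"}[self.kind]
        for name in ("phi", "M_phi", "lam"):
            val = getattr(self, name)
            if name == need and val is None:
                raise ValueError(f"{self.kind} model requires {name}")
            if name != need and val is not None:
                raise ValueError(f"{self.kind} model does not take {name}")
        if self.kind == "RT" and not 0 < self.phi <= 1:
            raise ValueError("phi must lie in (0, 1]")
        if self.kind == "AT" and self.M_phi < 1:
            raise ValueError("M_phi must be a positive integer")
        if self.kind == "SI" and not self.lam > 0:
            raise ValueError("lam must be positive")

    @staticmethod
    def relative_threshold(phi: float, p: float) -> "DynamicsModel":
        return DynamicsModel("RT", p, phi=phi)

    @staticmethod
    def absolute_threshold(M_phi: int, p: float) -> "DynamicsModel":
        return DynamicsModel("AT", p, M_phi=int(M_phi))

    @staticmethod
    def si(lam: float, p: float) -> "DynamicsModel":
        return DynamicsModel("SI", p, lam=lam)

    @property
    def kind_code(self) -> int:
        return {"RT": _RT, "AT": _AT, "SI": _SI}[self.kind]


def transmission_rate(model: DynamicsModel, m_dot_w, k_dot_w):
    """F(m.w, k.w) for the chosen model; vectorized.

    A node with no active influence (k.w = 0) can only be infected by noise
    under RT — required for the annealed limit, where the network plays no
    role and all infection is noise-driven.
    """
    m = np.asarray(m_dot_w, dtype=float)
    k = np.asarray(k_dot_w, dtype=float)
    if np.any(m < 0) or np.any(k < 0):
        raise ValueError("m.w and k.w must be non-negative")
    if np.any(m > k + _THRESH_TOL):
        raise ValueError("m.w cannot exceed k.w")
    if model.kind == "RT":
        hit = (k > 0) & (m >= model.phi * k - _THRESH_TOL)
        out = np.where(hit, 1.0, model.p)
    elif model.kind == "AT":
        out = np.where(m >= model.M_phi - _THRESH_TOL, 1.0, model.p)
    else:
        out = np.maximum(model.p, model.lam * m)
    return out if out.shape else float(out)


def noise_only_time(rho_c: float, p: float) -> float:
    """Time for noise alone to reach density rho_c: -ln(1 - rho_c)/p."""
    return -math.log1p(-rho_c) / p


# ---------------------------------------------------------------------------
# inverse-survival tables shared by the kernel and the vectorized paths
# ---------------------------------------------------------------------------

from .distributions import inverse_survival_table as _inverse_survival_table


# ---------------------------------------------------------------------------
# reference implementations (single edge / vectorized batch)
# ---------------------------------------------------------------------------

def init_stationary(net: StaticNetwork, dist, kernel: MemoryKernel, seed=None):
    """First event time per edge for a stationary start: -eta + residual.

    Subsequent interevent gaps are i.i.d. draws from psi, realised lazily by
    the simulator; at t = 0 the edge states are distributed as E_j.
    """
    rng = np.random.default_rng(seed)
    res = dist.sample(net.n_edges, seed=rng, which="residual")
    return -kernel.eta + res


def edge_state_at(events, t: float, kernel: MemoryKernel, seed=None) -> int:
    """State of a single edge with the given event times, observed at t.

    Step kernel: the number of events in (t - eta, t].  Exponential kernel:
    events whose independently drawn Exp(eta) lifetime has not yet elapsed.
    """
    ev = np.asarray(events, dtype=float)
    ev = ev[ev <= t]
    if kernel.kind == "step":
        return int(np.sum(ev > t - kernel.eta))
    rng = np.random.default_rng(seed)
    lifetimes = rng.exponential(kernel.eta, size=ev.size)
    return int(np.sum(ev + lifetimes > t))


def stationary_states(
    n_edges: int, dist, kernel: MemoryKernel, seed=None
) -> np.ndarray:
    """Stationary edge states at one observation instant, vectorized.

    Looking backward from the observation instant, the most recent event has
    age distributed as the residual law and earlier events follow at i.i.d.
    interevent gaps; the state counts ages inside the memory window (step)
    or events surviving an Exp(eta) lifetime (exponential kernel).
    """
    rng = np.random.default_rng(seed)
    eta = kernel.eta
    cutoff = eta if kernel.kind == "step" else eta * math.log(1e12)
    states = np.zeros(n_edges, dtype=np.int64)
    age = dist.sample(n_edges, seed=rng, which="residual")
    alive = age <= cutoff
    while alive.any():
        idx = np.flatnonzero(alive)
        if kernel.kind == "step":
            states[idx] += 1
        else:
            keep = rng.random(idx.size) < np.exp(-age[idx] / eta)
            states[idx] += keep
        age[idx] += dist.sample(idx.size, seed=rng)
        alive[idx] = age[idx] <= cutoff
    return states


# ---------------------------------------------------------------------------
# event-driven kernel (numba)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _heap_push(ht, hc, hn, t, code):
    i = hn
    ht[i] = t
    hc[i] = code
    while i > 0:
        parent = (i - 1) >> 1
        if ht[parent] > ht[i] or (ht[parent] == ht[i] and hc[parent] > hc[i]):
            ht[parent], ht[i] = ht[i], ht[parent]
            hc[parent], hc[i] = hc[i], hc[parent]
            i = parent
        else:
            break
    return hn + 1


@njit(cache=True, inline="always")
def _heap_pop(ht, hc, hn):
    t0, c0 = ht[0], hc[0]
    hn -= 1
    ht[0], hc[0] = ht[hn], hc[hn]
    i = 0
    while True:
        l, r = 2 * i + 1, 2 * i + 2
        m = i
        if l < hn and (ht[l] < ht[m] or (ht[l] == ht[m] and hc[l] < hc[m])):
            m = l
        if r < hn and (ht[r] < ht[m] or (ht[r] == ht[m] and hc[r] < hc[m])):
            m = r
        if m == i:
            break
        ht[m], ht[i] = ht[i], ht[m]
        hc[m], hc[i] = hc[i], hc[m]
        i = m
    return t0, c0, hn


@njit(cache=True, inline="always")
def _grow(ht, hc, cap):
    ht2 = np.empty(cap * 2, np.float64)
    hc2 = np.empty(cap * 2, np.int64)
    ht2[:cap] = ht
    hc2[:cap] = hc
    return ht2, hc2, cap * 2


@njit(cache=True, inline="always")
def _draw_tau(xs, ys):
    return math.exp(np.interp(-math.log(np.random.random()), xs, ys))


@njit(cache=True, inline="always")
def _is_above(kind, phi, M_phi, kw, mw):
    if kind == _RT:
        return kw > 0 and mw >= phi * kw - _THRESH_TOL
    return mw >= M_phi - _THRESH_TOL  # _AT


@njit(cache=True, inline="always")
def _reclassify(kind, phi, M_phi, lam, p, kw, mw, rate, pool, pos, n_above, u, R):
    """Refresh node u's rate bookkeeping after its (kw, mw) changed.

    Returns the updated (R, n_above).  For SI the per-node rate array and
    total rate are adjusted; for RT/AT the node is moved in or out of the
    above-threshold pool (rate 1) with O(1) swap-removal.
    """
    if kind == _SI:
        new_rate = max(p, lam * mw[u])
        R += new_rate - rate[u]
        rate[u] = new_rate
        return R, n_above
    now = _is_above(kind, phi, M_phi, kw[u], mw[u])
    was = pos[u] >= 0
    if now and not was:
        pool[n_above] = u
        pos[u] = n_above
        n_above += 1
        R += 1.0 - p
    elif was and not now:
        n_above -= 1
        last = pool[n_above]
        pool[pos[u]] = last
        pos[last] = pos[u]
        pos[u] = -1
        R += p - 1.0
    return R, n_above


@njit(cache=True)
def _run_kernel(
    n_nodes, indptr, nbr, nbr_eid, edge_u, edge_v,
    xs_ie, ys_ie, xs_re, ys_re,
    eta, exp_kernel,
    kind, phi, M_phi, lam, p,
    target, horizon, seed,
):
    np.random.seed(seed)
    n_edges = edge_u.shape[0]

    cap = 4 * n_edges + 64
    ht = np.empty(cap, np.float64)
    hc = np.empty(cap, np.int64)
    hn = 0

    state = np.zeros(n_edges, np.int64)
    kw = np.zeros(n_nodes, np.int64)
    mw = np.zeros(n_nodes, np.int64)
    infected = np.zeros(n_nodes, np.bool_)

    # ---- stationary warm-up on [-eta, 0] ---------------------------------
    for e in range(n_edges):
        te = -eta + math.exp(np.interp(-math.log(np.random.random()), xs_re, ys_re))
        if te <= horizon:
            hn = _heap_push(ht, hc, hn, te, 2 * e)

    while hn > 0 and ht[0] <= 0.0:
        if hn + 2 > cap:
            ht, hc, cap = _grow(ht, hc, cap)
        t, code, hn = _heap_pop(ht, hc, hn)
        e = code >> 1
        if code & 1:  # memory expiry
            state[e] -= 1
            kw[edge_u[e]] -= 1
            kw[edge_v[e]] -= 1
        else:  # renewal event
            state[e] += 1
            kw[edge_u[e]] += 1
            kw[edge_v[e]] += 1
            texp = t + (np.random.exponential(eta) if exp_kernel else eta)
            if texp <= horizon:
                hn = _heap_push(ht, hc, hn, texp, 2 * e + 1)
            tnext = t + _draw_tau(xs_ie, ys_ie)
            if tnext <= horizon:
                hn = _heap_push(ht, hc, hn, tnext, 2 * e)

    states0 = state.copy()

    # ---- node bookkeeping at t = 0 ---------------------------------------
    # With mw = 0 everywhere no node is above threshold (phi > 0, M_phi >= 1),
    # so RT/AT pools start empty and every node infects at the noise rate.
    pool = np.empty(n_nodes, np.int64)
    pos = np.full(n_nodes, -1, np.int64)
    n_above = 0
    rate = np.full(n_nodes, p, np.float64)  # SI only
    R = p * n_nodes

    inf_times = np.empty(target, np.float64)
    inf_noise = np.empty(target, np.int8)
    n_inf = 0

    t = 0.0
    while n_inf < target:
        ts = ht[0] if hn > 0 else horizon + 1.0
        tc = t + np.random.exponential(1.0 / R) if R > 0.0 else horizon + 1.0
        if tc <= ts and tc <= horizon:
            # ---- infection ------------------------------------------------
            t = tc
            u = -1
            if kind == _SI:
                x = np.random.random() * R
                acc = 0.0
                for v in range(n_nodes):
                    if not infected[v]:
                        acc += rate[v]
                        if acc >= x:
                            u = v
                            break
                if u < 0:  # float-drift guard
                    for v in range(n_nodes - 1, -1, -1):
                        if not infected[v]:
                            u = v
                            break
                is_noise = lam * mw[u] <= p
            elif np.random.random() * R < 1.0 * n_above:
                u = pool[np.random.randint(n_above)]
                is_noise = False
            else:
                # uniform over uninfected below-threshold nodes by rejection
                while True:
                    v = np.random.randint(n_nodes)
                    if not infected[v] and pos[v] < 0:
                        u = v
                        break
                is_noise = True
            infected[u] = True
            if kind == _SI:
                R -= rate[u]
                rate[u] = 0.0
            elif pos[u] >= 0:
                n_above -= 1
                last = pool[n_above]
                pool[pos[u]] = last
                pos[last] = pos[u]
                pos[u] = -1
                R -= 1.0
            else:
                R -= p
            for a in range(indptr[u], indptr[u + 1]):
                v = nbr[a]
                if infected[v]:
                    continue
                s = state[nbr_eid[a]]
                if s > 0:
                    mw[v] += s
                    R, n_above = _reclassify(
                        kind, phi, M_phi, lam, p, kw, mw, rate, pool, pos,
                        n_above, v, R,
                    )
            inf_times[n_inf] = t
            inf_noise[n_inf] = 1 if is_noise else 0
            n_inf += 1
        elif ts <= horizon:
            # ---- structural edge event ------------------------------------
            if hn + 2 > cap:
                ht, hc, cap = _grow(ht, hc, cap)
            t, code, hn = _heap_pop(ht, hc, hn)
            e = code >> 1
            if code & 1:
                delta = -1
                state[e] -= 1
            else:
                delta = 1
                state[e] += 1
                texp = t + (np.random.exponential(eta) if exp_kernel else eta)
                if texp <= horizon:
                    hn = _heap_push(ht, hc, hn, texp, 2 * e + 1)
                tnext = t + _draw_tau(xs_ie, ys_ie)
                if tnext <= horizon:
                    hn = _heap_push(ht, hc, hn, tnext, 2 * e)
            u = edge_u[e]
            v = edge_v[e]
            kw[u] += delta
            kw[v] += delta
            if not infected[u]:
                if infected[v]:
                    mw[u] += delta
                R, n_above = _reclassify(
                    kind, phi, M_phi, lam, p, kw, mw, rate, pool, pos,
                    n_above, u, R,
                )
            if not infected[v]:
                if infected[u]:
                    mw[v] += delta
                R, n_above = _reclassify(
                    kind, phi, M_phi, lam, p, kw, mw, rate, pool, pos,
                    n_above, v, R,
                )
        else:
            t = horizon
            break

    return inf_times[:n_inf], inf_noise[:n_inf], t, states0


# ---------------------------------------------------------------------------
# trajectories and observables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """One realisation (or one analytic solution) of a cascade.

    ``times``/``rho`` trace the infected density; ``rho_tilde`` is the
    expected noise-infected density p Int_0^t (1 - rho).  For Monte Carlo
    runs ``noise_flags`` marks infections whose channel was noise at the
    instant of firing (F = p), giving the counted-channel variant of rho_f.
    """

    times: np.ndarray
    rho: np.ndarray
    rho_tilde: np.ndarray
    rho_c: float
    p: float
    reached: bool
    noise_flags: np.ndarray | None = None
    states0: np.ndarray | None = None

    @property
    def t_c(self) -> float:
        """First time the infected density reaches rho_c."""
        if not self.reached:
            raise ValueError("trajectory did not reach rho_c (flagged)")
        i = int(np.searchsorted(self.rho, self.rho_c))
        return float(self.times[min(i, len(self.times) - 1)])

    @property
    def rho_f(self) -> float:
        """Fraction of infections due to noise: rho_tilde(t_c)/rho(t_c)."""
        if not self.reached:
            raise ValueError("trajectory did not reach rho_c (flagged)")
        i = int(np.searchsorted(self.rho, self.rho_c))
        i = min(i, len(self.times) - 1)
        return float(self.rho_tilde[i] / self.rho[i])

    @property
    def t_f(self) -> float:
        """Diffusion time normalised by the noise-only time."""
        return self.t_c / noise_only_time(self.rho_c, self.p)

    @property
    def rho_f_counted(self) -> float:
        """Share of realised infections whose firing channel was noise."""
        if self.noise_flags is None:
            raise ValueError("no per-infection channels on this trajectory")
        i = int(np.searchsorted(self.rho, self.rho_c)) if self.reached else len(self.rho)
        i = min(max(i, 1), len(self.noise_flags))
        return float(self.noise_flags[:i].mean())

    def rho_at(self, t):
        return np.interp(t, self.times, self.rho, left=0.0)

    def rho_tilde_at(self, t):
        return np.interp(t, self.times, self.rho_tilde, left=0.0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times, "rho": self.rho, "rho_tilde": self.rho_tilde}
        )

    def summary(self) -> dict:
        out = {
            "rho_c": self.rho_c,
            "p": self.p,
            "reached": bool(self.reached),
            "rho_final": float(self.rho[-1]) if len(self.rho) else 0.0,
        }
        if self.reached:
            out.update(t_c=self.t_c, rho_f=self.rho_f, t_f=self.t_f)
            if self.noise_flags is not None:
                out["rho_f_counted"] = self.rho_f_counted
        return out


def observables(traj: Trajectory, rho_c: float | None = None, p: float | None = None):
    """(rho_f, t_f) of a trajectory; errors if rho_c was never reached."""
    rho_c = traj.rho_c if rho_c is None else rho_c
    p = traj.p if p is None else p
    if not traj.reached:
        raise ValueError("rho_c not reached within the horizon (reached=False)")
    i = int(np.searchsorted(traj.rho, rho_c))
    i = min(i, len(traj.times) - 1)
    t_c = float(traj.times[i])
    rho_f = float(traj.rho_tilde[i] / traj.rho[i])
    return rho_f, t_c / noise_only_time(rho_c, p)


def run_cascade(
    net: StaticNetwork,
    dist: InteventDistribution,
    kernel: MemoryKernel,
    model: DynamicsModel,
    rho_c: float = 0.4,
    horizon: float | None = None,
    seed=None,
) -> Trajectory:
    """Simulate one cascade until rho_c is reached (or the horizon expires).

    The default horizon is twice the noise-only time, which bounds t_c up to
    fluctuations since noise alone reaches rho_c at that time in expectation.
    """
    if not 0 < rho_c < 1:
        raise ValueError("rho_c must lie in (0, 1)")
    if horizon is None:
        horizon = 2.0 * noise_only_time(rho_c, model.p)
    xs_ie, ys_ie = _inverse_survival_table(dist, "interevent")
    xs_re, ys_re = _inverse_survival_table(dist, "residual")
    indptr, nbr, nbr_eid = net.adjacency_csr()
    edge_u = np.ascontiguousarray(net.edges[:, 0])
    edge_v = np.ascontiguousarray(net.edges[:, 1])
    target = int(math.ceil(rho_c * net.n_nodes))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed = int(ss.generate_state(1, np.uint32)[0] % (2**31))
    inf_t, inf_noise, t_end, states0 = _run_kernel(
        net.n_nodes, indptr, nbr, nbr_eid, edge_u, edge_v,
        xs_ie, ys_ie, xs_re, ys_re,
        float(kernel.eta), kernel.kind == "exponential",
        model.kind_code,
        float(model.phi or 0.0), float(model.M_phi or 0), float(model.lam or 0.0),
        float(model.p),
        target, float(horizon), seed,
    )
    n = net.n_nodes
    rho = np.arange(1, len(inf_t) + 1) / n
    # exact p * Int (1 - rho): rho is a step function between infections
    gaps = np.diff(np.concatenate([[0.0], inf_t]))
    one_minus_rho = 1.0 - np.concatenate([[0.0], rho[:-1]])
    rho_tilde = model.p * np.cumsum(gaps * one_minus_rho)
    return Trajectory(
        times=inf_t,
        rho=rho,
        rho_tilde=rho_tilde,
        rho_c=rho_c,
        p=model.p,
        reached=len(inf_t) >= target,
        noise_flags=inf_noise.astype(bool),
        states0=states0,
    )
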