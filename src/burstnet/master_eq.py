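"""Master-equation solution of binary-state cascades on temporal networks.

A node is classified by the pair of vectors (k, m): k_j counts its edges in
state j (so sum_j k_j = k, the underlying degree) and m_j counts infected
neighbours reached through state-j edges.  The density s_{k,m} of uninfected
nodes in each class — normalised within each underlying degree so that
sum_{C_k} (s + i) = 1 — evolves under three coupled mechanisms:

* ego transitions: class (k, m) loses uninfected nodes at the transmission
  rate F_{k,m} of the contagion model;
* neighbour transitions: an uninfected neighbour behind a state-j edge
  becomes infected at the ensemble rate
  beta_j = sum_S p_k (k_j - m_j) F s / sum_S p_k (k_j - m_j) s,
  moving the node from (k, m) to (k, m + e_j);
* edge transitions: a state-j edge jumps to j +/- 1 at the stationary
  renewal rates mu_j / nu_j, shifting (k, m) by Delta_j^± = -e_j + e_{j±1}
  in k (and in m when the neighbour behind the edge is infected).

The resulting nonlinear system ds/dt = (W_ego + W_neigh + W_edge) s is
integrated with an adaptive explicit scheme; infected-class densities are
evolved with the same neighbour/edge flows (without the ego term) so that
per-degree probability conservation is an auditable invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import integrate as sci_integrate
from scipy import sparse, special

from .edge_state import EdgeStateSpectrum
from .netgen import DegreeModel
from .simulate import DynamicsModel, Trajectory, noise_only_time, transmission_rate

__all__ = [
    "ConfigurationSpace",
    "GeneratorMatrices",
    "build_space",
    "space_size",
    "beta_rates",
    "assemble",
    "initial_condition",
    "integrate",
    "DEGREE_CUTOFF_CUMULATIVE",
]

#: Degree support kept for the master equation: smallest k_max whose
#: cumulative probability reaches this value; the pmf is renormalized.
DEGREE_CUTOFF_CUMULATIVE = 1.0 - 1e-3

#: Refuse to enumerate configuration spaces larger than this.
DEFAULT_CLASS_BUDGET = 2_000_000


def space_size(k: int, n: int) -> int:
    """|C_k| = C(k + 2n - 1, 2n - 1): compositions of k into n edge states
    times the nested 0 <= m_j <= k_j choices."""
    return math.comb(k + 2 * n - 1, 2 * n - 1)


@dataclass(frozen=True)
class ConfigurationSpace:
    """Enumerated (k, m) classes for every degree in the truncated support."""

    n: int
    p_k: DegreeModel
    kvecs: np.ndarray = field(repr=False)  # (|C|, n) int16
    mvecs: np.ndarray = field(repr=False)
    degree: np.ndarray = field(repr=False)  # underlying degree per class
    index: dict = field(repr=False)  # (kvec, mvec) tuple -> row

    @property
    def n_classes(self) -> int:
        return len(self.degree)

    @property
    def weights(self) -> np.ndarray:
        """p(k) of each class's underlying degree (class weight in Eq.-10
        style ensemble sums and in rho)."""
        pk = dict(zip(self.p_k.support.tolist(), self.p_k.pmf.tolist()))
        return np.array([pk[int(k)] for k in self.degree])

    def locate(self, kvec, mvec) -> int:
        return self.index[(tuple(kvec), tuple(mvec))]


def build_space(
    p_k: DegreeModel, n: int, budget: int = DEFAULT_CLASS_BUDGET
) -> ConfigurationSpace:
    """Exhaustively enumerate C in lexicographic (k, m)-tuple order."""
    if n < 1:
        raise ValueError("n >= 1 required")
    support = [int(k) for k, w in zip(p_k.support, p_k.pmf) if w > 0]
    predicted = sum(space_size(k, n) for k in support)
    if predicted > budget:
        raise MemoryError(
            f"configuration space has {predicted:,} classes "
            f"(budget {budget:,}); reduce n or the degree cutoff"
        )
    classes = []
    for k in support:
        for kvec in _compositions(k, n):
            for mvec in product(*(range(kj + 1) for kj in kvec)):
                classes.append((kvec, mvec))
    classes.sort()
    kvecs = np.array([c[0] for c in classes], dtype=np.int16)
    mvecs = np.array([c[1] for c in classes], dtype=np.int16)
    degree = kvecs.sum(axis=1).astype(np.int64)
    index = {c: i for i, c in enumerate(classes)}
    return ConfigurationSpace(n, p_k, kvecs, mvecs, degree, index)


def _compositions(k: int, n: int):
    if n == 1:
        yield (k,)
        return
    for first in range(k + 1):
        for rest in _compositions(k - first, n - 1):
            yield (first,) + rest


# ---------------------------------------------------------------------------
# generator matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorMatrices:
    """Constant parts of W; the state-dependent beta_j weights multiply the
    per-j neighbour matrices at every right-hand-side evaluation."""

    F: np.ndarray  # ego rates per class (diagonal of -W_ego)
    W_edge: sparse.csr_matrix  # mu/nu flows, probability conserving
    B: list  # per-j neighbour flow matrices (unit beta)
    a: np.ndarray = field(repr=False)  # (n, |C|): p_k (k_j - m_j) weights


def assemble(
    space: ConfigurationSpace,
    spectrum: EdgeStateSpectrum,
    model: DynamicsModel,
) -> GeneratorMatrices:
    """Build W_ego's diagonal, W_edge and the unit-beta neighbour matrices.

    The spectrum must be truncated to the space's n states; its tail is
    folded into the top state so the edge chain is stationary on the finite
    space (mu_{n-1} = 0, nu_{n-1} rebalanced).
    """
    if spectrum.n != space.n:
        raise ValueError(
            f"spectrum has {spectrum.n} states but the space has {space.n}"
        )
    sp = spectrum.folded() if spectrum.tail_mass > 0 else spectrum
    n = space.n
    kv = space.kvecs.astype(np.int64)
    mv = space.mvecs.astype(np.int64)
    w = np.arange(n)
    F = np.asarray(
        transmission_rate(model, (mv * w).sum(axis=1), (kv * w).sum(axis=1)),
        dtype=float,
    )

    idx = space.index
    n_classes = space.n_classes
    kt = [tuple(row) for row in space.kvecs.tolist()]
    mt = [tuple(row) for row in space.mvecs.tolist()]

    rows_e, cols_e, vals_e = [], [], []
    B = []

    def add_edge_flow(src, dst, rate):
        rows_e.append(dst)
        cols_e.append(src)
        vals_e.append(rate)
        rows_e.append(src)
        cols_e.append(src)
        vals_e.append(-rate)

    for c in range(n_classes):
        kvec, mvec = kt[c], mt[c]
        for j in range(n):
            kj, mj = kvec[j], mvec[j]
            if kj == 0:
                continue
            # positive edge transitions j -> j+1 at mu_j
            if j + 1 < n and sp.mu[j] > 0:
                k_up = _shift(kvec, j, j + 1)
                if kj - mj > 0:
                    add_edge_flow(c, idx[(k_up, mvec)], sp.mu[j] * (kj - mj))
                if mj > 0:
                    add_edge_flow(c, idx[(k_up, _shift(mvec, j, j + 1))], sp.mu[j] * mj)
            # negative edge transitions j -> j-1 at nu_j
            if j >= 1 and sp.nu[j] > 0:
                k_dn = _shift(kvec, j, j - 1)
                if kj - mj > 0:
                    add_edge_flow(c, idx[(k_dn, mvec)], sp.nu[j] * (kj - mj))
                if mj > 0:
                    add_edge_flow(c, idx[(k_dn, _shift(mvec, j, j - 1))], sp.nu[j] * mj)

    W_edge = sparse.csr_matrix(
        (vals_e, (rows_e, cols_e)), shape=(n_classes, n_classes)
    )

    for j in range(n):
        rows, cols, vals = [], [], []
        free = (kv[:, j] - mv[:, j]).astype(float)  # k_j - m_j
        for c in np.flatnonzero(free > 0):
            dst = idx[(kt[c], _bump(mt[c], j))]
            rows.append(dst)
            cols.append(c)
            vals.append(free[c])
            rows.append(c)
            cols.append(c)
            vals.append(-free[c])
        B.append(
            sparse.csr_matrix((vals, (rows, cols)), shape=(n_classes, n_classes))
        )

    a = (space.weights[None, :] * (kv - mv).T).astype(float)  # (n, |C|)
    return GeneratorMatrices(F, W_edge, B, a)


def _shift(vec: tuple, j: int, j2: int) -> tuple:
    out = list(vec)
    out[j] -= 1
    out[j2] += 1
    return tuple(out)


def _bump(vec: tuple, j: int) -> tuple:
    out = list(vec)
    out[j] += 1
    return tuple(out)


def beta_rates(
    space: ConfigurationSpace,
    s: np.ndarray,
    model: DynamicsModel,
    matrices: GeneratorMatrices | None = None,
) -> np.ndarray:
    """Neighbour transition rates beta_j from the current uninfected state.

    beta_j dt is the probability that the uninfected neighbour behind a
    state-j edge of an uninfected node becomes infected in dt; an empty
    ensemble (no uninfected-uninfected j-edges) yields beta_j = 0, whose
    flows carry zero weight anyway.
    """
    if matrices is None:
        kv = space.kvecs.astype(np.int64)
        mv = space.mvecs.astype(np.int64)
        w = np.arange(space.n)
        F = np.asarray(
            transmission_rate(model, (mv * w).sum(axis=1), (kv * w).sum(axis=1)),
            dtype=float,
        )
        a = (space.weights[None, :] * (kv - mv).T).astype(float)
    else:
        F, a = matrices.F, matrices.a
    num = a @ (F * s)
    den = a @ s
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(den > 0, num / den, 0.0)
    return beta


def initial_condition(
    space: ConfigurationSpace, spectrum: EdgeStateSpectrum
) -> np.ndarray:
    """All nodes uninfected; k-vectors multinomial in the stationary E_j.

    s0(k, m=0) = k!/(prod k_j!) prod E_j^{k_j}, the probability that a
    degree-k node's edges occupy the states independently with the folded
    stationary occupancies.
    """
    if spectrum.n != space.n:
        raise ValueError("spectrum/space state-count mismatch")
    E = spectrum.folded().E if spectrum.tail_mass > 0 else spectrum.E
    logE = np.full(space.n, -np.inf)
    pos = E > 0
    logE[pos] = np.log(E[pos])
    kv = space.kvecs.astype(np.int64)
    s0 = np.zeros(space.n_classes)
    m_zero = ~space.mvecs.any(axis=1)
    with np.errstate(invalid="ignore"):
        logw = (
            special.gammaln(space.degree + 1)
            - special.gammaln(kv + 1).sum(axis=1)
            + np.where(kv > 0, kv * logE[None, :], 0.0).sum(axis=1)
        )
    s0[m_zero] = np.exp(logw[m_zero])
    # renormalize exactly within each degree (guards E rounding)
    for k in np.unique(space.degree):
        sel = m_zero & (space.degree == k)
        s0[sel] /= s0[sel].sum()
    return s0


def rho_of(space: ConfigurationSpace, s: np.ndarray) -> float:
    """Infected density 1 - sum_k p(k) sum_{C_k} s."""
    return 1.0 - float(space.weights @ s)


def integrate(
    space: ConfigurationSpace,
    matrices: GeneratorMatrices,
    model: DynamicsModel,
    s0: np.ndarray,
    *,
    rho_c: float = 0.4,
    horizon: float | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-10,
    method: str = "RK45",
    return_state: bool = False,
):
    """Integrate the master equation until rho crosses rho_c.

    The state vector stacks (s, i, rho_tilde); beta_j is recomputed from the
    current s at every right-hand-side evaluation (the system is nonlinear).
    Returns a Trajectory on a uniform reporting grid plus the exact crossing
    time located by the solver's event root-finding.
    """
    if horizon is None:
        horizon = 2.0 * noise_only_time(rho_c, model.p)
    C = space.n_classes
    pw = space.weights
    F = matrices.F
    W_edge = matrices.W_edge
    B = matrices.B

    def rhs(_, y):
        s = y[:C]
        i = y[C : 2 * C]
        beta = beta_rates(space, s, model, matrices)
        X = np.stack([s, i], axis=1)
        flow = W_edge @ X
        for j, bj in enumerate(B):
            if beta[j] != 0.0:
                flow += beta[j] * (bj @ X)
        ego = F * s
        return np.concatenate(
            [flow[:, 0] - ego, flow[:, 1] + ego, [model.p * (pw @ s)]]
        )

    # step the solver manually, recording (t, rho, rho_tilde) per accepted
    # step: the trajectory then resolves the cascade at the solver's own
    # time scale without retaining the full state history
    solver_cls = {"RK45": sci_integrate.RK45, "LSODA": sci_integrate.LSODA}[method]
    y0 = np.concatenate([s0, np.zeros(C), [0.0]])
    solver = solver_cls(rhs, 0.0, y0, t_bound=horizon, rtol=rtol, atol=atol)
    times = [0.0]
    rho = [1.0 - float(pw @ s0)]
    rho_tilde = [0.0]
    reached = rho[0] >= rho_c
    while solver.status == "running" and not reached:
        msg = solver.step()
        if solver.status == "failed":
            raise RuntimeError(f"master-equation integration failed: {msg}")
        r = 1.0 - float(pw @ solver.y[:C])
        times.append(solver.t)
        rho.append(r)
        rho_tilde.append(float(solver.y[-1]))
        if r >= rho_c:
            reached = True
            # refine the crossing on the local interpolant
            dense = solver.dense_output()
            lo, hi = dense.t_min, dense.t_max
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if 1.0 - pw @ dense(mid)[:C] < rho_c:
                    lo = mid
                else:
                    hi = mid
            t_c = 0.5 * (lo + hi)
            y_c = dense(t_c)
            times[-1] = t_c
            rho[-1] = 1.0 - float(pw @ y_c[:C])
            rho_tilde[-1] = float(y_c[-1])
    traj = Trajectory(
        times=np.asarray(times),
        rho=np.maximum.accumulate(rho),
        rho_tilde=np.asarray(rho_tilde),
        rho_c=rho_c,
        p=model.p,
        reached=reached,
    )
    return (traj, solver.y) if return_state else traj


def conservation_defect(space: ConfigurationSpace, y: np.ndarray) -> float:
    """Max per-degree deviation of sum_{C_k}(s + i) from 1."""
    C = space.n_classes
    tot = y[:C] + y[C : 2 * C]
    worst = 0.0
    for k in np.unique(space.degree):
        worst = max(worst, abs(tot[space.degree == k].sum() - 1.0))
    return worst
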