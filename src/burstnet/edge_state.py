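"""Stationary edge-state spectrum of a renewal process seen through memory.

An edge whose events follow a stationary renewal process with interevent law
psi is assigned the state j = number of events in active memory.  Under a
step-function kernel of width eta this is the event count in the trailing
window (t - eta, t].  The stationary occupancy E_j, the upward rate mu_j
(state j -> j+1) and the downward rate nu_j (j -> j-1) follow from
convolution identities in the Laplace domain,

    E_j  propto  (Psi * psi^{*(j-1)} * Psi)(eta),     j >= 1,
    mu_j = (Psi * psi^{*j})(eta) / (Psi * psi^{*(j-1)} * Psi)(eta),
    nu_j = (Psi * psi^{*(j-1)})(eta) / (Psi * psi^{*(j-1)} * Psi)(eta),

with the j = 0 members given by the effective sparsification

    xi_E = E_0 = (1/<tau>) Int_eta^inf Psi,    xi_mu = mu_0,

the fraction of edges holding no event in memory and their escape rate.
The inverse transforms are evaluated at eta by the Gaver-Stehfest algorithm
in extended precision; a direct grid-convolution route is provided as an
independent cross-check, and a Monte-Carlo estimator covers the exponential
(constant-forgetting-rate) memory kernel, for which no transform route is
derived here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache

import mpmath
import numpy as np
from scipy import stats

from .distributions import InteventDistribution

__all__ = [
    "EdgeStateSpectrum",
    "xi_E",
    "xi_mu",
    "spectrum",
    "spectrum_by_convolution",
    "state0_fraction_exponential_kernel",
    "default_state_count",
]

#: Gaver-Stehfest terms (must be even) and working precision in digits.
STEHFEST_TERMS = 16
STEHFEST_DPS = 60

#: Tail probability targeted when choosing the represented state count.
TAIL_TARGET = 1e-6


class SpectrumError(RuntimeError):
    """Numerical failure of the Laplace-inversion route."""


@dataclass(frozen=True)
class EdgeStateSpectrum:
    """Occupancies and transition rates of the edge-state birth-death chain."""

    eta: float
    dist: InteventDistribution
    n: int
    E: np.ndarray
    mu: np.ndarray
    nu: np.ndarray
    xi_E: float
    xi_mu: float
    tail_mass: float
    method: str

    @property
    def mean_state(self) -> float:
        """Sum_j j E_j; equals eta/<tau> up to the truncated tail."""
        return float(np.arange(self.n) @ self.E)

    def folded(self) -> "EdgeStateSpectrum":
        """Fold the truncated tail into the top state.

        Used by the master equation, which needs a finite chain whose
        occupancies sum to one.  The downward rate of the top state is
        rebalanced so the folded chain keeps E stationary exactly.
        """
        E = self.E.copy()
        E[-1] += self.tail_mass
        nu = self.nu.copy()
        mu = self.mu.copy()
        mu[-1] = 0.0
        if self.n >= 2 and E[-1] > 0:
            nu[-1] = mu[-2] * E[-2] / E[-1]
        return EdgeStateSpectrum(
            self.eta, self.dist, self.n, E, mu, nu,
            self.xi_E, self.xi_mu, 0.0, self.method + "+folded",
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"j": np.arange(self.n), "E": self.E, "mu": self.mu, "nu": self.nu}
        )

    def to_json(self) -> str:
        meta = {
            "family": self.dist.family,
            "mean": self.dist.mean,
            "sd": self.dist.sd,
            "eta": self.eta,
            "n": self.n,
            "method": self.method,
            "tail_mass": self.tail_mass,
            "xi_E": self.xi_E,
            "xi_mu": self.xi_mu,
            "E": self.E.tolist(),
            "mu": self.mu.tolist(),
            "nu": self.nu.tolist(),
        }
        return json.dumps(meta, indent=1)


# ---------------------------------------------------------------------------
# the j = 0 members
# ---------------------------------------------------------------------------

def xi_E(dist: InteventDistribution, eta: float) -> float:
    """Effective sparsification: stationary fraction of edges in state 0.

    xi_E = (1/<tau>) Int_eta^inf Psi(tau) d tau, i.e. the probability that
    the residual time from a random instant to the next event exceeds eta.
    Monotone non-increasing in eta, equal to 1 at eta = 0.
    """
    if eta < 0:
        raise ValueError("eta >= 0 required")
    return float(dist.residual_survival(eta))


def xi_mu(dist: InteventDistribution, eta: float) -> float:
    """Escape rate of state-0 edges: Int_eta^inf psi / Int_eta^inf Psi."""
    if eta < 0:
        raise ValueError("eta >= 0 required")
    denom = dist.mean * xi_E(dist, eta)  # = Int_eta^inf Psi
    if denom <= 0 or not np.isfinite(denom):
        raise ValueError(f"state-0 mass vanishes at eta={eta:g}; xi_mu undefined")
    return float(dist.survival(eta)) / denom  # Int_eta^inf psi = Psi(eta)


# ---------------------------------------------------------------------------
# Gaver-Stehfest route
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _stehfest_coefficients(n_terms: int, dps: int):
    """Classic Stehfest weights; catastrophically ill-conditioned in doubles,
    hence computed and applied at `dps` significant digits."""
    with mpmath.workdps(dps):
        half = n_terms // 2
        coeffs = []
        for k in range(1, n_terms + 1):
            s = mpmath.mpf(0)
            for j in range((k + 1) // 2, min(k, half) + 1):
                num = (
                    mpmath.mpf(j) ** half
                    * mpmath.factorial(2 * j)
                )
                den = (
                    mpmath.factorial(half - j)
                    * mpmath.factorial(j)
                    * mpmath.factorial(j - 1)
                    * mpmath.factorial(k - j)
                    * mpmath.factorial(2 * j - k)
                )
                s += num / den
            coeffs.append((-1) ** (k + half) * s)
        return coeffs


def default_state_count(dist: InteventDistribution, eta: float) -> int:
    """Represented states: cover the Poisson proxy mean eta/<tau> out to the
    tail-probability target, at least 8 standard deviations beyond the mean."""
    lam = eta / dist.mean
    n = int(stats.poisson(lam).isf(TAIL_TARGET) + 1)
    n = max(n, int(math.ceil(lam + 8 * math.sqrt(max(lam, 1e-12)))))
    return max(n + 1, 2)


def spectrum(
    dist: InteventDistribution,
    eta: float,
    n: int | None = None,
    *,
    n_terms: int = STEHFEST_TERMS,
    dps: int = STEHFEST_DPS,
    method: str = "auto",
) -> EdgeStateSpectrum:
    """Stationary (E_j, mu_j, nu_j) for j = 0..n-1 via Laplace inversion.

    For exponential interevent times the closed Poisson form is used:
    E_j = Poisson(eta/<tau>), mu_j = 1/<tau>, nu_j = j/eta.  With
    ``method="auto"`` an unstable inversion (sharply peaked sub-Poissonian
    laws, where Stehfest convergence degrades) falls back to the direct
    grid-convolution route, which is authoritative when the two disagree.
    """
    if eta <= 0:
        raise ValueError("eta > 0 required")
    if n is None:
        n = default_state_count(dist, eta)
    if n < 2:
        raise ValueError("n >= 2 required")

    if dist.family == "exponential":
        return _poisson_spectrum(dist, eta, n)
    if method == "convolution":
        return spectrum_by_convolution(dist, eta, n, eta / 4000)
    if method == "auto":
        try:
            return spectrum(dist, eta, n, n_terms=n_terms, dps=dps, method="stehfest")
        except SpectrumError:
            return spectrum_by_convolution(dist, eta, n, eta / 4000)

    with mpmath.workdps(dps):
        coeffs = _stehfest_coefficients(n_terms, dps)
        ln2 = mpmath.ln(2)
        eta_mp = mpmath.mpf(eta)
        s_nodes = [k * ln2 / eta_mp for k in range(1, n_terms + 1)]
        psi_hat = [dist.laplace_mp(s) for s in s_nodes]
        psi_tilde = [(1 - ph) / s for ph, s in zip(psi_hat, s_nodes)]

        def invert(powers_of_psi: int, n_psi_tilde: int) -> float:
            # L^{-1}[ Psi~^n_psi_tilde * psi^powers ](eta)
            acc = mpmath.mpf(0)
            for k in range(n_terms):
                acc += (
                    coeffs[k]
                    * psi_tilde[k] ** n_psi_tilde
                    * psi_hat[k] ** powers_of_psi
                )
            return float(acc * ln2 / eta_mp)

        D = np.array([invert(j - 1, 2) for j in range(1, n)])  # ~ E_j <tau>
        N = np.array([invert(j, 1) for j in range(0, n)])  # (Psi * psi^{*j})(eta)

    mean = dist.mean
    E = np.empty(n)
    E[0] = xi_E(dist, eta)
    E[1:] = D / mean
    # Stehfest at 16 terms carries ~1e-6 absolute method error; far-tail
    # occupancies below that scale surface as small negatives and are clipped
    if np.any(E < -1e-5) or not np.all(np.isfinite(E)):
        raise SpectrumError(
            "Gaver-Stehfest inversion produced invalid occupancies "
            f"(min {E.min():.3g}); use spectrum_by_convolution instead"
        )
    E = np.maximum(E, 0.0)
    tail = max(0.0, 1.0 - E.sum())

    mu = np.empty(n)
    nu = np.empty(n)
    mu[0] = xi_mu(dist, eta)
    nu[0] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu[1:] = np.where(D > 0, N[1:] / D, 0.0)
        nu[1:] = np.where(D > 0, N[:-1] / D, 0.0)
    mu = np.maximum(mu, 0.0)
    nu = np.maximum(nu, 0.0)
    return EdgeStateSpectrum(
        eta, dist, n, E, mu, nu, float(E[0]), float(mu[0]), tail, "gaver-stehfest"
    )


def _poisson_spectrum(dist, eta, n) -> EdgeStateSpectrum:
    lam = eta / dist.mean
    j = np.arange(n)
    E = stats.poisson(lam).pmf(j)
    mu = np.full(n, 1.0 / dist.mean)
    nu = j / eta
    tail = float(stats.poisson(lam).sf(n - 1))
    return EdgeStateSpectrum(
        eta, dist, n, E, mu, nu, float(E[0]), float(mu[0]), tail, "poisson-closed-form"
    )


# ---------------------------------------------------------------------------
# grid-convolution oracle
# ---------------------------------------------------------------------------

def spectrum_by_convolution(
    dist: InteventDistribution,
    eta: float,
    n: int | None = None,
    grid_step: float = 1e-3,
) -> EdgeStateSpectrum:
    """Direct real-space evaluation of the convolution identities.

    psi is discretized into cell masses w_i = Psi(x_i) - Psi(x_{i+1}) with
    atoms at cell midpoints, so densities with an integrable singularity at
    zero (heavy-tailed Weibull/gamma shapes) lose no mass.  Convolution
    powers are exact discrete convolutions of the mass vectors, and
    (Psi * psi^{*(j-1)} * Psi)(eta) = sum_i w^{(j-1)}_i (Psi*Psi)(eta - a_i)
    with (Psi*Psi) tabulated once by trapezoidal convolution.  Error is
    O(grid_step); the route is independent of the Laplace-domain machinery
    and serves as its oracle.
    """
    if eta <= 0:
        raise ValueError("eta > 0 required")
    if not grid_step < eta / 10:
        raise ValueError("grid_step must be << eta")
    if n is None:
        n = default_state_count(dist, eta)

    h = grid_step
    m = int(round(eta / h))
    edges = np.arange(m + 1) * h
    surv_edges = dist.survival(edges)
    cell_mass = surv_edges[:-1] - surv_edges[1:]  # atom i at (i + 1/2) h

    # (Psi * Psi)(t) tabulated on the grid; trapezoid rule, both endpoint
    # corrections equal Psi(0) Psi(t) h / 2
    G = np.convolve(surv_edges, surv_edges)[: m + 1] * h - h * surv_edges

    mass = np.array([1.0])  # psi^{*0}: unit atom at the origin
    atom_offset = 0.0
    D = np.full(n, np.nan)  # D[j] = (Psi * psi^{*(j-1)} * Psi)(eta), j >= 1
    N = np.empty(n)  # N[j] = (Psi * psi^{*j})(eta)
    N[0] = float(dist.survival(eta))
    for j in range(1, n):
        pos = atom_offset + np.arange(mass.size) * h
        D[j] = float(mass @ np.interp(eta - pos, edges, G))
        mass = np.convolve(mass, cell_mass)
        atom_offset += h / 2
        pos = atom_offset + np.arange(mass.size) * h
        keep = pos <= eta  # atoms beyond eta cannot contribute at eta again
        mass = mass[keep]
        N[j] = float(mass @ dist.survival(eta - pos[keep]))

    E = np.empty(n)
    E[0] = xi_E(dist, eta)
    E[1:] = D[1:] / dist.mean
    total = E.sum()
    if total > 1 + 1e-3:
        raise ValueError(
            f"grid too coarse: occupancies sum to {total:.5f} > 1; reduce grid_step"
        )
    tail = max(0.0, 1.0 - total)
    mu = np.empty(n)
    nu = np.empty(n)
    mu[0] = xi_mu(dist, eta)
    nu[0] = 0.0
    mu[1:] = N[1:] / D[1:]
    nu[1:] = N[:-1] / D[1:]
    return EdgeStateSpectrum(
        eta, dist, n, E, mu, nu, float(E[0]), float(mu[0]), tail, "grid-convolution"
    )


# ---------------------------------------------------------------------------
# exponential memory kernel (Monte Carlo)
# ---------------------------------------------------------------------------

def state0_fraction_exponential_kernel(
    dist: InteventDistribution,
    eta: float,
    n_hist: int = 100_000,
    seed=None,
    return_se: bool = False,
):
    """Stationary P(state = 0) when events are forgotten at rate 1/eta.

    Each past event of age a is still remembered with probability
    exp(-a/eta).  Over simulated stationary renewal histories the
    probability that no event is remembered is the mean of
    prod_i (1 - exp(-a_i/eta)), taking the expectation over the
    independent memory coin-flips analytically within each history.
    Ages beyond eta * ln(1/eps) contribute less than eps and are cut off.
    """
    if eta < 0:
        raise ValueError("eta >= 0 required")
    if eta == 0:
        return (1.0, 0.0) if return_se else 1.0
    if n_hist < 10_000:
        raise ValueError("n_hist >= 1e4 required for a stable estimate")
    from .distributions import inverse_survival_table

    xs_ie, ys_ie = inverse_survival_table(dist, "interevent")
    xs_re, ys_re = inverse_survival_table(dist, "residual")
    kernel_seed = int(
        np.random.SeedSequence(
            seed.integers(2**31) if isinstance(seed, np.random.Generator) else seed
        ).generate_state(1, np.uint32)[0]
        % 2**31
    )
    est, se = _state0_kernel(
        xs_ie, ys_ie, xs_re, ys_re, float(eta), int(n_hist), kernel_seed
    )
    return (est, se) if return_se else est


def _state0_kernel(xs_ie, ys_ie, xs_re, ys_re, eta, n_hist, seed):
    from numba import njit

    global _state0_kernel_jit
    if "_state0_kernel_jit" not in globals():

        @njit(cache=True)
        def impl(xs_ie, ys_ie, xs_re, ys_re, eta, n_hist, seed):
            np.random.seed(seed)
            a_max = eta * math.log(1e12)
            acc = 0.0
            acc2 = 0.0
            for _ in range(n_hist):
                age = math.exp(
                    np.interp(-math.log(np.random.random()), xs_re, ys_re)
                )
                logp = 0.0
                # histories whose remembered-set probability is already
                # negligible are abandoned early (bursty pasts)
                while age < a_max and logp > -45.0:
                    logp += math.log1p(-math.exp(-age / eta))
                    age += math.exp(
                        np.interp(-math.log(np.random.random()), xs_ie, ys_ie)
                    )
                p0 = math.exp(logp) if logp > -45.0 else 0.0
                acc += p0
                acc2 += p0 * p0
            mean = acc / n_hist
            var = max(acc2 / n_hist - mean * mean, 0.0)
            return mean, math.sqrt(var / n_hist)

        _state0_kernel_jit = impl
    return _state0_kernel_jit(xs_ie, ys_ie, xs_re, ys_re, eta, n_hist, seed)
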