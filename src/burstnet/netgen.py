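"""Static configuration-model skeletons and degree-distribution utilities.

The temporal network runs on top of a static, undirected, simple graph whose
degree sequence is drawn from a prescribed distribution p(k) — by default a
discretized lognormal parameterised by its mean <k> and standard deviation
sigma_k, matching the synthetic experiments.  Wiring uses the erased
configuration model: uniform stub matching followed by removal of self-loops
and parallel edges, with the erased fraction reported (it vanishes as 1/N).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

__all__ = ["DegreeModel", "StaticNetwork", "sample_degrees", "wire", "degree_moments"]

DEGREE_FAMILIES = ("lognormal_discrete", "regular", "poisson", "explicit_pmf")

#: Support cutoff: keep degrees until the continuous CDF reaches 1 - this.
PMF_TRUNCATION = 1e-12


@dataclass(frozen=True)
class DegreeModel:
    """A degree distribution with finite support and exact pmf moments.

    ``mean_k``/``sd_k`` are the *requested* moments; ``pmf_mean``/``pmf_sd``
    are those of the discretized pmf actually sampled from (the small shift
    introduced by rounding and the k >= 1 restriction).  Percolation-side
    computations use the discretized moments for consistency with generated
    networks.
    """

    family: str
    mean_k: float
    sd_k: float
    support: np.ndarray = field(repr=False)
    pmf: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.family not in DEGREE_FAMILIES:
            raise ValueError(f"unknown degree family {self.family!r}")
        if abs(self.pmf.sum() - 1.0) > 1e-9:
            raise ValueError("pmf must sum to 1")

    @property
    def pmf_mean(self) -> float:
        return float(self.support @ self.pmf)

    @property
    def pmf_sd(self) -> float:
        m = self.pmf_mean
        return math.sqrt(max(float((self.support - m) ** 2 @ self.pmf), 0.0))

    @property
    def discretization_shift(self) -> tuple[float, float]:
        """(mean, sd) error of the discretized pmf vs the requested moments."""
        return self.pmf_mean - self.mean_k, self.pmf_sd - self.sd_k

    def truncated(self, cumulative: float) -> "DegreeModel":
        """Restrict support to the smallest k_max with CDF >= ``cumulative``
        and renormalize; used by the master equation's finite state space."""
        cdf = np.cumsum(self.pmf)
        k_idx = int(np.searchsorted(cdf, cumulative))
        k_idx = min(k_idx, len(self.support) - 1)
        sup = self.support[: k_idx + 1]
        pmf = self.pmf[: k_idx + 1] / self.pmf[: k_idx + 1].sum()
        return DegreeModel(self.family, self.mean_k, self.sd_k, sup, pmf)

    # -- constructors -------------------------------------------------------

    @staticmethod
    def lognormal(mean_k: float, sd_k: float) -> "DegreeModel":
        """Discretized lognormal: round the continuous law to the nearest
        integer and condition on k >= 1."""
        if not (mean_k > 0 and sd_k > 0):
            raise ValueError("mean_k and sd_k must be positive")
        s2 = math.log1p((sd_k / mean_k) ** 2)
        s = math.sqrt(s2)
        mu = math.log(mean_k) - s2 / 2
        cont = stats.lognorm(s, scale=math.exp(mu))
        k_max = max(int(math.ceil(cont.isf(PMF_TRUNCATION))) + 1, 3)
        ks = np.arange(1, k_max + 1)
        pmf = cont.cdf(ks + 0.5) - cont.cdf(ks - 0.5)
        pmf = np.clip(pmf, 0.0, None)
        pmf /= pmf.sum()
        return DegreeModel("lognormal_discrete", mean_k, sd_k, ks, pmf)

    @staticmethod
    def regular(z: int) -> "DegreeModel":
        if z < 1:
            raise ValueError("z >= 1 required")
        return DegreeModel("regular", float(z), 0.0, np.array([z]), np.array([1.0]))

    @staticmethod
    def poisson(mean_k: float) -> "DegreeModel":
        law = stats.poisson(mean_k)
        k_max = int(law.isf(PMF_TRUNCATION)) + 1
        ks = np.arange(0, k_max + 1)
        pmf = law.pmf(ks)
        pmf /= pmf.sum()
        return DegreeModel("poisson", mean_k, math.sqrt(mean_k), ks, pmf)

    @staticmethod
    def from_pmf(support, pmf) -> "DegreeModel":
        support = np.asarray(support, dtype=int)
        pmf = np.asarray(pmf, dtype=float)
        pmf = pmf / pmf.sum()
        m = float(support @ pmf)
        sd = math.sqrt(max(float((support - m) ** 2 @ pmf), 0.0))
        return DegreeModel("explicit_pmf", m, sd, support, pmf)


@dataclass(frozen=True)
class StaticNetwork:
    """Simple undirected graph as an edge array plus adjacency in CSR form."""

    n_nodes: int
    edges: np.ndarray  # (n_edges, 2), u < v
    erased_stubs: int = 0

    def __post_init__(self):
        e = self.edges
        if e.size and (np.any(e[:, 0] == e[:, 1])):
            raise ValueError("self-loops are not allowed")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def adjacency_csr(self):
        """(indptr, neighbour indices, incident edge ids) for fast traversal."""
        e = self.edges
        src = np.concatenate([e[:, 0], e[:, 1]])
        dst = np.concatenate([e[:, 1], e[:, 0]])
        eid = np.concatenate([np.arange(len(e)), np.arange(len(e))])
        order = np.argsort(src, kind="stable")
        indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
        np.add.at(indptr, src + 1, 1)
        indptr = np.cumsum(indptr)
        return indptr, dst[order], eid[order]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def write_edgelist(self, path):
        np.savetxt(path, self.edges, fmt="%d")

    @staticmethod
    def read_edgelist(path) -> "StaticNetwork":
        e = np.loadtxt(path, dtype=np.int64, ndmin=2)
        e = np.sort(e, axis=1)
        return StaticNetwork(int(e.max()) + 1, e)


def sample_degrees(model: DegreeModel, n: int, seed=None) -> np.ndarray:
    """Draw N degrees from the pmf; the sum is forced even by incrementing
    one uniformly chosen node's degree when necessary."""
    if n < 2:
        raise ValueError("N >= 2 required")
    rng = np.random.default_rng(seed)
    deg = rng.choice(model.support, size=n, p=model.pmf)
    if deg.sum() % 2 == 1:
        deg[rng.integers(n)] += 1
    return deg.astype(np.int64)


def wire(degrees: np.ndarray, seed=None) -> StaticNetwork:
    """Erased configuration model: uniform stub matching, then self-loops
    and multi-edges removed.  The count of erased stubs is recorded."""
    degrees = np.asarray(degrees, dtype=np.int64)
    total = int(degrees.sum())
    if total % 2 == 1:
        raise ValueError("degree sum must be even")
    rng = np.random.default_rng(seed)
    stubs = np.repeat(np.arange(len(degrees)), degrees)
    rng.shuffle(stubs)
    pairs = stubs.reshape(-1, 2)
    pairs = np.sort(pairs, axis=1)
    keep = pairs[:, 0] != pairs[:, 1]
    pairs = pairs[keep]
    pairs = np.unique(pairs, axis=0)
    erased = total // 2 - len(pairs)
    return StaticNetwork(len(degrees), pairs, erased_stubs=2 * erased)


def degree_moments(model: DegreeModel) -> tuple[float, float]:
    """(<k>, <k(k-1)>) as exact sums over the discretized pmf."""
    k = model.support.astype(float)
    return float(k @ model.pmf), float((k * (k - 1)) @ model.pmf)
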