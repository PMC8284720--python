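"""Global and nodal graph-theory measures on binarized networks.

Conventions (all on undirected, unweighted graphs without self-loops):

* clustering coefficient ``C_i`` — fraction of the node's neighbor pairs
  that are themselves connected; nodes with degree < 2 contribute 0, and
  ``Cp`` is the plain mean over all nodes;
* characteristic path length ``Lp`` — mean shortest-path length over
  *connected* ordered pairs only, which keeps it finite on the partially
  disconnected graphs that low sparsity thresholds produce;
* efficiencies — ``Eglobal`` averages 1/l_ij over all ordered pairs with
  1/inf = 0 for disconnected pairs; ``Elocal`` averages the global
  efficiency of each node's neighbor-induced subgraph (0 when the node has
  fewer than 2 neighbors);
* nodal measures — degree k_i, betweenness b_i with the ordered-pair
  1/((n-1)(n-2)) normalization, and nodal efficiency
  e_i = mean_j 1/l_ij (1/inf = 0);
* small-world indices — gamma = Cp/<Cp_rand>, lambda = Lp/<Lp_rand>,
  sigma = gamma/lambda, where the reference ensemble consists of
  degree-preserving Maslov-Sneppen rewirings of the observed graph
  (10 x K attempted swaps per reference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ._rewire import double_edge_swap
from .network import BinaryGraph

logger = logging.getLogger(__name__)

GraphLike = Union[BinaryGraph, np.ndarray]


@dataclass(frozen=True)
class NodalMetrics:
    """Per-node degree, betweenness centrality, and nodal efficiency."""

    degree: np.ndarray
    betweenness: np.ndarray
    efficiency: np.ndarray

    def to_frame(self, atlas=None):
        import pandas as pd

        idx = atlas.abbreviations if atlas is not None else range(len(self.degree))
        return pd.DataFrame(
            {
                "degree": self.degree,
                "betweenness": self.betweenness,
                "efficiency": self.efficiency,
            },
            index=pd.Index(idx, name="region"),
        )


@dataclass(frozen=True)
class SmallWorldIndex:
    gamma: float
    lambda_: float
    sigma: float


@dataclass(frozen=True)
class GlobalMetrics:
    """All global measures of one binarized network."""

    sparsity: float
    cp: float
    lp: float
    gamma: float
    lambda_: float
    sigma: float
    e_global: float
    e_local: float


def _adj(g: GraphLike) -> np.ndarray:
    a = g.adjacency if isinstance(g, BinaryGraph) else np.asarray(g)
    return a.astype(np.uint8, copy=False)


def _distance_matrix(a: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(a), method="auto", unweighted=True, directed=False)


def clustering_coefficients(g: GraphLike) -> np.ndarray:
    a = _adj(g).astype(float)
    k = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a)  # 2x triangle count per node
    with np.errstate(divide="ignore", invalid="ignore"):
        c = triangles / (k * (k - 1.0))
    c[k < 2] = 0.0
    return c


def _cp_lp(a: np.ndarray, dist: np.ndarray | None = None) -> tuple[float, float]:
    if a.sum() == 0:
        raise ValueError("characteristic path length is undefined for an edgeless graph")
    cp = float(clustering_coefficients(a).mean())
    if dist is None:
        dist = _distance_matrix(a)
    off = ~np.eye(a.shape[0], dtype=bool)
    finite = off & np.isfinite(dist)
    lp = float(dist[finite].mean())
    return cp, lp


def clustering_and_path(g: GraphLike) -> tuple[float, float]:
    """(Cp, Lp); raises on an edgeless graph where Lp is undefined."""
    return _cp_lp(_adj(g))


def _global_efficiency(a: np.ndarray, dist: np.ndarray | None = None) -> float:
    n = a.shape[0]
    if n < 2:
        return 0.0
    if dist is None:
        dist = _distance_matrix(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def efficiencies(g: GraphLike) -> tuple[float, float]:
    """(Eglobal, Elocal); disconnection contributes 1/inf = 0 throughout."""
    a = _adj(g)
    dist = _distance_matrix(a)
    e_global = _global_efficiency(a, dist)
    e_local = 0.0
    for i in range(a.shape[0]):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size >= 2:
            sub = a[np.ix_(nbrs, nbrs)]
            e_local += _global_efficiency(sub)
    e_local /= a.shape[0]
    return e_global, float(e_local)


def nodal_efficiency(g: GraphLike) -> np.ndarray:
    a = _adj(g)
    n = a.shape[0]
    dist = _distance_matrix(a)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def betweenness(g: GraphLike) -> np.ndarray:
    """Normalized betweenness centrality (Brandes algorithm via networkx)."""
    import networkx as nx

    a = _adj(g)
    n = a.shape[0]
    if n < 3:
        return np.zeros(n)
    gx = nx.from_numpy_array(a)
    bc = nx.betweenness_centrality(gx, normalized=True)
    return np.array([bc[i] for i in range(n)])


def nodal_metrics(g: GraphLike) -> NodalMetrics:
    a = _adj(g)
    return NodalMetrics(
        degree=a.sum(axis=1).astype(int),
        betweenness=betweenness(a),
        efficiency=nodal_efficiency(a),
    )


# ---------------------------------------------------------------------------
# degree-preserving null model and small-world indices

def _rewired_adjacency(a: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    iu, ju = np.nonzero(np.triu(a, k=1))
    k = iu.size
    if k < 2:
        raise ValueError("need at least 2 edges to rewire")
    attempts = 10 * k
    e1 = rng.integers(0, k, size=attempts)
    e2 = rng.integers(0, k, size=attempts)
    orient = rng.integers(0, 2, size=attempts).astype(np.uint8)
    out = a.copy()
    double_edge_swap(out, iu.astype(np.int64), ju.astype(np.int64), e1, e2, orient)
    return out


def random_reference(
    g: BinaryGraph,
    rng_seed: int | np.random.Generator | None = None,
) -> BinaryGraph:
    """Degree-matched random graph via Maslov-Sneppen double edge swaps."""
    rng = np.random.default_rng(rng_seed)
    return BinaryGraph(
        atlas=g.atlas,
        adjacency=_rewired_adjacency(g.adjacency, rng),
        sparsity=g.sparsity,
    )


def small_world(
    g: GraphLike,
    n_random: int = 100,
    rng_seed: int | np.random.Generator | None = None,
) -> SmallWorldIndex:
    """gamma, lambda, sigma against ``n_random`` degree-preserving references.

    References whose clustering is exactly zero are excluded from the mean
    (with a logged warning); if all are excluded the indices are undefined.
    """
    a = _adj(g)
    rng = np.random.default_rng(rng_seed)
    cp, lp = _cp_lp(a)
    cp_refs, lp_refs = [], []
    n_excluded = 0
    for _ in range(n_random):
        ref = _rewired_adjacency(a, rng)
        cp_r, lp_r = _cp_lp(ref)
        if cp_r == 0.0:
            n_excluded += 1
            continue
        cp_refs.append(cp_r)
        lp_refs.append(lp_r)
    if n_excluded:
        logger.warning(
            "excluded %d/%d random references with zero clustering", n_excluded, n_random
        )
    if not cp_refs:
        raise ValueError("all random references had zero clustering; sigma undefined")
    gamma = cp / float(np.mean(cp_refs))
    lambda_ = lp / float(np.mean(lp_refs))
    return SmallWorldIndex(gamma=gamma, lambda_=lambda_, sigma=gamma / lambda_)


def global_metrics(
    g: BinaryGraph,
    n_random: int = 100,
    rng_seed: int | np.random.Generator | None = None,
) -> GlobalMetrics:
    """All global measures (Cp, Lp, gamma, lambda, sigma, Eglobal, Elocal)."""
    cp, lp = clustering_and_path(g)
    e_global, e_local = efficiencies(g)
    sw = small_world(g, n_random=n_random, rng_seed=rng_seed)
    return GlobalMetrics(
        sparsity=g.sparsity,
        cp=cp,
        lp=lp,
        gamma=sw.gamma,
        lambda_=sw.lambda_,
        sigma=sw.sigma,
        e_global=e_global,
        e_local=e_local,
    )
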