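"""Inter-subject correlation networks and sparsity-threshold binarization.

The network is built *across subjects*: edge weight (i, j) is the Pearson
correlation between the uptake of regions i and j over the subjects of one
condition.  Binarization keeps the K pairs with the largest |r|, where
K = round(sparsity * N(N-1)/2); ranking by absolute correlation keeps
strong anticorrelations as connections, the usual covariance-network
convention.  Ties at the cutoff are broken lexicographically by
(min index, max index) so that the result is deterministic and the edge
sets of a sparsity sweep are nested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
import numpy as np

from .atlas import RegionAtlas, UptakeTable

EDGE_COUNT_CONVENTIONS = ("unordered_pairs", "half_matrix")


@dataclass
class CorrelationNetwork:
    """Symmetric region x region Pearson matrix; diagonal stored as 0."""

    atlas: RegionAtlas
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = self.atlas.n_regions
        if self.r.shape != (n, n):
            raise ValueError(f"correlation matrix must be {n}x{n}, got {self.r.shape}")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.atlas.n_regions


@dataclass(frozen=True)
class SparsityGrid:
    """Ordered sparsity thresholds; the standard sweep is 0.10-0.50 by 0.01."""

    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) == 0:
            raise ValueError("sparsity grid must not be empty")
        if any(not (0.0 < s <= 1.0) for s in t):
            raise ValueError("sparsity thresholds must lie in (0, 1]")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("sparsity thresholds must be strictly increasing")

    def __len__(self) -> int:
        return len(self.thresholds)

    def __iter__(self):
        return iter(self.thresholds)

    @classmethod
    def default(cls) -> "SparsityGrid":
        return cls(tuple(np.round(np.arange(10, 51) / 100.0, 2)))


@dataclass
class BinaryGraph:
    """Undirected 0/1 adjacency at one sparsity threshold, no self-loops."""

    atlas: RegionAtlas
    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        n = self.atlas.n_regions
        if a.shape != (n, n):
            raise ValueError(f"adjacency must be {n}x{n}, got {a.shape}")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.atlas.n_regions

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


def build_correlation_network(table: UptakeTable) -> CorrelationNetwork:
    """Pearson correlation of every region pair across subjects."""
    if table.n_subjects < 3:
        raise ValueError(
            f"need at least 3 subjects to correlate, got {table.n_subjects}"
        )
    sd = table.values.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = [table.atlas.abbreviations[i] for i in flat]
        raise ValueError(f"zero-variance region column(s): {names}")
    r = np.corrcoef(table.values, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return CorrelationNetwork(atlas=table.atlas, r=r)


def edge_count(n_nodes: int, sparsity: float) -> int:
    """K = round(sparsity * N(N-1)/2), rounding half away from zero."""
    return int(math.floor(sparsity * n_nodes * (n_nodes - 1) / 2.0 + 0.5))


@lru_cache(maxsize=8)
def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def rank_pairs(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All unordered pairs ordered by |r| descending, ties by (i, j) ascending."""
    n = r.shape[0]
    iu, ju = _pair_indices(n)
    order = np.lexsort((ju, iu, -np.abs(r[iu, ju])))
    return iu[order], ju[order]


def _adjacency_from_pairs(n: int, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    a = np.zeros((n, n), dtype=np.uint8)
    a[ii, jj] = 1
    a[jj, ii] = 1
    return a


def binarize_at_sparsity(net: CorrelationNetwork, sparsity: float) -> BinaryGraph:
    """Keep the K strongest |r| pairs at the given sparsity."""
    if not (0.0 < sparsity <= 1.0):
        raise ValueError(f"sparsity must lie in (0, 1], got {sparsity}")
    n = net.n_nodes
    k = edge_count(n, sparsity)
    ii, jj = rank_pairs(net.r)
    return BinaryGraph(
        atlas=net.atlas,
        adjacency=_adjacency_from_pairs(n, ii[:k], jj[:k]),
        sparsity=float(sparsity),
    )


def sweep(net: CorrelationNetwork, grid: SparsityGrid) -> list[BinaryGraph]:
    """One binarized graph per grid threshold; edge sets are nested."""
    if len(grid) == 0:
        raise ValueError("sparsity grid must not be empty")
    n = net.n_nodes
    ii, jj = rank_pairs(net.r)
    graphs = []
    for s in grid:
        k = edge_count(n, s)
        graphs.append(
            BinaryGraph(
                atlas=net.atlas,
                adjacency=_adjacency_from_pairs(n, ii[:k], jj[:k]),
                sparsity=float(s),
            )
        )
    return graphs


def report_edge_count(net: CorrelationNetwork, convention: str = "unordered_pairs") -> int:
    """Total possible edge count under either reporting convention.

    ``unordered_pairs`` is N(N-1)/2 (the count actually used in
    construction); ``half_matrix`` is N^2/2, the convention under which a
    96-node network is reported as having 4,608 edges.
    """
    n = net.n_nodes
    if convention == "unordered_pairs":
        return n * (n - 1) // 2
    if convention == "half_matrix":
        return n * n // 2
    raise ValueError(
        f"convention must be one of {EDGE_COUNT_CONVENTIONS}, got {convention!r}"
    )


# ---------------------------------------------------------------------------
# writers

def write_correlation_csv(net: CorrelationNetwork, path: str | Path) -> None:
    import pandas as pd

    abbr = net.atlas.abbreviations
    pd.DataFrame(net.r, index=abbr, columns=abbr).to_csv(path)


def write_edge_list(graph: BinaryGraph, path: str | Path) -> None:
    abbr = graph.atlas.abbreviations
    ii, jj = np.nonzero(np.triu(graph.adjacency, k=1))
    with open(path, "w") as fh:
        for i, j in zip(ii, jj):
            fh.write(f"{abbr[i]}\t{abbr[j]}\n")


def to_networkx(graph: BinaryGraph):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(graph.atlas.abbreviations)
    abbr = graph.atlas.abbreviations
    ii, jj = np.nonzero(np.triu(graph.adjacency, k=1))
    g.add_edges_from((abbr[i], abbr[j]) for i, j in zip(ii, jj))
    return g


def write_graphml(graph: BinaryGraph, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(graph), path)
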