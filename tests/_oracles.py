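"""Independent brute-force oracles for graph metrics.

Everything here is computed from first principles on the adjacency matrix:
distances and shortest-path counts come from successive matrix powers
((A^d)[i,j] > 0 first at d = distance, and the entry then counts the
shortest paths, since minimal-length walks are simple), clustering from
explicit neighbor-pair enumeration, and betweenness from the path-count
identity sigma_hj(i) = sigma_hi * sigma_ij when d(h,i) + d(i,j) = d(h,j).
No shortest-path library routine is used, so these are valid independent
checks of the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def distances_and_counts(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(distance matrix with inf for disconnected, shortest-path counts)."""
    a = np.asarray(a, dtype=np.int64)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    counts = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(counts, 1)
    power = np.eye(n, dtype=np.int64)
    for d in range(1, n):
        power = power @ a
        newly = np.isinf(dist) & (power > 0)
        dist[newly] = d
        counts[newly] = power[newly]
    return dist, counts


def degrees(a: np.ndarray) -> np.ndarray:
    return np.asarray(a).sum(axis=1)


def clustering_mean(a: np.ndarray) -> float:
    a = np.asarray(a)
    n = a.shape[0]
    cs = []
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = nbrs.size
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(a[u, v] for u, v in itertools.combinations(nbrs, 2))
        cs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cs))


def path_length(a: np.ndarray) -> float:
    dist, _ = distances_and_counts(a)
    n = a.shape[0]
    vals = [dist[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(dist[i, j])]
    return float(np.mean(vals))


def global_efficiency(a: np.ndarray) -> float:
    a = np.asarray(a)
    n = a.shape[0]
    if n < 2:
        return 0.0
    dist, _ = distances_and_counts(a)
    total = sum(
        1.0 / dist[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(dist[i, j])
    )
    return total / (n * (n - 1))


def local_efficiency(a: np.ndarray) -> float:
    a = np.asarray(a)
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size >= 2:
            total += global_efficiency(a[np.ix_(nbrs, nbrs)])
    return total / n


def nodal_efficiency(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    n = a.shape[0]
    dist, _ = distances_and_counts(a)
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(
            1.0 / dist[i, j] for j in range(n) if j != i and np.isfinite(dist[i, j])
        ) / (n - 1)
    return out


def betweenness(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    n = a.shape[0]
    if n < 3:
        return np.zeros(n)
    dist, counts = distances_and_counts(a)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for h in range(n):
            for j in range(n):
                if h == j or h == i or j == i:
                    continue
                if not np.isfinite(dist[h, j]):
                    continue
                if dist[h, i] + dist[i, j] == dist[h, j]:
                    acc += counts[h, i] * counts[i, j] / counts[h, j]
        out[i] = acc / ((n - 1) * (n - 2))
    return out


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the textbook definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        q[idx] = running_min
    return q
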