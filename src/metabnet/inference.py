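"""Permutation inference for pre/post differences in network metrics.

The test mirrors the study design it supports: all subjects from both
conditions are pooled and repeatedly reassigned at random into two groups
of the original sizes; for every reassignment both correlation networks
are rebuilt, binarized across the sparsity grid, and the metric difference
(group 2 minus group 1) is recorded.  Two-sided p-values use the add-one
estimator p = (1 + #{|null| >= |observed|}) / (1 + n_perm), so p is never
zero and is exact under exchangeability.

Multiple comparisons are handled by Benjamini-Hochberg FDR.  The default
family is all nodes within one (metric, threshold) — 96 tests on the
default atlas; global metrics are corrected across thresholds within each
metric.  An AUC summary (trapezoidal area of the metric curve over the
sparsity grid) is available as a single statistic per quantity when a
per-threshold readout is not wanted.

Before drawing reassignments the pooled rows are sorted lexicographically,
which makes p-values bit-identical under any re-ordering of subjects
within their groups; under the null the rows are exchangeable, so this is
statistically a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .atlas import UptakeTable
from .metrics import (
    _cp_lp,
    _distance_matrix,
    _global_efficiency,
    betweenness as _betweenness,
    efficiencies as _efficiencies,
    small_world as _small_world,
)
from .network import SparsityGrid, edge_count, rank_pairs

GLOBAL_METRICS = ("Cp", "Lp", "Eglobal", "Elocal", "gamma", "lambda", "sigma")
NODAL_METRICS = ("degree", "betweenness", "efficiency")
THRESHOLD_SUMMARIES = ("per_threshold", "auc")
FDR_SCOPES = ("nodes_within_metric_threshold", "metric_joint")


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for group-reassignment permutation testing."""

    n_permutations: int = 10_000
    rng_seed: int | None = None
    alpha: float = 0.05
    grid: SparsityGrid = field(default_factory=SparsityGrid.default)
    threshold_summary: str = "per_threshold"
    paired: bool = False
    fdr_scope: str = "nodes_within_metric_threshold"
    n_random_refs: int = 20  # references per graph when testing gamma/lambda/sigma

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.threshold_summary not in THRESHOLD_SUMMARIES:
            raise ValueError(f"threshold_summary must be one of {THRESHOLD_SUMMARIES}")
        if self.fdr_scope not in FDR_SCOPES:
            raise ValueError(f"fdr_scope must be one of {FDR_SCOPES}")


@dataclass
class PermutationResult:
    """One tested quantity: observed difference, p, FDR-q, null summary."""

    metric: str
    threshold: float | None
    node: str | None
    node_index: int | None
    observed_pre: float
    observed_post: float
    observed_diff: float
    p_value: float
    q_value: float | None = None
    null_mean: float = float("nan")
    null_sd: float = float("nan")
    null_quantiles: tuple[float, float, float] = (float("nan"),) * 3

    @property
    def quantity(self) -> str:
        parts = [self.metric]
        if self.node is not None:
            parts.append(f"[{self.node}]")
        if self.threshold is not None:
            parts.append(f"@{self.threshold:g}")
        return "".join(parts)

    def significant(self, alpha: float = 0.05) -> bool:
        q = self.q_value if self.q_value is not None else self.p_value
        return q <= alpha


def _corr(values: np.ndarray) -> np.ndarray:
    z = values - values.mean(axis=0)
    sd = z.std(axis=0)
    sd[sd == 0] = np.nan  # degenerate columns yield nan r, never selected as nan sorts last
    z = z / sd
    r = (z.T @ z) / values.shape[0]
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return r


def _metric_values(
    values: np.ndarray,
    thresholds: Sequence[float],
    metrics: Sequence[str],
    n_random_refs: int,
    rng: np.random.Generator,
) -> dict[tuple[str, float], np.ndarray | float]:
    """Metric value(s) for one group at every threshold.

    Nodal metrics map to a length-N vector, global metrics to a scalar.
    """
    r = _corr(values)
    n = r.shape[0]
    ii, jj = rank_pairs(r)
    need_adj = any(m != "degree" for m in metrics)
    need_dist = any(m in ("Lp", "Eglobal", "efficiency") for m in metrics)
    need_sw = any(m in ("gamma", "lambda", "sigma") for m in metrics)
    out: dict[tuple[str, float], np.ndarray | float] = {}
    for s in thresholds:
        k = edge_count(n, s)
        si, sj = ii[:k], jj[:k]
        if "degree" in metrics:
            deg = np.bincount(si, minlength=n) + np.bincount(sj, minlength=n)
            out[("degree", s)] = deg.astype(float)
        if not need_adj:
            continue
        a = np.zeros((n, n), dtype=np.uint8)
        a[si, sj] = 1
        a[sj, si] = 1
        dist = _distance_matrix(a) if need_dist else None
        if "Cp" in metrics or "Lp" in metrics:
            cp, lp = _cp_lp(a, dist)
            if "Cp" in metrics:
                out[("Cp", s)] = cp
            if "Lp" in metrics:
                out[("Lp", s)] = lp
        if "Eglobal" in metrics:
            out[("Eglobal", s)] = _global_efficiency(a, dist)
        if "Elocal" in metrics:
            out[("Elocal", s)] = _efficiencies(a)[1]
        if "efficiency" in metrics:
            with np.errstate(divide="ignore"):
                inv = 1.0 / dist
            inv[~np.isfinite(inv)] = 0.0
            np.fill_diagonal(inv, 0.0)
            out[("efficiency", s)] = inv.sum(axis=1) / (n - 1)
        if "betweenness" in metrics:
            out[("betweenness", s)] = _betweenness(a)
        if need_sw:
            sw = _small_world(a, n_random=n_random_refs, rng_seed=rng)
            if "gamma" in metrics:
                out[("gamma", s)] = sw.gamma
            if "lambda" in metrics:
                out[("lambda", s)] = sw.lambda_
            if "sigma" in metrics:
                out[("sigma", s)] = sw.sigma
    return out


def _canonical_rows(values: np.ndarray) -> np.ndarray:
    """Rows sorted lexicographically — a canonical order for the pooled sample."""
    order = np.lexsort(values.T[::-1])
    return values[order]


def _summarize(
    observed: dict, thresholds, summary: str
) -> tuple[dict, list[tuple[str, float | None]]]:
    """Optionally collapse per-threshold curves to a trapezoidal AUC."""
    if summary == "per_threshold":
        return observed, [(m, s) for (m, s) in observed.keys()]
    metrics = sorted({m for (m, _s) in observed.keys()})
    x = np.asarray(thresholds, dtype=float)
    collapsed = {}
    for m in metrics:
        curve = np.stack([np.atleast_1d(np.asarray(observed[(m, s)], dtype=float)) for s in thresholds])
        auc = np.trapezoid(curve, x=x, axis=0)
        collapsed[(m, None)] = auc if auc.size > 1 else float(auc[0])
    return collapsed, list(collapsed.keys())


def permutation_test(
    pre: UptakeTable,
    post: UptakeTable,
    metrics: Sequence[str] = NODAL_METRICS,
    cfg: PermutationConfig | None = None,
) -> list[PermutationResult]:
    """Test post-minus-pre differences of network metrics by permutation.

    Returns one :class:`PermutationResult` per (metric, threshold[, node])
    quantity, with BH q-values attached according to ``cfg.fdr_scope``.
    """
    cfg = cfg if cfg is not None else PermutationConfig()
    if pre.atlas != post.atlas:
        raise ValueError("pre and post tables must share the same atlas")
    unknown = [m for m in metrics if m not in GLOBAL_METRICS + NODAL_METRICS]
    if unknown:
        raise ValueError(f"unknown metrics: {unknown}")
    n1, n2 = pre.n_subjects, post.n_subjects
    if min(n1, n2) < 3:
        raise ValueError("each group must contain at least 3 subjects")
    if cfg.paired and n1 != n2:
        raise ValueError("paired permutation requires equal group sizes")

    thresholds = list(cfg.grid)
    rng = np.random.default_rng(cfg.rng_seed)

    obs_pre = _metric_values(pre.values, thresholds, metrics, cfg.n_random_refs, rng)
    obs_post = _metric_values(post.values, thresholds, metrics, cfg.n_random_refs, rng)
    obs_pre, keys = _summarize(obs_pre, thresholds, cfg.threshold_summary)
    obs_post, _ = _summarize(obs_post, thresholds, cfg.threshold_summary)

    if cfg.paired:
        pair_key = np.hstack([pre.values, post.values])
        order = np.lexsort(pair_key.T[::-1])
        pre_rows, post_rows = pre.values[order], post.values[order]
    else:
        pooled = _canonical_rows(np.vstack([pre.values, post.values]))

    # null difference arrays, one row per permutation
    nulls = {
        key: np.empty(
            (cfg.n_permutations,) + np.shape(np.atleast_1d(obs_pre[key])),
            dtype=np.float32,
        )
        for key in keys
    }
    for t in range(cfg.n_permutations):
        if cfg.paired:
            flip = rng.integers(0, 2, size=n1).astype(bool)
            g1 = np.where(flip[:, None], post_rows, pre_rows)
            g2 = np.where(flip[:, None], pre_rows, post_rows)
        else:
            perm = rng.permutation(n1 + n2)
            g1, g2 = pooled[perm[:n1]], pooled[perm[n1:]]
        m1 = _metric_values(g1, thresholds, metrics, cfg.n_random_refs, rng)
        m2 = _metric_values(g2, thresholds, metrics, cfg.n_random_refs, rng)
        m1, _ = _summarize(m1, thresholds, cfg.threshold_summary)
        m2, _ = _summarize(m2, thresholds, cfg.threshold_summary)
        for key in keys:
            nulls[key][t] = np.atleast_1d(
                np.asarray(m2[key], dtype=float) - np.asarray(m1[key], dtype=float)
            )

    abbrs = pre.atlas.abbreviations
    results: list[PermutationResult] = []
    for metric, thr in keys:
        o_pre = np.atleast_1d(np.asarray(obs_pre[(metric, thr)], dtype=float))
        o_post = np.atleast_1d(np.asarray(obs_post[(metric, thr)], dtype=float))
        diff = o_post - o_pre
        null = nulls[(metric, thr)].astype(float)
        exceed = (np.abs(null) >= np.abs(diff)[None, :]).sum(axis=0)
        p = (1.0 + exceed) / (1.0 + cfg.n_permutations)
        qlo, qmed, qhi = np.quantile(null, [0.025, 0.5, 0.975], axis=0)
        nodal = metric in NODAL_METRICS
        for idx in range(diff.size):
            results.append(
                PermutationResult(
                    metric=metric,
                    threshold=thr,
                    node=abbrs[idx] if nodal else None,
                    node_index=idx if nodal else None,
                    observed_pre=float(o_pre[idx]),
                    observed_post=float(o_post[idx]),
                    observed_diff=float(diff[idx]),
                    p_value=float(p[idx]),
                    null_mean=float(null[:, idx].mean()),
                    null_sd=float(null[:, idx].std(ddof=1)) if cfg.n_permutations > 1 else 0.0,
                    null_quantiles=(float(qlo[idx]), float(qmed[idx]), float(qhi[idx])),
                )
            )
    _apply_fdr(results, cfg)
    return results


def _apply_fdr(results: list[PermutationResult], cfg: PermutationConfig) -> None:
    if cfg.fdr_scope == "metric_joint":
        group_of = lambda r: r.metric  # noqa: E731
    else:
        # nodal: across nodes within (metric, threshold); global: across
        # thresholds within metric
        group_of = lambda r: (r.metric, r.threshold if r.node is not None else None)  # noqa: E731
    groups: dict = {}
    for r in results:
        groups.setdefault(group_of(r), []).append(r)
    for members in groups.values():
        q, _sig = fdr_bh(np.array([r.p_value for r in members]), cfg.alpha)
        for r, qv in zip(members, q):
            r.q_value = float(qv)


def fdr_bh(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (q_values, significant mask)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    _reject, q, _a1, _a2 = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


def select_seeds(
    nodal_results: Iterable[PermutationResult],
    alpha: float = 0.05,
) -> list[str]:
    """Regions FDR-significant in at least one nodal metric, in atlas order."""
    hits: dict[int, str] = {}
    for r in nodal_results:
        if r.node is None or r.q_value is None:
            continue
        if r.q_value <= alpha:
            hits[r.node_index] = r.node
    return [hits[i] for i in sorted(hits)]


def results_to_frame(results: Sequence[PermutationResult], alpha: float = 0.05):
    import pandas as pd

    return pd.DataFrame(
        {
            "quantity": [r.quantity for r in results],
            "metric": [r.metric for r in results],
            "threshold": [r.threshold for r in results],
            "node": [r.node for r in results],
            "observed_pre": [r.observed_pre for r in results],
            "observed_post": [r.observed_post for r in results],
            "diff": [r.observed_diff for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "significant": [r.significant(alpha) for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
        }
    )
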