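"""Synthetic two-condition uptake data with a controllable covariance graph.

The generator emulates the study design every stage of the pipeline is
built for: two conditions (pre/post) x 32 subjects x 96 regions.  Each
subject row is built from a latent-factor model

    x = 1 + (L f + noise_sd * eps) / (5 * s_max),

where ``f`` are independent standard-normal latent factors, ``L`` is a
loading matrix derived from the chosen covariance structure, and ``s_max``
is the largest regional standard deviation of the latent part.  Dividing
by ``5 * s_max`` (rather than truncating) keeps every value positive with
overwhelming probability while preserving the Gaussian correlation
structure exactly; column means sit at 1.0, the whole-brain-normalized
scale, with a regional coefficient of variation of about 20%.

Structures:

* ``modular`` — regions partitioned into ``n_modules`` blocks, one shared
  factor per block with loading ``a``; within-module population
  correlation is a^2 / (a^2 + noise_sd^2) (0.5 at the defaults).
* ``small_world`` — one factor per region, each region loading equally on
  the factors of its closed neighborhood in a ring-lattice-with-shortcuts
  (Watts-Strogatz) graph; neighborhood overlap then makes the population
  correlation decay with lattice distance, so the binarized empirical
  network inherits the small-world regime of the ground-truth graph.
* ``unstructured`` — pure noise (all population correlations zero).

Planted effects: in the post condition each designated seed region gains a
new latent factor shared with its designated targets, with loading
``effect_delta``.  This raises seed-target (and target-target)
correlations by delta^2 against an otherwise identical model, making
"planted connectivity increase" a single interpretable knob.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .atlas import Region, RegionAtlas, UptakeTable
from .network import BinaryGraph

STRUCTURES = ("modular", "small_world", "unstructured")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic generator.

    Defaults mirror the emulated design (96 regions, 32 subjects per
    condition) with a within-module population correlation of 0.5 and a
    regional CV of ~20% — representative of rodent FDG covariance data.
    """

    n_regions: int = 96
    n_subjects: int = 32
    structure: str = "modular"
    n_modules: int = 8
    ws_neighbors: int = 10  # ring-lattice degree of the small-world structure
    ws_rewire_p: float = 0.1  # shortcut probability
    loading: float = 0.3  # latent loading a
    noise_sd: float = 0.3
    planted_seeds: tuple[str, ...] = ()
    planted_targets: tuple[tuple[str, ...], ...] = ()
    effect_delta: float = 0.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}")
        if self.n_regions < 2 or self.n_subjects < 3:
            raise ValueError("need at least 2 regions and 3 subjects")
        if self.effect_delta < 0:
            raise ValueError("effect_delta must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if len(self.planted_seeds) != len(self.planted_targets):
            raise ValueError("planted_targets must list one target tuple per seed")


def _atlas_for(cfg: GeneratorConfig) -> RegionAtlas:
    if cfg.n_regions == 96:
        return RegionAtlas.default()
    return RegionAtlas(
        Region(i + 1, f"synthetic region {i + 1:03d}", f"R{i + 1:03d}", "midline")
        for i in range(cfg.n_regions)
    )


def _ws_graph(cfg: GeneratorConfig, seed: int):
    import networkx as nx

    return nx.watts_strogatz_graph(
        cfg.n_regions, cfg.ws_neighbors, cfg.ws_rewire_p, seed=seed
    )


def _base_loadings(cfg: GeneratorConfig, ws_seed: int) -> tuple[np.ndarray, object]:
    """(N x F loading matrix, optional ground-truth graph)."""
    n = cfg.n_regions
    if cfg.structure == "modular":
        L = np.zeros((n, cfg.n_modules))
        module = np.arange(n) % cfg.n_modules
        L[np.arange(n), module] = cfg.loading
        return L, None
    if cfg.structure == "small_world":
        g = _ws_graph(cfg, ws_seed)
        L = np.zeros((n, n))
        for i in range(n):
            closed = [i] + sorted(g.neighbors(i))
            L[i, closed] = cfg.loading / np.sqrt(len(closed))
        return L, g
    return np.zeros((n, 0)), None


def _planted_loadings(cfg: GeneratorConfig, atlas: RegionAtlas) -> np.ndarray:
    """Extra post-condition columns: one shared factor per planted seed."""
    cols = []
    n = cfg.n_regions
    for seed, targets in zip(cfg.planted_seeds, cfg.planted_targets):
        col = np.zeros(n)
        col[atlas.index_of(seed)] = cfg.effect_delta
        for t in targets:
            col[atlas.index_of(t)] = cfg.effect_delta
        cols.append(col)
    if not cols:
        return np.zeros((n, 0))
    return np.column_stack(cols)


def _sample(
    L: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator, scale_sd: float
) -> np.ndarray:
    f = rng.standard_normal((cfg.n_subjects, L.shape[1]))
    eps = rng.standard_normal((cfg.n_subjects, cfg.n_regions))
    latent = f @ L.T + cfg.noise_sd * eps
    values = 1.0 + latent / (5.0 * scale_sd)
    if np.any(values <= 0):
        raise ValueError("generator produced non-positive uptake; reduce loadings/noise")
    return values


def _build(cfg: GeneratorConfig):
    rng = np.random.default_rng(cfg.rng_seed)
    ws_seed = int(rng.integers(2**31))
    atlas = _atlas_for(cfg)
    L_pre, truth = _base_loadings(cfg, ws_seed)
    L_post = np.hstack([L_pre, _planted_loadings(cfg, atlas)])
    # shared positivity scale so pre and post live on the same axis
    scale_sd = float(np.sqrt((L_post**2).sum(axis=1) + cfg.noise_sd**2).max())
    subjects = tuple(f"rat{i + 1:02d}" for i in range(cfg.n_subjects))
    pre = UptakeTable("pre", subjects, _sample(L_pre, cfg, rng, scale_sd), atlas)
    post = UptakeTable("post", subjects, _sample(L_post, cfg, rng, scale_sd), atlas)
    return pre, post, truth, atlas


def generate_pair(cfg: GeneratorConfig) -> tuple[UptakeTable, UptakeTable]:
    """Draw (pre, post) tables; identical model when ``effect_delta`` is 0."""
    pre, post, _truth, _atlas = _build(cfg)
    return pre, post


def generate_small_world_truth(
    cfg: GeneratorConfig,
) -> tuple[UptakeTable, UptakeTable, BinaryGraph]:
    """(pre, post, ground-truth graph) for the small-world structure."""
    if cfg.structure != "small_world":
        raise ValueError("generate_small_world_truth requires structure='small_world'")
    pre, post, truth, atlas = _build(cfg)
    n = cfg.n_regions
    adj = np.zeros((n, n), dtype=np.uint8)
    for i, j in truth.edges:
        adj[i, j] = 1
        adj[j, i] = 1
    sparsity = truth.number_of_edges() / (n * (n - 1) / 2)
    return pre, post, BinaryGraph(atlas=atlas, adjacency=adj, sparsity=sparsity)


def population_correlation(cfg: GeneratorConfig, condition: str = "pre") -> np.ndarray:
    """The model's exact correlation matrix for one condition.

    Correlations are invariant to the affine positivity transform, so this
    is computed directly from Sigma = L L^T + noise_sd^2 I.
    """
    if condition not in ("pre", "post"):
        raise ValueError("condition must be 'pre' or 'post'")
    rng = np.random.default_rng(cfg.rng_seed)
    ws_seed = int(rng.integers(2**31))
    atlas = _atlas_for(cfg)
    L, _ = _base_loadings(cfg, ws_seed)
    if condition == "post":
        L = np.hstack([L, _planted_loadings(cfg, atlas)])
    sigma = L @ L.T + cfg.noise_sd**2 * np.eye(cfg.n_regions)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def write_simulation(cfg: GeneratorConfig, out_dir: str | Path) -> dict:
    """Write pre/post CSV tables plus a ground-truth JSON manifest."""
    from .atlas import write_uptake_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pre, post = generate_pair(cfg)
    write_uptake_table(pre, out / "pre.csv")
    write_uptake_table(post, out / "post.csv")
    manifest = {
        "n_regions": cfg.n_regions,
        "n_subjects_per_condition": cfg.n_subjects,
        "structure": cfg.structure,
        "loading": cfg.loading,
        "noise_sd": cfg.noise_sd,
        "planted_seeds": list(cfg.planted_seeds),
        "planted_targets": [list(t) for t in cfg.planted_targets],
        "effect_delta": cfg.effect_delta,
        "rng_seed": cfg.rng_seed,
        "files": {"pre": "pre.csv", "post": "post.csv"},
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
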