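# Methods

This note documents the statistical model behind `metabnet`, the
conventions and numerical choices baked into each stage, what the
synthetic-data generator does and does not emulate, and the package's
known limitations.

## The inter-subject covariance network

Let `X` be the subjects × regions matrix of whole-brain-normalized
uptake (SUV ratio) for one condition. The network on N regions has edge
weights `r_ij = corr(X[:, i], X[:, j])` across subjects. This is a
*group-level* object: one network per condition, not per animal, which
is why group comparison requires permutation over subjects rather than
any per-subject statistic.

**Whole-brain normalization.** Regional means are divided by the
voxel-count-weighted mean over all labeled voxels (equivalently, the
mean of the raw image restricted to the atlas mask). The weighted mean
of the normalized values is exactly 1, and the output is invariant to
global rescaling of the image (e.g., injected dose). Non-atlas tissue is
excluded from "whole brain"; with a whole-brain parcellation the
difference is negligible and the labeled-voxel definition is the
reproducible one.

**Binarization.** At sparsity s the K = round(s·N(N−1)/2) unordered
pairs with the largest |r| become edges (round = half away from zero,
so the edge count is an exact, testable function of s). Ranking uses
the *absolute* correlation: strong anticorrelations are structure, and
dropping them would make results depend on arbitrary sign conventions;
the signed r is retained for the seed analysis. Ties at the cutoff are
broken lexicographically by (min index, max index) — determinism across
platforms — and because the ranking is a fixed total order, the edge
sets of a sparsity sweep are always nested. The diagonal never
participates. On 96 nodes there are 4,560 unordered pairs; the
`half_matrix` reporting convention (N²/2 = 4,608) is exposed for
comparability with the printed literature value but is never used in
construction.

## Graph measures

All measures are for undirected, unweighted graphs without self-loops.

- `C_i` = fraction of a node's neighbor pairs that are connected;
  nodes with degree < 2 contribute C_i = 0 (an explicit convention, not
  an exclusion). `Cp` is the unweighted mean over nodes.
- `Lp` = mean shortest-path length over *connected ordered pairs only*.
  Graphs at the sparse end of the sweep are routinely disconnected;
  restricting to connected pairs keeps Lp finite, while the
  efficiency-based measures encode disconnection via 1/∞ = 0.
- `Eglobal` = mean of 1/l_ij over all ordered pairs (1/∞ = 0);
  `Elocal` = mean over nodes of Eglobal of the neighbor-induced
  subgraph, 0 for nodes with < 2 neighbors.
- Nodal: degree k_i; betweenness b_i with the ordered-pair
  1/((n−1)(n−2)) normalization (Brandes algorithm); nodal efficiency
  e_i = mean_j 1/l_ij, whose node-average equals Eglobal exactly.
- Small-world indices: γ = Cp/⟨Cp_rand⟩, λ = Lp/⟨Lp_rand⟩, σ = γ/λ.

**Null model.** "Random networks" are degree-preserving Maslov–Sneppen
rewirings of the observed graph: 10 × K attempted double-edge swaps per
reference, 100 references by default (20 in the routine test suite;
estimates of ⟨Cp_rand⟩ and ⟨Lp_rand⟩ are means over references, so the
reference count affects only Monte-Carlo error, not location). Swaps
that would create self-loops or duplicate edges are rejected, which
preserves the degree sequence exactly. References with zero clustering
are excluded from the means with a logged warning (γ would otherwise be
undefined); this only occurs for near-tree graphs far sparser than the
10–50 % sweep. The kernel is JIT-compiled and driven by a
`numpy.random.Generator`, so references are reproducible per seed.

Shortest paths use breadth-first search (`scipy.sparse.csgraph`);
clustering uses the diag(A³) triangle count. All seven measures are
verified in the test suite against an independent matrix-power
path-enumeration oracle to 1e-12 on every connected graph with ≤ 7
nodes and on random graphs with ≤ 12 nodes.

## Permutation inference

Pre/post differences are tested by pooling all subjects and repeatedly
reassigning them at random into two groups of the original sizes,
rebuilding both networks and recomputing the metric(s) at every
threshold per reassignment. The unpaired reassignment deliberately
mirrors the original study design even though the underlying animals
are repeated-measures; a paired mode (condition-label flips within
subject) is available via `PermutationConfig(paired=True)`.

- Two-sided add-one estimator: p = (1 + #{|null| ≥ |obs|})/(1 + n_perm).
  Never zero, exact under exchangeability.
- Before drawing reassignments the pooled rows are sorted
  lexicographically. Under the null the rows are exchangeable, so this
  changes nothing statistically, but it makes p-values bit-identical
  under re-ordering of subjects within groups — a useful reproducibility
  contract.
- FDR (Benjamini–Hochberg, via statsmodels): the default family is all
  nodes within one (metric, threshold) — 96 tests on the default atlas.
  Global metrics are corrected across thresholds within each metric.
  The family is configurable (`fdr_scope="metric_joint"` corrects a
  metric's full node × threshold grid jointly) because the original
  report does not state how its 41 thresholds were combined; an AUC
  summary (trapezoidal area of the metric curve over the sweep) is the
  other supported way to collapse the sweep into one test.
- Seed regions for the connectivity analysis default to the FDR
  survivors of the nodal tests (significant in ≥ 1 nodal metric,
  deduplicated, atlas order); the published four-seed set is a preset.
- Seed connectivity change is tested per target with the Fisher-z
  difference Δz = atanh(r_post) − atanh(r_pre) (variance-stabilized,
  symmetric in r; |r| is clipped at 0.999999 before atanh with a logged
  warning). Per-target significance defaults to uncorrected p ≤ 0.05,
  matching the stated level of the original seed analysis; BH across
  the 95 targets is optional.

The degree statistic is integer-valued, so the two-sided permutation
p-value is mildly conservative under ties; the measured type-I error at
the 0.05 level is ≈ 0.04 (see the acceptance suite), inside the
Monte-Carlo band [0.03, 0.07].

## Synthetic-data generator

Each subject row is `x = 1 + (L f + noise_sd · ε)/(5 · s_max)` with
standard-normal latent factors `f` and noise `ε`, where `s_max` is the
largest latent standard deviation across regions. Dividing by `5·s_max`
(rather than truncating) keeps values positive with probability
~1 − 3e-7 per value while preserving the Gaussian correlation structure
exactly; column means sit at 1.0 (the whole-brain-normalized scale)
with a regional CV of ≈ 20 %. The generator raises on the rare
non-positive draw; replicate-sweep helpers redraw such datasets from a
fresh substream (a negligible conditioning on all-positive output).

Structures for the base loading matrix `L`:

- **modular** (default): `n_modules = 8` equal blocks, one shared factor
  per block with loading a = 0.3 against noise_sd = 0.3, giving a
  within-module population correlation a²/(a² + σ²) = 0.5 — a typical
  magnitude for reported rodent metabolic covariance — and zero
  correlation across modules.
- **small_world**: one factor per region; each region loads
  a/√|N̄(i)| on the factors of its closed neighborhood N̄(i) in a
  Watts–Strogatz graph (k = 10, rewiring p = 0.1, the canonical
  small-world regime). Neighborhood overlap makes the population
  correlation decay with lattice distance, so the thresholded empirical
  network inherits the ground-truth graph's small-world organization;
  `generate_small_world_truth` also returns that graph.
- **unstructured**: pure noise.

**Planted effects.** In the post condition each designated seed gains a
new factor shared with its designated targets, loading `effect_delta`.
This raises every within-set correlation by δ² (before renormalization)
and is the single knob for "connectivity increase".

**What the generator does not emulate.** Independent draws per
condition (no rat-level repeated-measures correlation between pre and
post — matching the unpaired default analysis, and required for the
unpaired permutation test to be exactly calibrated on generator data);
no voxel-level image formation, scanner noise, partial-volume effects,
or physiological covariates. Passing tests on this generator validate
the statistical machinery, not PET physics.

Two finite-sample phenomena discovered while validating are worth
knowing about:

1. **Noise floor of σ.** Graphs thresholded from pure sample-correlation
   noise are *not* Erdős–Rényi: sample correlation matrices have
   intrinsic transitivity, so at n = 32 the small-world scalar of a
   structureless correlation network sits near 1.3, not 1.0, regardless
   of noise amplitude. σ ≈ 1 should not be used as a "no structure"
   baseline for correlation networks at this sample size.
2. **Degree changes are nearly zero-sum.** A planted factor inflates
   the planted nodes' variance, which dilutes their pre-existing
   correlations; with fixed-K binarization the nodes lose roughly as
   many incidental edges as they gain planted ones, and the sampling
   noise of Pearson r at n = 32 (sd ≈ 0.18) keeps the null
   degree-difference sd near 5 edges. A δ = 0.5 effect on 8 targets
   (≈ +8 edges naively) therefore cannot reach 96-test FDR
   significance at this sample size under any parameterization we
   found — the nodal-degree route is far less sensitive than the
   seed-connectivity route, whose Fisher-z statistic detects the same
   effect reliably. The corresponding acceptance test records this
   expectation gap rather than papering over it.

## Problem sizes and defaults

Default analysis scale mirrors the emulated study: 96 regions,
32 subjects per condition, 41 thresholds, 100 random references,
10,000 permutations (`PermutationConfig`). The routine test suite and
the acceptance script run reduced but structurally identical versions
(20 references for sweep-wide σ checks; 200 replicates × 500
permutations for calibration), chosen so the whole validation runs in
minutes on one core; reference counts and permutation counts affect
Monte-Carlo error only.

## Limitations

- Binary graphs only; no weighted metrics, modularity, rich-club, or
  network-based-statistic cluster inference.
- ROI extraction expects already-registered volumes; spatial
  normalization, reslicing, and smoothing are upstream concerns.
- The permutation test treats subjects as exchangeable under the null;
  with real repeated-measures data the unpaired default is valid but
  conservative, and the paired mode requires matched subject order.
- Betweenness is exactly zero for many nodes in dense graphs, making
  its permutation null heavily tied and its test conservative — one
  plausible reason nodal betweenness differences are rarely detected.
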