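"""Permutation testing, BH FDR, and seed selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import _oracles as oracle
from metabnet import (
    GeneratorConfig,
    PermutationConfig,
    fdr_bh,
    generate_pair,
    permutation_test,
    select_seeds,
)
from metabnet.inference import PermutationResult, results_to_frame
from metabnet.network import SparsityGrid

GRID15 = SparsityGrid((0.15,))


@pytest.fixture(scope="module")
def small_pair():
    cfg = GeneratorConfig(n_subjects=12, rng_seed=31)
    return generate_pair(cfg)


class TestPermutationTest:
    def test_identical_tables_give_zero_diff_and_p_one(self, small_pair):
        pre, _ = small_pair
        post = type(pre)("post", pre.subject_ids, pre.values.copy(), pre.atlas)
        results = permutation_test(
            pre, post, metrics=("degree",),
            cfg=PermutationConfig(n_permutations=25, rng_seed=0, grid=GRID15),
        )
        assert all(r.observed_diff == 0.0 for r in results)
        assert all(r.p_value == 1.0 for r in results)

    def test_fixed_seed_reproduces_p_values_exactly(self, small_pair):
        pre, post = small_pair
        cfg = PermutationConfig(n_permutations=50, rng_seed=7, grid=GRID15)
        p1 = [r.p_value for r in permutation_test(pre, post, ("degree",), cfg)]
        p2 = [r.p_value for r in permutation_test(pre, post, ("degree",), cfg)]
        assert p1 == p2

    def test_p_values_invariant_to_subject_order_within_groups(self, small_pair):
        pre, post = small_pair
        cfg = PermutationConfig(n_permutations=50, rng_seed=3, grid=GRID15)
        base = [r.p_value for r in permutation_test(pre, post, ("degree",), cfg)]
        rng = np.random.default_rng(0)
        order = rng.permutation(pre.n_subjects)
        shuffled = type(pre)(
            "pre",
            tuple(pre.subject_ids[i] for i in order),
            pre.values[order],
            pre.atlas,
        )
        again = [r.p_value for r in permutation_test(shuffled, post, ("degree",), cfg)]
        assert base == again

    def test_global_and_nodal_quantities_are_emitted(self, small_pair):
        pre, post = small_pair
        cfg = PermutationConfig(n_permutations=10, rng_seed=1, grid=SparsityGrid((0.15, 0.30)))
        results = permutation_test(pre, post, ("Cp", "Lp", "degree"), cfg)
        by_metric = {}
        for r in results:
            by_metric.setdefault(r.metric, []).append(r)
        assert len(by_metric["Cp"]) == 2  # one per threshold
        assert len(by_metric["degree"]) == 2 * 96
        assert all(r.node is None for r in by_metric["Lp"])
        assert all(r.node is not None for r in by_metric["degree"])
        frame = results_to_frame(results)
        assert len(frame) == len(results)

    def test_auc_summary_collapses_thresholds(self, small_pair):
        pre, post = small_pair
        cfg = PermutationConfig(
            n_permutations=10, rng_seed=1,
            grid=SparsityGrid((0.15, 0.20, 0.25)), threshold_summary="auc",
        )
        results = permutation_test(pre, post, ("degree",), cfg)
        assert len(results) == 96
        assert all(r.threshold is None for r in results)

    def test_add_one_estimator_bounds(self, small_pair):
        pre, post = small_pair
        n_perm = 40
        results = permutation_test(
            pre, post, ("degree",),
            PermutationConfig(n_permutations=n_perm, rng_seed=2, grid=GRID15),
        )
        p = np.array([r.p_value for r in results])
        assert np.all(p >= 1 / (n_perm + 1))
        assert np.all(p <= 1.0)

    def test_too_small_groups_rejected(self, tiny_atlas, make_table):
        values = np.ones((2, 4)) + np.arange(8).reshape(2, 4)
        pre = make_table(values, tiny_atlas, "pre")
        post = make_table(values + 0.1, tiny_atlas, "post")
        with pytest.raises(ValueError, match="3 subjects"):
            permutation_test(pre, post, ("degree",), PermutationConfig(n_permutations=5, grid=GRID15))

    def test_unknown_metric_rejected(self, small_pair):
        pre, post = small_pair
        with pytest.raises(ValueError, match="unknown metrics"):
            permutation_test(pre, post, ("modularity",))

    def test_paired_mode_requires_equal_sizes(self, small_pair):
        pre, post = small_pair
        shorter = type(pre)("post", post.subject_ids[:-1], post.values[:-1], post.atlas)
        with pytest.raises(ValueError, match="paired"):
            permutation_test(
                pre, shorter, ("degree",),
                PermutationConfig(n_permutations=5, paired=True, grid=GRID15),
            )

    def test_paired_mode_runs_and_is_deterministic(self, small_pair):
        pre, post = small_pair
        cfg = PermutationConfig(n_permutations=30, rng_seed=5, paired=True, grid=GRID15)
        p1 = [r.p_value for r in permutation_test(pre, post, ("degree",), cfg)]
        p2 = [r.p_value for r in permutation_test(pre, post, ("degree",), cfg)]
        assert p1 == p2


class TestFdrBH:
    def test_hand_computed_step_up(self):
        q, sig = fdr_bh(np.array([0.01, 0.02, 0.03, 0.50]), alpha=0.05)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.50])
        assert sig.tolist() == [True, True, True, False]

    def test_all_ones_nothing_significant(self):
        q, sig = fdr_bh(np.ones(10))
        np.testing.assert_allclose(q, 1.0)
        assert not sig.any()

    def test_uniform_strong_signal_all_significant(self):
        q, sig = fdr_bh(np.full(10, 0.001))
        np.testing.assert_allclose(q, 0.001)
        assert sig.all()

    def test_empty_input_gives_empty_output(self):
        q, sig = fdr_bh(np.array([]))
        assert q.size == 0 and sig.size == 0

    def test_invalid_p_values_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.0, 0.5]))

    @given(
        st.lists(st.floats(1e-6, 1.0, exclude_min=False), min_size=1, max_size=20)
    )
    def test_matches_bruteforce_definition(self, p_list):
        p = np.array(p_list)
        q, _ = fdr_bh(p)
        np.testing.assert_allclose(q, oracle.bh_qvalues(p), atol=1e-12)
        assert np.all(q >= p - 1e-12)  # BH never decreases a p-value


def _nodal_result(metric, node, node_index, q):
    return PermutationResult(
        metric=metric, threshold=0.15, node=node, node_index=node_index,
        observed_pre=0.0, observed_post=0.0, observed_diff=0.0,
        p_value=q, q_value=q,
    )


class TestSelectSeeds:
    def test_no_significant_nodes_gives_empty_list(self):
        results = [_nodal_result("degree", "A", 0, 0.9)]
        assert select_seeds(results) == []

    def test_single_metric_hit_is_included(self):
        # significant in degree only, not efficiency: still selected
        results = [
            _nodal_result("degree", "EC.R", 5, 0.01),
            _nodal_result("efficiency", "EC.R", 5, 0.70),
        ]
        assert select_seeds(results) == ["EC.R"]

    def test_deduplicated_and_in_atlas_order(self):
        results = [
            _nodal_result("degree", "mPFC.L", 2, 0.01),
            _nodal_result("efficiency", "mPFC.L", 2, 0.02),
            _nodal_result("betweenness", "mPFC.L", 2, 0.001),
            _nodal_result("degree", "CPu.L", 0, 0.04),
        ]
        assert select_seeds(results) == ["CPu.L", "mPFC.L"]
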