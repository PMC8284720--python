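"""Graph-metric values on known graphs, invariants, and the null model."""

import numpy as np
import pytest

import _oracles as oracle
from metabnet import (
    BinaryGraph,
    Region,
    RegionAtlas,
    clustering_and_path,
    efficiencies,
    nodal_metrics,
    random_reference,
    small_world,
)
from metabnet.metrics import nodal_efficiency


def _atlas(n):
    return RegionAtlas(
        Region(i + 1, f"node {i}", f"N{i}", "midline") for i in range(n)
    )


def _graph(a, sparsity=None):
    a = np.asarray(a, dtype=np.uint8)
    n = a.shape[0]
    s = sparsity if sparsity is not None else a.sum() / (n * (n - 1))
    return BinaryGraph(atlas=_atlas(n), adjacency=a, sparsity=float(s))


def complete(n):
    a = np.ones((n, n), dtype=np.uint8)
    np.fill_diagonal(a, 0)
    return _graph(a)


def path3():
    a = np.zeros((3, 3), dtype=np.uint8)
    a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1
    return _graph(a)


def star(leaves):
    n = leaves + 1
    a = np.zeros((n, n), dtype=np.uint8)
    a[0, 1:] = a[1:, 0] = 1
    return _graph(a)


def ring_lattice(n, k):
    a = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            a[i, j] = a[j, i] = 1
    return _graph(a)


class TestClusteringAndPath:
    def test_complete_graph(self):
        cp, lp = clustering_and_path(complete(4))
        assert (cp, lp) == (1.0, 1.0)

    def test_path_graph(self):
        cp, lp = clustering_and_path(path3())
        assert cp == 0.0
        assert lp == pytest.approx(4 / 3)

    def test_ring_lattice_closed_form(self):
        # C = 3(k-2)/(4(k-1)) for a ring lattice with k neighbors: 0.5 at k=4
        cp, _lp = clustering_and_path(ring_lattice(10, 4))
        assert cp == pytest.approx(0.5)

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError, match="edgeless"):
            clustering_and_path(_graph(np.zeros((4, 4)), sparsity=0.01))


class TestEfficiencies:
    def test_complete_graph(self):
        assert efficiencies(complete(4)) == (1.0, 1.0)

    def test_path_graph(self):
        e_global, e_local = efficiencies(path3())
        assert e_global == pytest.approx(5 / 6)
        assert e_local == 0.0

    def test_two_disjoint_edges(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
        e_global, _ = efficiencies(_graph(a))
        assert e_global == pytest.approx(1 / 3)


class TestNodalMetrics:
    def test_complete_graph(self):
        nm = nodal_metrics(complete(4))
        assert np.all(nm.degree == 3)
        np.testing.assert_allclose(nm.betweenness, 0.0)
        np.testing.assert_allclose(nm.efficiency, 1.0)

    def test_star_graph(self):
        nm = nodal_metrics(star(4))
        assert nm.degree[0] == 4
        assert nm.betweenness[0] == pytest.approx(1.0)
        assert nm.efficiency[0] == pytest.approx(1.0)
        np.testing.assert_allclose(nm.degree[1:], 1)
        np.testing.assert_allclose(nm.betweenness[1:], 0.0)
        np.testing.assert_allclose(nm.efficiency[1:], 0.625)

    def test_path_graph(self):
        nm = nodal_metrics(path3())
        assert nm.degree.tolist() == [1, 2, 1]
        assert nm.betweenness[1] == pytest.approx(1.0)
        assert nm.efficiency[1] == pytest.approx(1.0)
        assert nm.efficiency[0] == pytest.approx(0.75)

    def test_handshake_and_mean_nodal_efficiency(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = rng.integers(5, 15)
            a = (rng.random((n, n)) < 0.3).astype(np.uint8)
            a = np.triu(a, 1)
            a = a + a.T
            g = _graph(a)
            nm = nodal_metrics(g)
            assert nm.degree.sum() == 2 * g.n_edges
            e_global, _ = efficiencies(g)
            assert nm.efficiency.mean() == pytest.approx(e_global, abs=1e-12)

    def test_invariant_under_node_relabeling(self):
        rng = np.random.default_rng(7)
        n = 10
        a = (rng.random((n, n)) < 0.35).astype(np.uint8)
        a = np.triu(a, 1)
        a = a + a.T
        perm = rng.permutation(n)
        ap = a[np.ix_(perm, perm)]
        nm = nodal_metrics(_graph(a))
        nmp = nodal_metrics(_graph(ap))
        np.testing.assert_array_equal(nm.degree[perm], nmp.degree)
        np.testing.assert_allclose(nm.betweenness[perm], nmp.betweenness, atol=1e-12)
        np.testing.assert_allclose(nm.efficiency[perm], nmp.efficiency, atol=1e-12)
        cp, lp = clustering_and_path(_graph(a))
        cpp, lpp = clustering_and_path(_graph(ap))
        assert (cp, lp) == pytest.approx((cpp, lpp))


class TestRandomReference:
    def test_degree_sequence_preserved(self):
        rng = np.random.default_rng(11)
        n = 20
        a = (rng.random((n, n)) < 0.3).astype(np.uint8)
        a = np.triu(a, 1)
        a = a + a.T
        g = _graph(a)
        ref = random_reference(g, rng_seed=3)
        np.testing.assert_array_equal(np.sort(ref.degrees), np.sort(g.degrees))
        np.testing.assert_array_equal(ref.degrees, g.degrees)
        assert np.all(np.diag(ref.adjacency) == 0)

    def test_triangle_is_its_own_null(self):
        ref = random_reference(complete(3), rng_seed=0)
        np.testing.assert_array_equal(ref.adjacency, complete(3).adjacency)

    def test_same_seed_reproduces(self):
        rng = np.random.default_rng(12)
        n = 15
        a = (rng.random((n, n)) < 0.4).astype(np.uint8)
        a = np.triu(a, 1)
        a = a + a.T
        g = _graph(a)
        r1 = random_reference(g, rng_seed=99)
        r2 = random_reference(g, rng_seed=99)
        np.testing.assert_array_equal(r1.adjacency, r2.adjacency)

    def test_actually_rewires_large_graphs(self):
        rng = np.random.default_rng(13)
        n = 40
        a = (rng.random((n, n)) < 0.2).astype(np.uint8)
        a = np.triu(a, 1)
        a = a + a.T
        g = _graph(a)
        ref = random_reference(g, rng_seed=5)
        assert not np.array_equal(ref.adjacency, g.adjacency)


class TestSmallWorld:
    def test_complete_graph_is_its_own_null(self):
        sw = small_world(complete(10), n_random=5, rng_seed=0)
        assert (sw.gamma, sw.lambda_, sw.sigma) == (1.0, 1.0, 1.0)

    def test_watts_strogatz_regime_has_sigma_above_one(self):
        import networkx as nx

        ws = nx.watts_strogatz_graph(96, 10, 0.1, seed=42)
        g = _graph(nx.to_numpy_array(ws, dtype=np.uint8))
        sw = small_world(g, n_random=20, rng_seed=1)
        assert sw.sigma > 1.0
        assert sw.gamma > 1.0

    def test_random_graph_is_roughly_its_own_null(self):
        import networkx as nx

        er = nx.gnp_random_graph(96, 0.15, seed=7)
        g = _graph(nx.to_numpy_array(er, dtype=np.uint8))
        sw = small_world(g, n_random=20, rng_seed=2)
        assert 0.8 <= sw.sigma <= 1.2


class TestOracleSpotChecks:
    """Small randomized cross-checks; the exhaustive sweep lives in acceptance."""

    def test_metrics_match_bruteforce_on_random_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = int(rng.integers(4, 10))
            a = (rng.random((n, n)) < 0.4).astype(np.uint8)
            a = np.triu(a, 1)
            a = a + a.T
            g = _graph(a)
            if a.sum() == 0:
                continue
            cp, lp = clustering_and_path(g)
            assert cp == pytest.approx(oracle.clustering_mean(a), abs=1e-12)
            assert lp == pytest.approx(oracle.path_length(a), abs=1e-12)
            e_glob, e_loc = efficiencies(g)
            assert e_glob == pytest.approx(oracle.global_efficiency(a), abs=1e-12)
            assert e_loc == pytest.approx(oracle.local_efficiency(a), abs=1e-12)
            np.testing.assert_allclose(
                nodal_efficiency(a), oracle.nodal_efficiency(a), atol=1e-12
            )
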