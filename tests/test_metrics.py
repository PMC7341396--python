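"""Unit and property tests for the global graph metrics."""

import numpy as np
import pytest

from adgraph import metrics as M
from conftest import (bf_char_path_length, bf_clustering, bf_global_efficiency,
                      bf_transitivity, random_adjacency)


def graph_from_edges(n, edges):
    adj = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return adj


K4 = graph_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
PATH3 = graph_from_edges(3, [(0, 1), (1, 2)])
STAR4 = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
TRIANGLE_PENDANT = graph_from_edges(4, [(0, 1), (0, 2), (1, 2), (2, 3)])
TWO_K2 = graph_from_edges(4, [(0, 1), (2, 3)])


class TestClosedForms:
    def test_complete_graph_all_metrics_one(self):
        char, connected = M.characteristic_path_length(K4)
        assert char == 1.0 and connected
        assert M.global_efficiency(K4) == 1.0
        assert M.clustering_coefficient(K4) == 1.0
        assert M.transitivity(K4) == 1.0

    def test_path_graph_enumerated_pairs(self):
        # pairs (0,1)=1, (1,2)=1, (0,2)=2
        assert M.characteristic_path_length(PATH3)[0] == pytest.approx(4 / 3)
        assert M.global_efficiency(PATH3) == pytest.approx(5 / 6)

    def test_star_graph_has_no_triangles(self):
        assert M.clustering_coefficient(STAR4) == 0.0
        assert M.transitivity(STAR4) == 0.0

    def test_triangle_with_pendant_matches_bruteforce(self):
        assert M.clustering_coefficient(TRIANGLE_PENDANT) == pytest.approx(
            bf_clustering(TRIANGLE_PENDANT), abs=1e-12)
        assert M.transitivity(TRIANGLE_PENDANT) == pytest.approx(
            bf_transitivity(TRIANGLE_PENDANT), abs=1e-12)

    def test_disconnected_pairs_excluded_and_flagged(self):
        char, connected = M.characteristic_path_length(TWO_K2)
        assert char == 1.0
        assert not connected

    def test_empty_graph_efficiency_zero_path_undefined(self):
        empty = np.zeros((4, 4), dtype=np.uint8)
        assert M.global_efficiency(empty) == 0.0
        with pytest.raises(ValueError, match="no reachable"):
            M.characteristic_path_length(empty)

    def test_no_triples_transitivity_warns_zero(self):
        with pytest.warns(UserWarning, match="transitivity undefined"):
            assert M.transitivity(TWO_K2) == 0.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_graphs_match_bruteforce(self, seed):
        """Vectorized metrics equal exhaustive enumeration on small graphs."""
        rng = np.random.default_rng(seed)
        for _ in range(10):
            n = int(rng.integers(3, 13))
            adj = random_adjacency(n, rng.uniform(0.1, 1.0), rng)
            if adj.any():
                assert M.characteristic_path_length(adj)[0] == pytest.approx(
                    bf_char_path_length(adj), abs=1e-10)
            assert M.global_efficiency(adj) == pytest.approx(
                bf_global_efficiency(adj), abs=1e-10)
            assert M.clustering_coefficient(adj) == pytest.approx(
                bf_clustering(adj), abs=1e-10)
            if (adj.sum(1) >= 2).any():
                assert M.transitivity(adj) == pytest.approx(
                    bf_transitivity(adj), abs=1e-10)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        adj = random_adjacency(10, 0.4, rng)
        perm = rng.permutation(10)
        padj = adj[np.ix_(perm, perm)]
        assert M.characteristic_path_length(padj)[0] == pytest.approx(
            M.characteristic_path_length(adj)[0])
        assert M.clustering_coefficient(padj) == pytest.approx(M.clustering_coefficient(adj))
        assert M.transitivity(padj) == pytest.approx(M.transitivity(adj))
        assert M.global_efficiency(padj) == pytest.approx(M.global_efficiency(adj))

    def test_efficiency_bounds_inverse_path_length(self):
        """Effi >= 1/Char on connected graphs (Jensen on reciprocals)."""
        rng = np.random.default_rng(4)
        checked = 0
        while checked < 20:
            adj = random_adjacency(9, rng.uniform(0.3, 0.9), rng)
            char, connected = M.characteristic_path_length(adj) if adj.any() else (None, False)
            if not connected:
                continue
            assert M.global_efficiency(adj) >= 1.0 / char - 1e-12
            checked += 1

    def test_adding_edge_monotonicity(self):
        rng = np.random.default_rng(5)
        adj = random_adjacency(8, 0.5, rng)
        missing = [(i, j) for i in range(8) for j in range(i + 1, 8) if not adj[i, j]]
        if not missing:
            pytest.skip("graph complete")
        i, j = missing[0]
        denser = adj.copy()
        denser[i, j] = denser[j, i] = 1
        assert M.global_efficiency(denser) >= M.global_efficiency(adj) - 1e-12
        char0, conn0 = M.characteristic_path_length(adj)
        char1, _ = M.characteristic_path_length(denser)
        if conn0:
            assert char1 <= char0 + 1e-12


class TestRandomReference:
    def test_density_one_reference_is_complete(self):
        ref = M.random_reference(K4, n_random=3, seed=0)
        assert ref.c0 == 1.0 and ref.l0 == 1.0

    def test_er_clustering_matches_density(self):
        """E[clustering] of a uniform random graph ~ its density."""
        rng = np.random.default_rng(0)
        adj = random_adjacency(90, 0.3, rng)
        k = int(np.triu(adj, 1).sum())
        density = k / (90 * 89 / 2)
        ref = M.random_reference(adj, n_random=50, seed=1)
        assert ref.c0 == pytest.approx(density, abs=0.02)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(2)
        adj = random_adjacency(20, 0.3, rng)
        r1 = M.random_reference(adj, n_random=10, seed=42)
        r2 = M.random_reference(adj, n_random=10, seed=42)
        assert (r1.c0, r1.l0) == (r2.c0, r2.l0)
        r3 = M.random_reference(adj, n_random=10, seed=43)
        assert (r3.c0, r3.l0) != (r1.c0, r1.l0)

    def test_cache_shares_ensembles_by_size_and_density(self):
        rng = np.random.default_rng(6)
        cache = M.ReferenceCache(n_random=5, seed=0)
        a = random_adjacency(12, 0.4, rng)
        perm = rng.permutation(12)
        b = a[np.ix_(perm, perm)]  # relabeled graph: same (n, k)
        assert cache.get(a) is cache.get(b)


class TestSmallWorldness:
    def test_direct_substitution(self):
        ref = M.RandomReference(c0=0.25, l0=2.0, n_random=1, seed=0, n_nodes=4, n_edges=4)
        adj = graph_from_edges(4, [(0, 1), (1, 2), (2, 0), (2, 3)])
        c = M.clustering_coefficient(adj)
        l, _ = M.characteristic_path_length(adj)
        assert M.small_worldness(adj, ref) == pytest.approx((c / 0.25) / (l / 2.0))

    def test_ring_lattice_is_small_world_positive(self):
        """A ring lattice beats matched random graphs on clustering/path ratio."""
        n, half_k = 30, 3
        adj = np.zeros((n, n), dtype=np.uint8)
        for i in range(n):
            for d in range(1, half_k + 1):
                adj[i, (i + d) % n] = adj[(i + d) % n, i] = 1
        ref = M.random_reference(adj, n_random=30, seed=0)
        assert M.small_worldness(adj, ref) > 1.0

    def test_zero_clustering_warns_zero(self):
        ref = M.RandomReference(c0=0.5, l0=1.5, n_random=1, seed=0, n_nodes=4, n_edges=3)
        with pytest.warns(UserWarning, match="zero clustering"):
            assert M.small_worldness(STAR4, ref) == 0.0

    def test_degenerate_reference_rejected(self):
        ref = M.RandomReference(c0=0.0, l0=1.5, n_random=1, seed=0, n_nodes=4, n_edges=3)
        with pytest.raises(ValueError, match="C0"):
            M.small_worldness(K4, ref)


class TestAUC:
    def test_constant_curve_rectangle(self):
        grid = np.arange(0.08, 0.53, 0.01)
        curve = M.MetricCurve(grid=grid, values=np.full_like(grid, 1.0),
                              metric_name="clustering")
        assert M.metric_auc(curve).value == pytest.approx(0.44)

    def test_linear_curve_triangle(self):
        curve = M.MetricCurve(grid=np.array([0.0, 0.5, 1.0]),
                              values=np.array([0.0, 0.5, 1.0]), metric_name="efficiency")
        assert M.metric_auc(curve).value == pytest.approx(0.5)

    def test_random_curve_matches_manual_trapezoid(self):
        rng = np.random.default_rng(1)
        grid = np.sort(rng.uniform(0.05, 0.6, 12))
        vals = rng.random(12)
        manual = sum((vals[i] + vals[i + 1]) / 2 * (grid[i + 1] - grid[i])
                     for i in range(11))
        curve = M.MetricCurve(grid=grid, values=vals, metric_name="transitivity")
        assert M.metric_auc(curve).value == pytest.approx(manual, abs=1e-12)

    def test_grid_value_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            M.MetricCurve(grid=np.array([0.1, 0.2]), values=np.array([1.0]),
                          metric_name="clustering")
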