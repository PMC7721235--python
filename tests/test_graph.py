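"""Graph metrics against brute-force oracles and structural invariants."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from braindyn.errors import InvalidArgumentError
from braindyn.graph import (
    BINARY,
    WEIGHTED,
    NullConfig,
    SparsityGrid,
    ThresholdedGraph,
    clustering_coefficient,
    metrics_over_grid,
    null_model,
    path_metrics,
    smallworldness,
    threshold_by_sparsity,
)
from conftest import random_symmetric


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation path)

def brute_binary_clustering(A):
    n = A.shape[0]
    C = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(1 for a, b in combinations(nbrs, 2) if A[a, b])
        C[i] = 2 * tri / (k * (k - 1))
    return C


def brute_weighted_clustering(A):
    # Onnela: geometric mean of max-normalized triangle weights
    n = A.shape[0]
    W = A / A.max()
    C = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        s = sum((W[i, a] * W[i, b] * W[a, b]) ** (1 / 3)
                for a, b in combinations(nbrs, 2) if A[a, b])
        C[i] = 2 * s / (k * (k - 1))
    return C


def brute_distances(A, binary):
    # Floyd-Warshall on lengths (1 for binary, 1/w for weighted)
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if A[i, j]:
                D[i, j] = 1.0 if binary else 1.0 / A[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def brute_global_metrics(A, binary=True):
    D = brute_distances(A, binary)
    n = A.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    L = D[finite].mean() if finite.any() else np.inf
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(D) | (D == 0), 0.0, 1.0 / D)
    E = inv[off].mean()
    return L, E


def brute_local_efficiency(A, binary=True):
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        if len(nbrs) < 2:
            continue
        out[i] = brute_global_metrics(A[np.ix_(nbrs, nbrs)], binary)[1]
    return out


class TestThreshold:
    def test_full_sparsity_keeps_every_positive_pair(self):
        m = random_symmetric(6, seed=0)
        g = threshold_by_sparsity(m, 1.0, BINARY)
        assert g.n_edges == 15

    def test_half_sparsity_keeps_the_largest_edges(self):
        m = random_symmetric(4, seed=1)
        g = threshold_by_sparsity(m, 0.5, WEIGHTED)
        assert g.n_edges == 3
        kept = np.sort(g.adjacency[np.triu_indices(4, 1)])[-3:]
        expected = np.sort(m[np.triu_indices(4, 1)])[-3:]
        np.testing.assert_array_equal(kept, expected)

    def test_negative_entries_excluded_matches_positive_ranking_oracle(self):
        m = random_symmetric(8, seed=2, negative=True)
        g = threshold_by_sparsity(m, 0.25, WEIGHTED)
        iu = np.triu_indices(8, 1)
        vals = m[iu]
        n_keep = round(0.25 * len(vals))
        oracle = set(np.argsort(-np.where(vals > 0, vals, -np.inf))[:n_keep])
        kept = set(np.flatnonzero(g.adjacency[iu] != 0))
        assert kept == oracle

    def test_zero_edge_request_rejected(self):
        with pytest.raises(InvalidArgumentError):
            threshold_by_sparsity(random_symmetric(4, seed=3), 0.01, BINARY)

    @pytest.mark.parametrize("seed", range(3))
    def test_edge_sets_nest_across_the_grid(self, seed):
        m = random_symmetric(10, seed=seed)
        grid = SparsityGrid()
        prev = None
        for s in grid.values:
            edges = set(map(tuple, np.argwhere(
                np.triu(threshold_by_sparsity(m, s, BINARY).adjacency, 1))))
            if prev is not None:
                assert prev <= edges
            prev = edges


class TestClustering:
    def test_complete_graph_fully_clustered(self):
        A = np.ones((5, 5)) - np.eye(5)
        g = ThresholdedGraph(A, 1.0, BINARY)
        nodal, mean = clustering_coefficient(g)
        np.testing.assert_array_equal(nodal.clustering, np.ones(5))
        assert mean == 1.0

    def test_star_graph_triangle_free(self):
        A = np.zeros((6, 6))
        A[0, 1:] = A[1:, 0] = 1
        nodal, mean = clustering_coefficient(ThresholdedGraph(A, 1.0, BINARY))
        assert mean == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_triangle_counting(self, seed):
        rng = np.random.default_rng(seed)
        A = (random_symmetric(12, seed=seed) < 0.5).astype(float)
        np.fill_diagonal(A, 0)
        nodal, _ = clustering_coefficient(ThresholdedGraph(A, 1.0, BINARY))
        np.testing.assert_allclose(nodal.clustering, brute_binary_clustering(A),
                                   atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_weighted_matches_onnela_oracle(self, seed):
        m = random_symmetric(8, seed=seed, density=0.6)
        g = threshold_by_sparsity(m, 1.0, WEIGHTED)
        nodal, _ = clustering_coefficient(g)
        np.testing.assert_allclose(nodal.clustering,
                                   brute_weighted_clustering(g.adjacency),
                                   atol=1e-12)


class TestPathMetrics:
    def test_complete_graph_unit_length_and_efficiency(self):
        A = np.ones((6, 6)) - np.eye(6)
        L, E, _, disc = path_metrics(ThresholdedGraph(A, 1.0, BINARY))
        assert L == 1.0 and E == 1.0 and disc == 0.0

    def test_three_node_path_hand_enumeration(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        L, E, _, _ = path_metrics(ThresholdedGraph(A, 1.0, BINARY))
        assert L == pytest.approx(4.0 / 3.0)
        assert E == pytest.approx(5.0 / 6.0)

    def test_disconnected_dyads_count_zero_efficiency_pairs(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1
        L, E, _, disc = path_metrics(ThresholdedGraph(A, 1.0, BINARY))
        assert L == 1.0                       # connected pairs only
        assert E == pytest.approx(4 / 12)     # 4 of 12 ordered pairs connected
        assert disc == pytest.approx(8 / 12)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("mode", [BINARY, WEIGHTED])
    def test_small_graphs_match_floyd_warshall_oracle(self, seed, mode):
        m = random_symmetric(7, seed=seed, density=0.55)
        g = threshold_by_sparsity(m, 1.0, mode)
        if g.n_edges == 0:
            pytest.skip("empty draw")
        L, E, local, _ = path_metrics(g)
        Lo, Eo = brute_global_metrics(g.adjacency, binary=mode == BINARY)
        assert L == pytest.approx(Lo, abs=1e-12)
        assert E == pytest.approx(Eo, abs=1e-12)
        np.testing.assert_allclose(
            local, brute_local_efficiency(g.adjacency, binary=mode == BINARY),
            atol=1e-12)


class TestNullModel:
    def test_degree_sequence_and_edge_count_preserved(self):
        m = random_symmetric(12, seed=5, density=0.5)
        g = threshold_by_sparsity(m, 0.4, BINARY)
        deg = (g.adjacency != 0).sum(1)
        for null in null_model(g, n_nulls=5, seed=1):
            assert null.n_edges == g.n_edges
            np.testing.assert_array_equal((null.adjacency != 0).sum(1), deg)

    def test_weighted_nulls_preserve_weight_multiset(self):
        m = random_symmetric(10, seed=6, density=0.6)
        g = threshold_by_sparsity(m, 0.4, WEIGHTED)
        iu = np.triu_indices(10, 1)
        orig = np.sort(g.adjacency[iu][g.adjacency[iu] != 0])
        for null in null_model(g, n_nulls=3, seed=2):
            vals = np.sort(null.adjacency[iu][null.adjacency[iu] != 0])
            np.testing.assert_allclose(vals, orig)

    def test_ring_lattice_loses_clustering_under_rewiring(self):
        G = nx.watts_strogatz_graph(30, 6, 0.0)
        A = nx.to_numpy_array(G)
        g = ThresholdedGraph(A, 0.2, BINARY)
        C = clustering_coefficient(g)[1]
        nulls = null_model(g, n_nulls=40, seed=3)
        lower = sum(clustering_coefficient(x)[1] < C for x in nulls)
        assert lower >= 0.95 * len(nulls)


class TestSmallworldness:
    def test_self_null_gives_unit_ratios(self):
        m = random_symmetric(10, seed=7, density=0.6)
        g = threshold_by_sparsity(m, 0.4, BINARY)
        gamma, lam, sigma = smallworldness(g, [g, g])
        assert gamma == pytest.approx(1.0)
        assert lam == pytest.approx(1.0)
        assert sigma == pytest.approx(1.0)

    def test_ring_lattice_is_small_world_relative_to_nulls(self):
        A = nx.to_numpy_array(nx.watts_strogatz_graph(60, 6, 0.05))
        g = ThresholdedGraph(A, 0.1, BINARY)
        nulls = null_model(g, n_nulls=20, seed=4)
        gamma, lam, sigma = smallworldness(g, nulls)
        assert gamma > 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_graphs_are_their_own_null_class(self, seed):
        A = nx.to_numpy_array(nx.gnp_random_graph(40, 0.3, seed=seed))
        g = ThresholdedGraph(A, 0.3, BINARY)
        nulls = null_model(g, n_nulls=20, seed=seed)
        sigma = smallworldness(g, nulls)[2]
        assert 0.8 < sigma < 1.25


class TestGrid:
    def test_single_level_single_matrix(self):
        m = random_symmetric(8, seed=8)
        table = metrics_over_grid(m, SparsityGrid((0.3,)), modes=(BINARY,))
        assert set(table["sparsity"]) == {0.3}
        assert (table["metric"] == "global_efficiency").sum() == 1

    def test_binary_efficiency_monotone_in_sparsity(self):
        m = random_symmetric(14, seed=9)
        table = metrics_over_grid(m, modes=(BINARY,))
        eff = table[(table["metric"] == "global_efficiency")].sort_values("sparsity")
        vals = eff["value"].to_numpy()
        assert np.all(np.diff(vals) >= -1e-12)

    def test_deterministic_for_identical_inputs(self):
        m = random_symmetric(8, seed=10)
        a = metrics_over_grid(m, SparsityGrid((0.2, 0.4)),
                              null_config=NullConfig(n_nulls=5, seed=0))
        b = metrics_over_grid(m, SparsityGrid((0.2, 0.4)),
                              null_config=NullConfig(n_nulls=5, seed=0))
        assert a.equals(b)

    def test_global_metrics_invariant_under_node_relabeling(self):
        m = random_symmetric(9, seed=11)
        perm = np.random.default_rng(1).permutation(9)
        a = metrics_over_grid(m, SparsityGrid((0.3,)), modes=(BINARY,))
        b = metrics_over_grid(m[np.ix_(perm, perm)], SparsityGrid((0.3,)),
                              modes=(BINARY,))
        for metric in ("clustering", "path_length", "global_efficiency"):
            va = a[(a.metric == metric) & (a.node == "")]["value"].iloc[0]
            vb = b[(b.metric == metric) & (b.node == "")]["value"].iloc[0]
            assert va == pytest.approx(vb, abs=1e-12)
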