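"""Graph-metric contracts: clustering coefficient and path length against
brute-force/networkx oracles, FDR edge selection against a long-form BH
implementation, strength/cost hand oracles, and hub detection."""
import itertools

import networkx as nx
import numpy as np
import pytest

from dfcstates import (AdjacencyMatrix, average_path_length,
                       centroid_to_state_graph, clustering_coefficient,
                       fdr_threshold_adjacency, identify_hubs, make_node_meta,
                       strength_and_cost, vectorize_upper)
from dfcstates.graph import correlation_pvalues, graph_metrics


def brute_force_cc(A):
    """Triangle enumeration over all neighbor pairs."""
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(A[j, l] for j, l in itertools.combinations(nbrs, 2))
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def brute_force_bh(pvals, alpha):
    """Sorted-threshold Benjamini-Hochberg by definition."""
    p = np.asarray(pvals)
    m = p.size
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = np.flatnonzero(p[order] <= thresh)
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below.max() + 1]] = True
    return reject


def _atlas_graphs(max_nodes=6):
    return [G for G in nx.graph_atlas_g()[1:]
            if 2 <= G.number_of_nodes() <= max_nodes]


class TestClusteringCoefficient:
    def test_triangle_graph_all_ones(self):
        A = np.ones((3, 3)) - np.eye(3)
        cc, mean_cc = clustering_coefficient(A)
        assert np.allclose(cc, 1.0) and mean_cc == pytest.approx(1.0)

    def test_star_center_zero(self):
        A = np.zeros((5, 5))
        A[0, 1:] = A[1:, 0] = 1
        cc, _ = clustering_coefficient(A)
        assert cc[0] == 0.0
        assert np.allclose(cc[1:], 0.0)  # leaves have degree 1 -> 0

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            A = (rng.random((8, 8)) < 0.4).astype(int)
            A = np.triu(A, 1)
            A = A + A.T
            assert np.allclose(clustering_coefficient(A)[0],
                               brute_force_cc(A))

    def test_matches_networkx_on_atlas(self):
        for G in _atlas_graphs(6):
            A = nx.to_numpy_array(G).astype(int)
            cc, _ = clustering_coefficient(A)
            ref = nx.clustering(G)
            for i, node in enumerate(G.nodes()):
                assert cc[i] == pytest.approx(ref[node], abs=1e-12)


class TestPathLength:
    def test_complete_graph_pl_one_efficiency_one(self):
        A = np.ones((44, 44)) - np.eye(44)
        pl, geff, reach = average_path_length(A)
        assert pl == pytest.approx(1.0)
        assert geff == pytest.approx(1.0)
        assert reach == pytest.approx(1.0)

    def test_path_graph_hand_enumeration(self):
        # 1-2-3 chain: ordered distances (1,1,1,1,2,2)/6 = 4/3
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        pl, geff, _ = average_path_length(A)
        assert pl == pytest.approx(4.0 / 3.0)
        assert geff == pytest.approx(0.75)

    def test_disconnected_components_match_floyd_warshall(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            A = (rng.random((8, 8)) < 0.25).astype(int)
            A = np.triu(A, 1)
            A = A + A.T
            n = 8
            # brute-force Floyd-Warshall
            D = np.where(A > 0, 1.0, np.inf)
            np.fill_diagonal(D, 0.0)
            for k in range(n):
                D = np.minimum(D, D[:, [k]] + D[[k], :])
            off = ~np.eye(n, dtype=bool)
            finite = np.isfinite(D) & off
            pl, _, reach = average_path_length(A)
            if finite.sum() == 0:
                assert np.isnan(pl)
                continue
            assert pl == pytest.approx(D[finite].mean())
            assert reach == pytest.approx(finite.sum() / (n * (n - 1)))

    def test_matches_networkx_on_atlas(self):
        for G in _atlas_graphs(6):
            A = nx.to_numpy_array(G).astype(int)
            pl, _, reach = average_path_length(A)
            if nx.is_connected(G) and G.number_of_nodes() > 1:
                assert pl == pytest.approx(
                    nx.average_shortest_path_length(G), abs=1e-12)
                assert reach == pytest.approx(1.0)

    def test_empty_graph_reported_missing(self):
        with pytest.warns(RuntimeWarning, match="no edges"):
            pl, geff, reach = average_path_length(np.zeros((4, 4)))
        assert np.isnan(pl) and reach == 0.0


class TestFdrAdjacency:
    def test_all_zero_correlations_give_null_graph(self):
        adj = fdr_threshold_adjacency(np.eye(6), n_samples=240)
        assert adj.total_connections == 0
        assert not adj.mask.any()

    def test_single_strong_edge_survives_alone(self):
        n = 10
        R = np.eye(n)
        R[0, 1] = R[1, 0] = 0.99
        adj = fdr_threshold_adjacency(R, n_samples=240)
        assert adj.total_connections == 1
        assert adj.mask[0, 1] and adj.mask[1, 0]
        assert adj.weights[0, 1] == pytest.approx(0.99)

    def test_matches_brute_force_bh_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            X = rng.standard_normal((60, 8))
            X[:, 1] = X[:, 0] + 0.4 * rng.standard_normal(60)
            X[:, 3] = -X[:, 2] + 0.6 * rng.standard_normal(60)
            R = np.corrcoef(X.T)
            adj = fdr_threshold_adjacency(R, n_samples=60, alpha=0.05)
            p = correlation_pvalues(R, 60)
            iu = np.triu_indices(8, 1)
            expected = brute_force_bh(p[iu], 0.05)
            assert np.array_equal(adj.mask[iu], expected)

    def test_bh_example_rejects_first_three(self):
        # classic example: {0.001, 0.02, 0.03, 0.9} at alpha 0.05
        reject = brute_force_bh([0.001, 0.02, 0.03, 0.9], 0.05)
        assert reject.tolist() == [True, True, True, False]
        from statsmodels.stats.multitest import multipletests
        assert np.array_equal(
            multipletests([0.001, 0.02, 0.03, 0.9], alpha=0.05,
                          method="fdr_bh")[0], reject)

    def test_perfect_correlation_p_zero_survives(self):
        R = np.eye(4)
        R[2, 3] = R[3, 2] = 1.0
        adj = fdr_threshold_adjacency(R, n_samples=10)
        assert adj.mask[2, 3]

    def test_lowering_alpha_never_adds_edges(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((80, 10))
        R = np.corrcoef(X.T)
        prev = None
        for alpha in (0.2, 0.1, 0.05, 0.01):
            mask = fdr_threshold_adjacency(R, 80, alpha=alpha).mask
            if prev is not None:
                assert not (mask & ~prev).any()
            prev = mask

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError, match="n_samples"):
            fdr_threshold_adjacency(np.eye(4), n_samples=3)

    def test_correlation_pvalue_matches_scipy(self):
        from scipy import stats as sps
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal((2, 30))
        r = np.corrcoef(x, y)[0, 1]
        R = np.array([[1.0, r], [r, 1.0]])
        p = correlation_pvalues(R, 30)[0, 1]
        assert p == pytest.approx(sps.pearsonr(x, y).pvalue, rel=1e-10)


class TestStrengthCost:
    def _adj(self, W, coords):
        meta = make_node_meta(W.shape[0], coords=np.asarray(coords, float))
        return AdjacencyMatrix(weights=W, mask=W != 0, node_meta=meta)

    def test_single_edge_cost_is_distance_times_weight(self):
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = 0.5
        adj = self._adj(W, [[0, 0, 0], [30, 0, 0]])
        ns, node_s, nc, node_c = strength_and_cost(adj)
        assert ns == pytest.approx(0.5)
        assert nc == pytest.approx(15.0)
        assert node_c.tolist() == pytest.approx([15.0, 15.0])

    def test_all_zero_weights(self):
        adj = self._adj(np.zeros((3, 3)), np.zeros((3, 3)))
        ns, _, nc, _ = strength_and_cost(adj)
        assert ns == 0.0 and nc == 0.0

    def test_four_node_toy_matches_manual_computation(self):
        coords = np.array([[0.0, 0, 0], [3, 4, 0], [0, 0, 10], [6, 8, 0]])
        W = np.zeros((4, 4))
        edges = [(0, 1, -0.5), (0, 2, 0.25), (1, 3, 0.8)]
        for i, j, w in edges:
            W[i, j] = W[j, i] = w
        adj = self._adj(W, coords)
        ns, node_s, nc, node_c = strength_and_cost(adj)
        # manual: |w| sums and distance*|w| sums
        d01, d02, d13 = 5.0, 10.0, 5.0
        assert ns == pytest.approx(0.5 + 0.25 + 0.8, abs=1e-12)
        assert nc == pytest.approx(d01 * 0.5 + d02 * 0.25 + d13 * 0.8,
                                   abs=1e-12)
        assert node_s[0] == pytest.approx(0.75, abs=1e-12)
        assert node_c[1] == pytest.approx(d01 * 0.5 + d13 * 0.8, abs=1e-12)
        assert node_c.sum() == pytest.approx(2 * nc, abs=1e-12)

    def test_cost_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(-50, 50, (6, 3))
        W = rng.standard_normal((6, 6))
        W = np.triu(W, 1)
        W = W + W.T
        adj1 = self._adj(W, coords)
        # random rotation + translation
        Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        adj2 = self._adj(W, coords @ Q.T + np.array([5.0, -12.0, 40.0]))
        ns1, _, nc1, c1 = strength_and_cost(adj1)
        ns2, _, nc2, c2 = strength_and_cost(adj2)
        assert nc1 == pytest.approx(nc2, rel=1e-10)
        assert np.allclose(c1, c2)

    def test_missing_coordinates_error_names_node(self):
        coords = np.array([[0.0, 0, 0], [np.nan, 0, 0], [1, 1, 1]])
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        adj = self._adj(W, coords)
        with pytest.raises(ValueError, match="IC02"):
            strength_and_cost(adj)


class TestHubs:
    def test_arithmetic_oracle_example(self):
        # mean 2.8, sd 4.0249, threshold 8.837 -> only the 10 flagged
        hubs = identify_hubs([1, 1, 1, 1, 10])
        assert hubs == [4]
        v = np.array([1, 1, 1, 1, 10.0])
        assert v.mean() + 1.5 * v.std(ddof=1) == pytest.approx(8.837, abs=0.001)

    def test_all_equal_values_no_hubs(self):
        with pytest.warns(RuntimeWarning, match="zero variance"):
            assert identify_hubs([3.0, 3.0, 3.0, 3.0]) == []

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        v = rng.random(20)
        assert identify_hubs(v) == identify_hubs(123.4 * v)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError, match="3 nodes"):
            identify_hubs([1.0, 2.0])


class TestCentroidGraph:
    def test_zero_vector_gives_empty_graph(self):
        adj = centroid_to_state_graph(np.zeros(10), edge_threshold_rule="abs:0")
        assert adj.total_connections == 0

    def test_roundtrip_vectorize_unvectorize(self):
        rng = np.random.default_rng(7)
        M = rng.standard_normal((6, 6))
        M = M + M.T
        np.fill_diagonal(M, 0.0)
        adj = centroid_to_state_graph(vectorize_upper(M),
                                      edge_threshold_rule="abs:0")
        assert np.allclose(adj.weights, M)

    def test_top_percent_rule_retains_exact_count(self):
        rng = np.random.default_rng(8)
        v = rng.standard_normal(45)  # 10 nodes
        adj = centroid_to_state_graph(v, edge_threshold_rule="top_percent:10")
        assert adj.total_connections == int(np.ceil(0.1 * 45))

    def test_length_mismatch_rejected(self):
        meta = make_node_meta(5)
        with pytest.raises(ValueError, match="does not match"):
            centroid_to_state_graph(np.zeros(9), node_meta=meta)


class TestGraphMetricsBundle:
    def test_bundle_consistency_on_random_adjacency(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((120, 10))
        X[:, 1] = X[:, 0] + 0.3 * rng.standard_normal(120)
        R = np.corrcoef(X.T)
        meta = make_node_meta(10, rng=rng)
        adj = fdr_threshold_adjacency(R, 120, node_meta=meta)
        gm = graph_metrics(adj)
        assert gm.total_connections == adj.total_connections
        assert gm.degree.sum() == 2 * gm.total_connections
        assert 0 <= gm.mean_cc <= 1
        if gm.network_cost is not None:
            assert gm.node_cost.sum() == pytest.approx(2 * gm.network_cost)
        assert set(gm.hub_set) <= set(range(10))
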