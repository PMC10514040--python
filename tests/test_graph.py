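"""Graph construction and weighted metrics vs closed forms and oracles."""

import numpy as np
import pytest

from plvnet.graph import (
    WeightedGraph,
    global_efficiency,
    graph_metrics,
    mean_clustering,
    metrics_over_density_sweep,
    node_strength,
    threshold_proportional,
    weighted_clustering,
)


def random_weighted(n, rng, density=1.0):
    W = rng.uniform(0.05, 1.0, (n, n))
    W = np.triu(W, 1)
    if density < 1:
        mask = rng.uniform(size=W.shape) < density
        W *= np.triu(mask, 1)
    W = W + W.T
    return W


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def onnela_cc_bruteforce(W):
    """Triangle enumeration over all (j, h) pairs, max-normalized weights."""
    n = W.shape[0]
    Wn = W / W.max()
    cc = np.zeros(n)
    for i in range(n):
        k = np.count_nonzero(W[i])
        if k < 2:
            continue
        t = 0.0
        for j in range(n):
            for h in range(n):
                t += (Wn[i, j] * Wn[j, h] * Wn[i, h]) ** (1 / 3)
        cc[i] = t / (k * (k - 1))
    return cc


def ge_floyd_warshall(W):
    """All-pairs shortest paths on lengths 1/w (max-normalized), averaged inverse."""
    n = W.shape[0]
    Wn = W / W.max()
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    D[Wn > 0] = 1.0 / Wn[Wn > 0]
    for k in range(n):
        D = np.minimum(D, D[:, k : k + 1] + D[k : k + 1, :])
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv.sum() / (n * (n - 1))


class TestThresholdProportional:
    def test_density_one_preserves_matrix(self, rng):
        W = random_weighted(6, rng)
        g = threshold_proportional(W, 1.0)
        assert np.allclose(g.W, W)

    def test_top_half_of_distinct_weights_kept(self):
        vals = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]
        W = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        W[iu] = vals
        W = W + W.T
        g = threshold_proportional(W, 0.5)
        kept = sorted(g.W[iu][g.W[iu] > 0], reverse=True)
        assert kept == [0.9, 0.8, 0.7]

    def test_edge_count_at_point_08_on_64_nodes(self, rng):
        W = random_weighted(64, rng)
        g = threshold_proportional(W, 0.08)
        assert int((g.W > 0).sum() // 2) == round(0.08 * 64 * 63 / 2) == 161

    def test_tie_break_stable_by_index(self):
        W = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        W[iu] = 0.5  # all equal
        W = W + W.T
        g = threshold_proportional(W, 0.5)
        # keeps the first 3 upper-triangle positions in (i, j) order
        kept = [(i, j) for i, j in zip(*iu) if g.W[i, j] > 0]
        assert kept == [(0, 1), (0, 2), (0, 3)]

    def test_too_few_nonzero_warns_and_keeps_all(self):
        W = np.zeros((5, 5))
        W[0, 1] = W[1, 0] = 0.8
        with pytest.warns(UserWarning, match="keeping all"):
            g = threshold_proportional(W, 0.9)
        assert int((g.W > 0).sum() // 2) == 1

    def test_invalid_density_rejected(self, rng):
        with pytest.raises(ValueError):
            threshold_proportional(random_weighted(4, rng), 0.0)


class TestStrength:
    def test_complete_unit_graph(self):
        W = np.ones((4, 4)) - np.eye(4)
        assert np.allclose(node_strength(WeightedGraph(W=W)), 3.0)

    def test_star_graph(self):
        W = np.zeros((4, 4))
        W[0, 1:] = W[1:, 0] = 0.5
        s = node_strength(WeightedGraph(W=W))
        assert s[0] == pytest.approx(1.5)
        assert np.allclose(s[1:], 0.5)

    def test_equals_row_sum_oracle(self, rng):
        W = random_weighted(10, rng, density=0.6)
        s = node_strength(WeightedGraph(W=W))
        oracle = [sum(W[i, j] for j in range(10)) for i in range(10)]
        assert np.allclose(s, oracle)


class TestClustering:
    def test_unit_triangle_cc_one(self):
        W = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        assert np.allclose(weighted_clustering(WeightedGraph(W=W)), 1.0)

    def test_path_graph_cc_zero(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[1, 2] = W[2, 1] = 1.0
        assert np.allclose(weighted_clustering(WeightedGraph(W=W)), 0.0)

    def test_weighted_triangle_closed_form(self):
        # weights 1, 0.5, 0.25 -> every node t = 0.125^(1/3) = 0.5, CC = 0.5
        W = np.zeros((3, 3))
        W[0, 1] = 1.0
        W[1, 2] = 0.5
        W[0, 2] = 0.25
        W = W + W.T
        assert np.allclose(weighted_clustering(WeightedGraph(W=W)), 0.5)

    def test_matches_bruteforce_enumeration(self, rng):
        W = random_weighted(10, rng, density=0.5)
        cc = weighted_clustering(WeightedGraph(W=W))
        assert np.abs(cc - onnela_cc_bruteforce(W)).max() < 1e-10

    def test_matches_networkx_onnela(self, rng):
        import networkx as nx

        W = random_weighted(12, rng, density=0.6)
        Wn = W / W.max()
        G = nx.from_numpy_array(Wn)
        ref = nx.clustering(G, weight="weight")
        cc = weighted_clustering(WeightedGraph(W=W))
        assert np.allclose(cc, [ref[i] for i in range(12)], atol=1e-10)

    def test_scale_invariant_after_normalization(self, rng):
        W = random_weighted(8, rng)
        a = weighted_clustering(WeightedGraph(W=W))
        b = weighted_clustering(WeightedGraph(W=3.7 * W))
        assert np.allclose(a, b)


class TestGlobalEfficiency:
    def test_complete_unit_graph_is_one(self):
        W = np.ones((5, 5)) - np.eye(5)
        assert global_efficiency(WeightedGraph(W=W)) == pytest.approx(1.0)

    def test_disjoint_dyads(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = W[2, 3] = W[3, 2] = 1.0
        assert global_efficiency(WeightedGraph(W=W)) == pytest.approx(1 / 3)

    def test_matches_floyd_warshall_oracle(self, rng):
        for _ in range(3):
            W = random_weighted(5, rng, density=0.7)
            ge = global_efficiency(WeightedGraph(W=W))
            assert ge == pytest.approx(ge_floyd_warshall(W), abs=1e-10)

    def test_scale_invariant_with_normalization(self, rng):
        W = random_weighted(7, rng)
        assert global_efficiency(WeightedGraph(W=W)) == pytest.approx(
            global_efficiency(WeightedGraph(W=0.2 * W))
        )


class TestPermutationInvariance:
    def test_metrics_permute_with_node_labels(self, rng):
        W = random_weighted(9, rng, density=0.6)
        perm = rng.permutation(9)
        Wp = W[np.ix_(perm, perm)]
        m, mp = graph_metrics(WeightedGraph(W=W)), graph_metrics(WeightedGraph(W=Wp))
        assert np.allclose(mp.strength, m.strength[perm])
        assert np.allclose(mp.clustering, m.clustering[perm])
        assert mp.global_efficiency == pytest.approx(m.global_efficiency)


class TestDensitySweep:
    def test_record_count_and_monotone_ge(self, rng):
        W = random_weighted(20, rng)
        densities = tuple(float(d) for d in np.round(np.arange(0.05, 0.51, 0.05), 2))
        sweep = metrics_over_density_sweep(W, densities)
        assert len(sweep) == len(densities)
        ge = [sweep[d].global_efficiency for d in densities]
        assert np.all(np.diff(ge) >= -1e-12)

    def test_mean_clustering_reducer(self, rng):
        W = random_weighted(6, rng)
        g = WeightedGraph(W=W)
        assert mean_clustering(g) == pytest.approx(weighted_clustering(g).mean())
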