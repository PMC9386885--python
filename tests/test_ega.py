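import numpy as np
import pytest
from conftest import as_estimate, block_corr

from factorretain.arms import ARMS
from factorretain.ega import (Network, _walk_profiles, ebic_glasso, ega_count,
                              ega_count_from_corr, modularity,
                              walktrap_partition)
from factorretain.sampling import SampleMatrix, draw_from_corr


def net_from_weights(W, n=1000):
    W = np.asarray(W, float)
    signed = W.copy()
    return Network(weights=np.abs(W), partial_corr=signed, n_obs=n)


def two_triangles():
    W = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        W[a, b] = W[b, a] = 1.0
    return W


def all_partitions(items):
    """Every set partition (Bell enumeration) of a list of nodes."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1:]
        yield [[first]] + smaller


def direct_delta_sigma(W, steps, members1, members2):
    """Merge cost straight from the definition: change in the within-
    community sum of squared strength-weighted profile distances."""
    T, s = _walk_profiles(W, steps)
    n = W.shape[0]
    inv_ns = np.zeros(n)
    inv_ns[s > 0] = 1.0 / s[s > 0]

    def sigma(members):
        pc = T[list(members)].mean(axis=0)
        return sum(float(np.sum((T[v] - pc) ** 2 * inv_ns)) for v in members)

    merged = list(members1) + list(members2)
    return (sigma(merged) - sigma(members1) - sigma(members2)) / n


class TestEbicGlasso:
    def test_identity_gives_empty_network(self):
        net = ebic_glasso(np.eye(8), n=500)
        assert net.n_edges == 0
        np.testing.assert_array_equal(net.partial_corr, 0.0)

    def test_two_block_structure_recovered(self):
        # exact 2-block input: the precision matrix is block diagonal at
        # every penalty, so no between-block edge can be selected
        S = block_corr([4, 4], np.sqrt(0.6))   # within-block r = 0.6
        net = ebic_glasso(S, n=1000)
        between = net.weights[:4, 4:]
        within = net.weights[:4, :4][np.triu_indices(4, 1)]
        assert np.all(between == 0)
        assert np.all(within > 0)

    def test_partial_correlations_well_formed(self, rng):
        from conftest import random_pd_corr
        S = random_pd_corr(rng, n_items=8, n_factors=4)
        net = ebic_glasso(S, n=800)
        np.testing.assert_allclose(net.partial_corr, net.partial_corr.T,
                                   atol=1e-10)
        np.testing.assert_array_equal(np.diag(net.partial_corr), 0.0)
        np.testing.assert_allclose(net.weights, np.abs(net.partial_corr))
        np.testing.assert_allclose(net.strength, net.weights.sum(axis=1))

    def test_selected_support_stabilizes_in_n(self):
        S = block_corr([3, 3], 0.7)
        sizes = [ebic_glasso(S, n).n_edges for n in (500, 5_000, 50_000)]
        assert sizes[1] == sizes[2]
        assert sizes[0] <= sizes[1] + 1


class TestWalktrap:
    def test_identical_profiles_have_zero_distance_and_cluster_together(self):
        # nodes 0 and 1 have identical adjacency rows, hence identical walk
        # profiles and pairwise distance 0; merging is restricted to
        # adjacent pairs, but they still end up in the same community
        W = np.zeros((4, 4))
        W[0, 2] = W[2, 0] = W[1, 2] = W[2, 1] = 1.0
        W[2, 3] = W[3, 2] = 0.5
        assert direct_delta_sigma(W, 2, [0], [1]) == pytest.approx(0.0,
                                                                   abs=1e-15)
        part = walktrap_partition(net_from_weights(W), steps=2)
        assert part.assignment[0] == part.assignment[1]

    def test_two_disconnected_triangles_found(self):
        part = walktrap_partition(net_from_weights(two_triangles()))
        assert part.n_communities == 2
        assert len(set(part.assignment[:3])) == 1
        assert len(set(part.assignment[3:])) == 1

    def test_disconnected_components_never_merged(self):
        part = walktrap_partition(net_from_weights(two_triangles()))
        for level in part.levels:
            groups = [np.flatnonzero(level == c) for c in np.unique(level)]
            assert all(set(g) <= {0, 1, 2} or set(g) <= {3, 4, 5}
                       for g in groups)

    def test_ward_update_matches_direct_definition(self, rng):
        for _ in range(15):
            W = rng.uniform(0, 1, size=(6, 6))
            W = (W + W.T) / 2
            W[W < 0.45] = 0.0
            np.fill_diagonal(W, 0.0)
            if not W.sum():
                continue
            part = walktrap_partition(net_from_weights(W), steps=4)
            for i, step in enumerate(part.merge_trace):
                before = part.levels[i]
                c1, c2 = step["merged"]
                m1 = np.flatnonzero(before == c1)
                m2 = np.flatnonzero(before == c2)
                direct = direct_delta_sigma(W, 4, m1, m2)
                assert step["dsigma"] == pytest.approx(direct, abs=1e-10)

    def test_zero_strength_nodes_stay_singletons(self):
        W = two_triangles()
        W = np.pad(W, (0, 1))          # node 6 isolated
        part = walktrap_partition(net_from_weights(W))
        assert part.n_communities == 3
        assert np.sum(part.assignment == part.assignment[6]) == 1

    def test_empty_graph_all_singletons(self):
        part = walktrap_partition(net_from_weights(np.zeros((5, 5))))
        assert part.n_communities == 5


class TestModularity:
    def test_single_community_zero(self):
        W = two_triangles()
        assert modularity(net_from_weights(W), np.zeros(6, int)) == pytest.approx(0.0)

    def test_two_cliques_half(self):
        W = two_triangles()
        q = modularity(net_from_weights(W), np.array([0, 0, 0, 1, 1, 1]))
        assert q == pytest.approx(0.5)

    def test_zero_weight_graph_rejected(self):
        with pytest.raises(ValueError):
            modularity(net_from_weights(np.zeros((3, 3))), np.zeros(3, int))

    def test_selected_partition_is_exhaustive_maximum(self, rng):
        # on small graphs the max-Q level of the merge trace should attain
        # the global maximum over *all* set partitions when communities are
        # clean (disconnected cliques)
        net = net_from_weights(two_triangles())
        part = walktrap_partition(net)
        best = max(all_partitions(list(range(6))),
                   key=lambda p: modularity(
                       net, np.array([next(i for i, b in enumerate(p) if v in b)
                                      for v in range(6)])))
        q_best = modularity(net, np.array(
            [next(i for i, b in enumerate(best) if v in b) for v in range(6)]))
        assert part.modularity == pytest.approx(q_best, abs=1e-12)

    def test_trace_selection_is_argmax_over_levels(self, rng):
        W = rng.uniform(0, 1, size=(6, 6))
        W = (W + W.T) / 2
        W[W < 0.3] = 0
        np.fill_diagonal(W, 0)
        net = net_from_weights(W)
        part = walktrap_partition(net)
        qs = [modularity(net, lvl) for lvl in part.levels]
        assert part.modularity == pytest.approx(max(qs), abs=1e-12)


class TestEgaCount:
    @pytest.mark.parametrize("n_blocks", [2, 3, 4, 5])
    def test_population_block_count_recovered(self, n_blocks):
        R = block_corr([4] * n_blocks, np.sqrt(0.6))
        assert ega_count_from_corr(R, n=1000) == n_blocks

    def test_unidimensional_guard_returns_one(self, rng):
        R = block_corr([8], 0.7)
        Z = SampleMatrix(draw_from_corr(R, 1000, rng))
        assert ega_count(Z, ARMS["cont_pearson"],
                         rng=np.random.default_rng(0)) == 1

    def test_three_blocks_from_sampled_data(self, rng, three_block_corr):
        Z = SampleMatrix(draw_from_corr(three_block_corr, 1000, rng))
        assert ega_count(Z, ARMS["cont_pearson"],
                         rng=np.random.default_rng(1)) == 3

    def test_binary_arm_pipeline(self, rng, three_block_corr):
        Z = SampleMatrix(draw_from_corr(three_block_corr, 1000, rng))
        assert ega_count(Z, ARMS["d50_pearson"],
                         rng=np.random.default_rng(2)) == 3


class TestAgainstIgraph:
    """Community counts cross-checked against the reference Walktrap."""

    def _igraph_count(self, W):
        import igraph as ig
        g = ig.Graph.Weighted_Adjacency(W.tolist(), mode="undirected")
        dend = g.community_walktrap(weights="weight", steps=4)
        return len(dend.as_clustering())

    @pytest.mark.parametrize("sizes, loading", [
        ([4, 4], 0.8), ([5, 5, 5], 0.75), ([4, 4, 4, 4], 0.8)])
    def test_block_network_counts_match(self, rng, sizes, loading):
        R = block_corr(sizes, loading)
        Z = draw_from_corr(R, 2000, rng)
        net = ebic_glasso(np.corrcoef(Z, rowvar=False), n=2000,
                          lambda_min_ratio=0.1)
        mine = walktrap_partition(net).n_communities
        assert mine == self._igraph_count(net.weights) == len(sizes)
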