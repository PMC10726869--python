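import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multiplexbrain import LayerMatrix, MultiplexNetwork, metrics

from conftest import random_multiplex
import oracles


def _net_from_edges(n, edges1, edges2):
    """Two binary layers from edge lists."""
    layers = []
    for edges in (edges1, edges2):
        w = np.zeros((n, n))
        for i, j in edges:
            w[i, j] = w[j, i] = 1.0
        layers.append(LayerMatrix(w))
    return MultiplexNetwork(layers)


class TestDegreeFamily:
    def test_identical_layers_overlap_equals_degree(self):
        rng = np.random.default_rng(0)
        net = random_multiplex(rng, 6)
        net.layers[1] = LayerMatrix(net.layers[0].weights.copy())
        k = (net.layers[0].weights > 0).sum(axis=1)
        np.testing.assert_array_equal(metrics.degree_overlap(net), k)
        np.testing.assert_array_equal(metrics.overlapping_degree(net), 2 * k)

    def test_edge_disjoint_layers_have_zero_overlap(self):
        net = _net_from_edges(4, [(0, 1), (2, 3)], [(0, 2), (1, 3)])
        np.testing.assert_array_equal(metrics.degree_overlap(net), np.zeros(4))

    def test_hand_intersection(self):
        # layer1 neighbors of node 0: {1, 2}; layer2: {2, 3} -> overlap 1
        net = _net_from_edges(4, [(0, 1), (0, 2)], [(0, 2), (0, 3)])
        assert metrics.degree_overlap(net)[0] == 1

    def test_overlapping_degree_sums_layers(self):
        # k1 = 3, k2 = 1 -> O = 4
        net = _net_from_edges(4, [(0, 1), (0, 2), (0, 3)], [(0, 1)])
        assert metrics.overlapping_degree(net)[0] == 4

    def test_overlapping_strength_sums_weights(self):
        w1 = np.zeros((3, 3))
        w1[0, 1] = w1[1, 0] = 1.0
        w1[0, 2] = w1[2, 0] = 2.0
        w2 = np.zeros((3, 3))
        w2[0, 1] = w2[1, 0] = 3.0
        net = MultiplexNetwork([LayerMatrix(w1), LayerMatrix(w2)])
        assert metrics.overlapping_strength(net)[0] == pytest.approx(6.0)

    def test_empty_second_layer_reduces_to_first(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        net = MultiplexNetwork([LayerMatrix(w), LayerMatrix(np.zeros((3, 3)))])
        assert metrics.overlapping_degree(net)[0] == 1
        assert metrics.overlapping_strength(net)[0] == 1.0


class TestParticipation:
    def test_equal_degrees_give_one(self):
        net = _net_from_edges(3, [(0, 1)], [(0, 2)])
        assert metrics.multiplex_participation(net)[0] == pytest.approx(1.0)

    def test_single_layer_connection_gives_zero(self):
        net = _net_from_edges(3, [(0, 1)], [(1, 2)])
        assert metrics.multiplex_participation(net)[0] == 0.0

    def test_three_one_split_gives_0_75(self):
        net = _net_from_edges(4, [(0, 1), (0, 2), (0, 3)], [(0, 1)])
        assert metrics.multiplex_participation(net)[0] == pytest.approx(0.75)

    def test_weighted_three_one_split_gives_0_75(self):
        w1 = np.zeros((3, 3))
        w1[0, 1] = w1[1, 0] = 0.6
        w1[0, 2] = w1[2, 0] = 0.9  # s1 = 1.5
        w2 = np.zeros((3, 3))
        w2[0, 1] = w2[1, 0] = 0.5  # s2 = 0.5 -> s ratio 3:1
        net = MultiplexNetwork([LayerMatrix(w1), LayerMatrix(w2)])
        assert metrics.weighted_multiplex_participation(net)[0] == pytest.approx(0.75)

    def test_isolated_node_is_zero_not_nan(self):
        net = _net_from_edges(3, [(0, 1)], [(0, 1)])
        assert metrics.multiplex_participation(net)[2] == 0.0
        assert metrics.weighted_multiplex_participation(net)[2] == 0.0


class TestClustering:
    def test_k3_in_both_layers_gives_one_everywhere(self):
        k3 = np.ones((3, 3)) - np.eye(3)
        net = MultiplexNetwork([LayerMatrix(k3), LayerMatrix(k3.copy())])
        np.testing.assert_allclose(metrics.multiplex_clustering(net), 1.0, atol=1e-12)

    def test_no_interlayer_triangles_gives_zero(self):
        net = _net_from_edges(4, [(0, 1), (0, 2)], [(0, 3)])
        np.testing.assert_array_equal(metrics.multiplex_clustering(net), np.zeros(4))

    def test_matches_brute_force_on_random_weighted_net(self):
        rng = np.random.default_rng(1)
        net = random_multiplex(rng, 5)
        np.testing.assert_allclose(
            metrics.multiplex_clustering(net),
            oracles.oracle_multiplex_clustering(net.weight_arrays()),
            atol=1e-12,
        )

    def test_unnormalized_weights_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 5.0
        net = MultiplexNetwork([LayerMatrix(w), LayerMatrix(w.copy())])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            metrics.multiplex_clustering(net)


class TestGlobalAverage:
    def test_mean_matches_direct_summation(self):
        rng = np.random.default_rng(2)
        v = rng.random(17)
        assert metrics.global_average(v) == pytest.approx(sum(v) / 17, abs=1e-12)
        assert metrics.global_average(np.array([0.0, 1.0])) == 0.5
        assert metrics.global_average(np.full(5, 3.7)) == pytest.approx(3.7)


class TestInvariants:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_bounds_and_orderings(self, seed):
        rng = np.random.default_rng(seed)
        net = random_multiplex(rng, int(rng.integers(3, 7)))
        k = metrics.layer_degrees(net)
        overlap = metrics.degree_overlap(net)
        assert np.all(overlap <= k.min(axis=0))
        assert np.all(metrics.overlapping_degree(net) >= overlap)
        for part in (
            metrics.multiplex_participation(net),
            metrics.weighted_multiplex_participation(net),
            metrics.multiplex_clustering(net),
        ):
            assert np.all((part >= 0.0) & (part <= 1.0 + 1e-12))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        net = random_multiplex(rng, n)
        perm = rng.permutation(n)
        permuted = MultiplexNetwork(
            [LayerMatrix(layer.weights[np.ix_(perm, perm)]) for layer in net.layers]
        )
        for fn in (
            metrics.degree_overlap,
            metrics.overlapping_degree,
            metrics.overlapping_strength,
            metrics.multiplex_participation,
            metrics.weighted_multiplex_participation,
            metrics.multiplex_clustering,
        ):
            np.testing.assert_allclose(fn(permuted), fn(net)[perm], atol=1e-12)
            assert metrics.global_average(fn(permuted)) == pytest.approx(
                metrics.global_average(fn(net)), abs=1e-12
            )

    def test_identical_layers_give_full_participation(self):
        rng = np.random.default_rng(3)
        net = random_multiplex(rng, 6)
        net.layers[1] = LayerMatrix(net.layers[0].weights.copy())
        connected = metrics.overlapping_degree(net) > 0
        part = metrics.multiplex_participation(net)
        np.testing.assert_allclose(part[connected], 1.0, atol=1e-12)
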