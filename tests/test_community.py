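import numpy as np
import pytest

from multiplexbrain import (
    CommunityPartition,
    LayerMatrix,
    MultiplexNetwork,
    flexibility,
    multilayer_quality,
    optimize_partition,
    persistence,
)

from conftest import random_multiplex
import oracles


def _two_disjoint_edges_net():
    w = np.zeros((4, 4))
    w[0, 1] = w[1, 0] = 1.0
    w[2, 3] = w[3, 2] = 1.0
    return MultiplexNetwork([LayerMatrix(w), LayerMatrix(w.copy())])


class TestQualityFunction:
    def test_pair_partition_of_disjoint_edges_scores_half(self):
        net = _two_disjoint_edges_net()
        labels = np.array([[0, 0, 1, 1], [0, 0, 1, 1]])
        assert multilayer_quality(net, labels, gamma=1.0, omega=0.0) == pytest.approx(0.5)

    def test_singleton_partition_closed_form(self):
        rng = np.random.default_rng(0)
        net = random_multiplex(rng, 5)
        labels = np.arange(10).reshape(2, 5)
        w = net.weight_arrays()
        expected = 0.0
        for a in range(2):
            s = w[a].sum(axis=1)
            expected -= (s**2).sum() / w[a].sum()
        expected /= w.sum()  # 2mu with omega = 0
        assert multilayer_quality(net, labels, 1.0, 0.0) == pytest.approx(expected, abs=1e-12)

    def test_all_one_community_is_zero_newman_identity(self):
        rng = np.random.default_rng(1)
        single = random_multiplex(rng, 6).layers[0]
        net = MultiplexNetwork([single, LayerMatrix(single.weights.copy())])
        labels = np.zeros((2, 6), dtype=int)
        assert multilayer_quality(net, labels, 1.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_term_by_term_oracle(self):
        rng = np.random.default_rng(2)
        for seed in range(5):
            net = random_multiplex(rng, 5)
            labels = rng.integers(0, 3, size=(2, 5))
            for omega in (0.0, 0.7, 2.0):
                assert multilayer_quality(net, labels, 1.3, omega) == pytest.approx(
                    oracles.oracle_quality(net.weight_arrays(), labels, 1.3, omega),
                    abs=1e-12,
                )

    def test_empty_layer_rejected(self):
        net = MultiplexNetwork.__new__(MultiplexNetwork)
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        net.layers = [LayerMatrix(w), LayerMatrix(np.zeros((3, 3)))]
        with pytest.raises(ValueError, match="no edges"):
            multilayer_quality(net, np.zeros((2, 3), int), 1.0, 1.0)


class TestOptimizer:
    def test_separates_disconnected_cliques_coherently(self):
        n = 8
        w = np.zeros((n, n))
        w[:4, :4] = 1.0
        w[4:, 4:] = 1.0
        np.fill_diagonal(w, 0.0)
        net = MultiplexNetwork([LayerMatrix(w), LayerMatrix(w.copy())])
        part = optimize_partition(net, gamma=1.0, omega=1.0, restarts=10, seed=0)
        lab = part.labels
        # same label across layers, cliques separated
        np.testing.assert_array_equal(lab[0], lab[1])
        assert len(set(lab[0][:4])) == 1 and len(set(lab[0][4:])) == 1
        assert lab[0][0] != lab[0][4]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        net = random_multiplex(rng, 7)
        a = optimize_partition(net, restarts=5, seed=42)
        b = optimize_partition(net, restarts=5, seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.quality == b.quality

    def test_beats_trivial_partitions(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            net = random_multiplex(rng, 6)
            part = optimize_partition(net, restarts=10, seed=seed)
            singleton = np.arange(12).reshape(2, 6)
            allone = np.zeros((2, 6), int)
            assert part.quality >= multilayer_quality(net, singleton) - 1e-12
            assert part.quality >= multilayer_quality(net, allone) - 1e-12

    def test_quality_self_consistent_with_labels(self):
        rng = np.random.default_rng(5)
        net = random_multiplex(rng, 6)
        part = optimize_partition(net, gamma=1.1, omega=0.8, restarts=8, seed=1)
        assert part.quality == pytest.approx(
            multilayer_quality(net, part.labels, 1.1, 0.8), abs=1e-12
        )

    def test_persistence_trends_up_with_coupling(self):
        rng = np.random.default_rng(6)
        lows, highs = [], []
        for seed in range(12):
            net = random_multiplex(rng, 8)
            lows.append(persistence(optimize_partition(net, omega=0.0, restarts=6, seed=seed)))
            highs.append(persistence(optimize_partition(net, omega=2.0, restarts=6, seed=seed)))
        assert np.mean(highs) >= np.mean(lows)

    def test_invalid_parameters_rejected(self):
        rng = np.random.default_rng(7)
        net = random_multiplex(rng, 4)
        with pytest.raises(ValueError):
            optimize_partition(net, gamma=0.0)
        with pytest.raises(ValueError):
            optimize_partition(net, omega=-1.0)
        with pytest.raises(ValueError):
            optimize_partition(net, restarts=0)


def _partition(labels):
    return CommunityPartition(labels=np.asarray(labels), quality=0.0)


class TestFlexibilityPersistence:
    def test_identical_labels_zero_flexibility_full_persistence(self):
        part = _partition([[0, 1, 2, 0], [0, 1, 2, 0]])
        np.testing.assert_array_equal(flexibility(part), np.zeros(4))
        assert persistence(part) == 1.0

    def test_all_relabeled_full_flexibility_zero_persistence(self):
        part = _partition([[0, 0, 1, 1], [2, 2, 3, 3]])
        np.testing.assert_array_equal(flexibility(part), np.ones(4))
        assert persistence(part) == 0.0

    def test_three_of_four_stable(self):
        part = _partition([[0, 0, 1, 1], [0, 0, 1, 5]])
        assert flexibility(part).mean() == pytest.approx(0.25)
        assert persistence(part) == pytest.approx(0.75)
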