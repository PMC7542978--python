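import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from gaitglove.errors import AnalysisError, ValidationError
from gaitglove.glove_io import SensorRun, default_layout, select_channels
from gaitglove.network import (
    JointNetwork,
    characteristic_path_length,
    compare_to_null,
    global_efficiency,
    louvain_modules,
    mean_network,
    modularity,
    null_ensemble,
    run_correlation,
    small_world,
    threshold_network,
)
from gaitglove.synthetic import pulse_train

NODES4 = ("a", "b", "c", "d")


def planted_network(within=0.8, between=-0.4):
    """12 nodes in three 4-node groups; strong positive within, negative between."""
    nodes = tuple(f"n{i}" for i in range(12))
    W = np.full((12, 12), between)
    for g in range(3):
        sl = slice(4 * g, 4 * g + 4)
        W[sl, sl] = within
    np.fill_diagonal(W, 0.0)
    return JointNetwork(nodes=nodes, weights=W), np.repeat([0, 1, 2], 4)


def graph12_run(rng, n_frames=800):
    layout = default_layout().subset(default_layout().graph12)
    t = np.arange(n_frames) / 50.0
    base = pulse_train(t, 1.0)
    data = 500.0 + 50.0 * np.outer(base, rng.uniform(0.5, 1.0, 12))
    data += rng.normal(0, 5.0, size=data.shape)
    return SensorRun(np.clip(data, 0, 1000), 50.0, "S01", "left", 1, layout)


class TestRunCorrelation:
    def test_self_correlation_and_zero_diagonal(self, rng):
        R = run_correlation(graph12_run(rng))
        assert np.allclose(np.diag(R), 0.0)
        assert np.all(np.abs(R) <= 1.0 + 1e-12)

    def test_identical_channels_unit_correlation(self, rng):
        run = graph12_run(rng)
        run.data[:, 1] = run.data[:, 0]
        R = run_correlation(run)
        assert R[0, 1] == pytest.approx(1.0)

    def test_antiphase_negative(self):
        layout = default_layout().subset(default_layout().graph12)
        t = np.arange(800) / 50.0
        a = pulse_train(t, 1.0, 0.0, waveform="sine")
        data = np.tile(500.0 + 100.0 * a[:, None], (1, 12))
        data[:, 5] = 500.0 - 100.0 * a
        run = SensorRun(data, 50.0, "S01", "left", 1, layout)
        R = run_correlation(run)
        assert R[0, 5] < -0.99

    def test_zero_variance_channel_named(self, rng):
        run = graph12_run(rng)
        run.data[:, 3] = 400.0
        with pytest.raises(AnalysisError, match=run.layout.labels[3]):
            run_correlation(run)


class TestMeanAndThreshold:
    def test_single_matrix_identity(self, rng):
        R = run_correlation(graph12_run(rng))
        nodes = default_layout().graph12
        net = mean_network([R], nodes)
        np.testing.assert_allclose(net.weights, R)

    def test_cancellation(self):
        nodes = tuple(f"n{i}" for i in range(3))
        M = np.array([[0, 0.5, -0.2], [0.5, 0, 0.1], [-0.2, 0.1, 0]])
        net = mean_network([M, -M], nodes)
        assert np.allclose(net.weights, 0.0)

    def test_threshold_zero_keeps_positive(self):
        net, _ = planted_network()
        pos = threshold_network(net, 0.0, "positive")
        assert np.all(pos.weights >= 0)
        assert np.sum(pos.weights > 0) == np.sum(net.weights > 0)

    def test_threshold_above_max_empties(self):
        net, _ = planted_network(within=0.3, between=0.1)
        assert np.all(threshold_network(net, 0.35, "positive").weights == 0)

    def test_threshold_separates_planted_modules(self):
        net, truth = planted_network()
        pos = threshold_network(net, 0.35, "positive")
        for i in range(12):
            for j in range(12):
                if i != j and pos.weights[i, j] != 0:
                    assert truth[i] == truth[j]

    def test_edge_count_66(self):
        net, _ = planted_network()
        assert net.edge_weights().size == 66


class TestGlobalEfficiency:
    def test_complete_unit_graph(self):
        W = np.ones((4, 4)) - np.eye(4)
        assert global_efficiency(JointNetwork(NODES4, W)) == pytest.approx(1.0)

    def test_two_isolated_nodes(self):
        assert global_efficiency(JointNetwork(("a", "b"), np.zeros((2, 2)))) == 0.0

    def test_path_graph_hand_enumerated(self):
        # path a-b-c-d with unit weights: pairwise efficiencies
        # 3 x 1 (adjacent) + 2 x 1/2 (distance 2) + 1 x 1/3 = 13/3 over 6 pairs
        W = np.zeros((4, 4))
        for i in range(3):
            W[i, i + 1] = W[i + 1, i] = 1.0
        e = global_efficiency(JointNetwork(NODES4, W))
        assert e == pytest.approx((3 * 1 + 2 * 0.5 + 1 / 3) / 6, abs=1e-12)

    def test_thresholding_cannot_increase_efficiency(self):
        net, _ = planted_network()
        e_full = global_efficiency(net)
        for tau in np.arange(0.0, 1.0, 0.05):
            e_thr = global_efficiency(threshold_network(net, tau, "positive"))
            assert e_thr <= e_full + 1e-12


class TestNullEnsemble:
    def test_weight_multiset_preserved(self):
        net, _ = planted_network()
        for g in null_ensemble(net, n_graphs=5, iterations=200, seed=1):
            np.testing.assert_allclose(
                np.sort(g.edge_weights()), np.sort(net.edge_weights())
            )

    def test_seed_reproducibility(self):
        net, _ = planted_network()
        e1 = null_ensemble(net, n_graphs=3, seed=9)
        e2 = null_ensemble(net, n_graphs=3, seed=9)
        for a, b in zip(e1, e2):
            np.testing.assert_array_equal(a.weights, b.weights)

    def test_metric_at_ensemble_median_high_p(self):
        net, _ = planted_network()
        ens = null_ensemble(net, n_graphs=30, seed=2)
        vals = np.array([global_efficiency(g) for g in ens])
        p = compare_to_null(float(np.median(vals)), vals)
        assert p > 0.5


class TestSmallWorld:
    def test_phi_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            W = rng.uniform(0.1, 0.9, size=(10, 10))
            W = 0.5 * (W + W.T)
            np.fill_diagonal(W, 0.0)
            net = JointNetwork(tuple(f"n{i}" for i in range(10)), W)
            phi, _ = small_world(net, n_null=10, seed=3)
            assert 0.0 <= phi <= 1.0

    def test_random_graph_sigma_near_one(self):
        rng = np.random.default_rng(4)
        W = rng.uniform(0.2, 0.8, size=(12, 12))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        net = JointNetwork(tuple(f"n{i}" for i in range(12)), W)
        _, sigma = small_world(net, n_null=30, seed=5)
        assert sigma == pytest.approx(1.0, abs=0.15)

    def test_ring_lattice_with_shortcuts_sigma_above_one(self):
        n = 12
        W = np.zeros((n, n))
        for i in range(n):
            for d in (1, 2):
                W[i, (i + d) % n] = W[(i + d) % n, i] = 0.9
        # a few weak shortcuts
        for i, j in ((0, 6), (3, 9)):
            W[i, j] = W[j, i] = 0.3
        net = JointNetwork(tuple(f"n{i}" for i in range(n)), W)
        _, sigma = small_world(net, n_null=30, seed=6)
        assert sigma > 1.0

    def test_disconnected_rejected(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        with pytest.raises(AnalysisError):
            characteristic_path_length(JointNetwork(NODES4, W))


class TestLouvain:
    def test_two_positive_cliques(self):
        W = np.zeros((8, 8))
        W[:4, :4] = 0.9
        W[4:, 4:] = 0.9
        np.fill_diagonal(W, 0.0)
        net = JointNetwork(tuple(f"n{i}" for i in range(8)), W)
        modules, q = louvain_modules(net, seed=0, restarts=20)
        labels = [modules[n] for n in net.nodes]
        assert len(set(labels)) == 2
        assert len({labels[i] for i in range(4)}) == 1
        assert len({labels[i] for i in range(4, 8)}) == 1
        assert q > 0

    def test_planted_three_modules(self):
        net, truth = planted_network()
        modules, _ = louvain_modules(net, seed=1, restarts=20)
        found = [modules[n] for n in net.nodes]
        assert adjusted_rand_score(truth, found) == 1.0

    def test_node_relabeling_permutes_modules(self):
        net, _ = planted_network()
        perm = np.random.default_rng(3).permutation(12)
        net_p = JointNetwork(
            tuple(net.nodes[i] for i in perm), net.weights[np.ix_(perm, perm)]
        )
        m1, _ = louvain_modules(net, seed=2, restarts=20)
        m2, _ = louvain_modules(net_p, seed=2, restarts=20)
        # same grouping of node names regardless of order
        part1 = {}
        for n, c in m1.items():
            part1.setdefault(c, set()).add(n)
        part2 = {}
        for n, c in m2.items():
            part2.setdefault(c, set()).add(n)
        assert sorted(map(sorted, part1.values())) == sorted(map(sorted, part2.values()))

    def test_all_zero_network_singletons(self):
        net = JointNetwork(NODES4, np.zeros((4, 4)))
        modules, q = louvain_modules(net, seed=0, restarts=5)
        assert sorted(modules.values()) == [0, 1, 2, 3]
        assert q == 0.0

    def test_modularity_of_planted_beats_merged(self):
        net, truth = planted_network()
        q_true = modularity(net, truth)
        q_merged = modularity(net, np.zeros(12, dtype=int))
        assert q_true > q_merged


class TestJointNetworkInvariants:
    def test_asymmetric_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = 0.5
        with pytest.raises(ValidationError):
            JointNetwork(("a", "b", "c"), W)

    def test_out_of_range_rejected(self):
        W = np.full((3, 3), 1.5)
        np.fill_diagonal(W, 0.0)
        with pytest.raises(ValidationError):
            JointNetwork(("a", "b", "c"), W)
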