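import numpy as np
import pytest

from flocknet import (
    AffiliationNetwork,
    OccupancySequences,
    SimConfig,
    baseline_network,
    baseline_weight,
    binary_network,
    connectivity_stats,
    fit_categorical,
    prune,
    segment_averaged_network,
    simulate,
    test_all_pairs,
)
from flocknet.affiliation_test import PairTestResult


def make_result(a, b, e_obs, beta, H=10, alpha=0.05):
    return PairTestResult(
        pair=(a, b),
        e_obs=e_obs,
        n_times=H,
        p_value=0.5,
        beta=beta,
        alpha=alpha,
        model_kind="categorical",
        p_series=np.full(H, 0.3),
    )


class TestBaselineWeight:
    @pytest.mark.parametrize(
        "e_obs,beta,H,expected",
        [
            (5, 5, 10, 0.0),  # not significant: weight zero
            (10, 3, 10, 1.0),  # maximal co-occurrence
            (65, 30, 100, 0.5),
            (3, -1, 10, 4 / 11),  # guarded vacuous critical value
        ],
    )
    def test_values(self, e_obs, beta, H, expected):
        assert baseline_weight(e_obs, beta, H) == pytest.approx(expected)

    def test_strictly_increasing_above_beta(self):
        ws = [baseline_weight(e, 30, 100) for e in range(31, 101)]
        assert all(a < b for a, b in zip(ws, ws[1:]))

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            baseline_weight(11, 3, 10)
        with pytest.raises(ValueError):
            baseline_weight(3, -2, 10)


class TestBinaryNetwork:
    def test_no_rejections_empty(self):
        results = [make_result("a", "b", 2, 5), make_result("a", "c", 1, 5),
                   make_result("b", "c", 0, 5)]
        net = binary_network(results, ["a", "b", "c"])
        assert net.edge_count() == 0

    def test_all_rejections_complete(self):
        results = [make_result("a", "b", 9, 5), make_result("a", "c", 8, 5),
                   make_result("b", "c", 7, 5)]
        net = binary_network(results, ["a", "b", "c"])
        assert net.edge_count() == 3

    def test_missing_pair_errors(self):
        with pytest.raises(ValueError, match="pairs"):
            binary_network([make_result("a", "b", 9, 5)], ["a", "b", "c"])

    def test_relabelling_equivariance(self):
        results = [make_result("a", "b", 9, 5), make_result("a", "c", 1, 5),
                   make_result("b", "c", 7, 5)]
        net = binary_network(results, ["a", "b", "c"])
        perm_net = binary_network(results, ["c", "a", "b"])
        for u, v in (("a", "b"), ("a", "c"), ("b", "c")):
            i, j = net.nodes.index(u), net.nodes.index(v)
            pi, pj = perm_net.nodes.index(u), perm_net.nodes.index(v)
            assert net.weights[i, j] == perm_net.weights[pi, pj]

    def test_subflock_structure_recovered(self):
        cfg = SimConfig(seed=33, n_animals=10, n_times=400, n_cells=16,
                        scenario="subflocks", rho=0.6, group_sizes=(5, 5))
        occ = simulate(cfg)
        models = [fit_categorical(occ, n) for n in range(10)]
        net = binary_network(
            test_all_pairs(occ, models, 0.005), list(occ.animal_ids)
        )
        cs = connectivity_stats(net, cfg.group_labels())
        assert min(cs.within_connectivity) > cs.between_connectivity


class TestSegmentAveraging:
    def _segments(self, k, seed=0):
        rng = np.random.default_rng(seed)
        return [
            OccupancySequences(rng.integers(0, 3, size=(40, 4)), 3,
                               ["a", "b", "c", "d"])
            for _ in range(k)
        ]

    def test_single_segment_equals_binary(self):
        segs = self._segments(1)
        net = segment_averaged_network(segs, alpha=0.05)
        stacked = segs[0]
        ref = binary_network(
            test_all_pairs(stacked, fit_categorical(stacked, "pooled"), 0.05),
            list(stacked.animal_ids),
        )
        np.testing.assert_array_equal(net.weights, ref.weights)

    def test_weights_are_mean_of_binary_adjacency(self):
        segs = self._segments(5, seed=3)
        net = segment_averaged_network(segs, alpha=0.05, train="per_segment")
        mean = np.zeros((4, 4))
        for occ in segs:
            res = test_all_pairs(occ, fit_categorical(occ, "pooled"), 0.05)
            mean += binary_network(res, list(occ.animal_ids)).weights
        np.testing.assert_allclose(net.weights, mean / 5)

    def test_independent_segments_mostly_empty(self):
        segs = self._segments(6, seed=9)
        net = segment_averaged_network(segs, alpha=0.001)
        assert net.weights.max() <= 1 / 6 + 1e-12

    def test_fractional_weight_from_partial_support(self):
        # a pair identical in 4 of 6 segments gets weight 4/6
        rng = np.random.default_rng(4)
        segs = []
        for k in range(6):
            idx = rng.integers(0, 4, size=(60, 3))
            if k < 4:
                idx[:, 1] = idx[:, 0]
            segs.append(OccupancySequences(idx, 4, ["a", "b", "c"]))
        net = segment_averaged_network(segs, alpha=0.005, train="per_segment")
        i, j = net.nodes.index("a"), net.nodes.index("b")
        assert net.weights[i, j] == pytest.approx(4 / 6)

    def test_mismatched_animals_error(self):
        segs = self._segments(2)
        segs[1] = OccupancySequences(segs[1].indices, 3, ["a", "b", "c", "e"])
        with pytest.raises(ValueError, match="share"):
            segment_averaged_network(segs)

    def test_markov_global_training_runs(self):
        segs = self._segments(3, seed=12)
        net = segment_averaged_network(segs, alpha=0.05, model_kind="markov")
        assert net.kind == "weighted"
        assert np.all(net.weights >= 0) and np.all(net.weights <= 1)


class TestPrune:
    def _net(self, weights):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = weights[0]
        W[0, 2] = W[2, 0] = weights[1]
        W[1, 2] = W[2, 1] = weights[2]
        return AffiliationNetwork(["a", "b", "c"], W)

    def test_strict_less_than_semantics(self):
        net = prune(self._net([0.05, 0.1, 0.2]), 0.1)
        assert net.weights[0, 1] == 0.0
        assert net.weights[0, 2] == 0.1  # equal to threshold survives
        assert net.weights[1, 2] == 0.2

    def test_threshold_zero_is_identity(self):
        net = self._net([0.05, 0.1, 0.2])
        np.testing.assert_array_equal(prune(net, 0.0).weights, net.weights)

    def test_threshold_one_keeps_only_full_weights(self):
        net = prune(self._net([1.0, 0.99, 0.5]), 1.0)
        assert net.edge_count() == 1


class TestConnectivityStats:
    def test_complete_graph(self):
        W = 1.0 - np.eye(4)
        net = AffiliationNetwork(list("abcd"), W, kind="binary")
        cs = connectivity_stats(net, ["g1", "g1", "g2", "g2"])
        assert cs.within_connectivity == (1.0, 1.0)
        assert cs.between_connectivity == 1.0

    def test_block_diagonal(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        net = AffiliationNetwork(list("abcd"), W, kind="binary")
        cs = connectivity_stats(net, ["g1", "g1", "g2", "g2"])
        assert cs.between_connectivity == 0.0
        assert "between" in cs.empty_blocks
        assert cs.between_mean_weight == 0.0

    def test_planted_weighted_blocks_hand_computed(self):
        nodes = list("abcde")
        labels = ["g1", "g1", "g1", "g2", "g2"]
        W = np.zeros((5, 5))
        pairs = {(0, 1): 0.4, (0, 2): 0.2, (3, 4): 0.6, (0, 3): 0.1}
        for (i, j), w in pairs.items():
            W[i, j] = W[j, i] = w
        net = AffiliationNetwork(nodes, W)
        cs = connectivity_stats(net, labels)
        assert cs.within_connectivity == (pytest.approx(2 / 3), 1.0)
        assert cs.between_connectivity == pytest.approx(1 / 6)
        assert cs.within_mean_weight == (pytest.approx(0.3), pytest.approx(0.6))
        assert cs.between_mean_weight == pytest.approx(0.1)

    def test_more_than_two_groups_rejected(self):
        net = AffiliationNetwork(list("abcd"), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            connectivity_stats(net, ["g1", "g2", "g3", "g1"])


class TestRoundTrips:
    def _net(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.25
        W[1, 2] = W[2, 1] = 0.75
        return AffiliationNetwork(["a", "b", "c"], W)

    def test_edgelist(self, tmp_path):
        net = self._net()
        path = tmp_path / "edges.csv"
        net.to_edgelist(path)
        back = AffiliationNetwork.from_edgelist(path, net.nodes)
        np.testing.assert_allclose(back.weights, net.weights)

    def test_graphml(self, tmp_path):
        net = self._net()
        path = tmp_path / "net.graphml"
        net.to_graphml(path, labels={"a": "g1", "b": "g1", "c": "g2"})
        back = AffiliationNetwork.from_graphml(path)
        assert set(back.nodes) == set(net.nodes)
        i, j = back.nodes.index("b"), back.nodes.index("c")
        assert back.weights[i, j] == pytest.approx(0.75)
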