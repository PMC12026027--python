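"""Graph metrics against closed forms and the exhaustive path oracle."""

import numpy as np
import pytest

from _oracles import global_path_length_bf, graph_metrics_bf
from miadapt import BinaryNetwork, global_path_length, hemisphere_summary, node_metrics
from miadapt.netmetrics import LEFT_KEY_15, RIGHT_KEY_15


def net(A, names=None):
    A = np.asarray(A, dtype=int)
    names = names or tuple(f"n{i}" for i in range(len(A)))
    return BinaryNetwork(A, names, fraction=1.0)


def complete(n):
    return np.ones((n, n), dtype=int) - np.eye(n, dtype=int)


class TestClosedForms:
    def test_complete_graph_k5(self):
        m = node_metrics(net(complete(5)))
        assert np.all(m.degree == 4)
        assert np.allclose(m.clustering, 1.0)
        assert np.allclose(m.path_length, 1.0)
        assert np.allclose(m.betweenness, 0.0)
        assert global_path_length(net(complete(5))) == pytest.approx(1.0)

    def test_path_graph(self):
        A = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
        m = node_metrics(net(A))
        assert list(m.degree) == [1, 2, 1]
        assert np.allclose(m.clustering, 0.0)
        assert global_path_length(net(A)) == pytest.approx(4 / 3)
        assert m.betweenness[1] == pytest.approx(1.0)
        assert m.betweenness[0] == m.betweenness[2] == 0.0

    def test_star_graph(self):
        A = np.zeros((5, 5), dtype=int)
        A[0, 1:] = A[1:, 0] = 1
        m = node_metrics(net(A))
        assert m.betweenness[0] == pytest.approx(6.0)  # all 6 leaf pairs
        assert np.allclose(m.local_efficiency[1:], 0.0)  # single-neighbor subgraphs
        assert np.allclose(m.betweenness[1:], 0.0)

    def test_isolated_node_has_nan_path_length(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = A[1, 0] = 1
        m = node_metrics(net(A))
        assert np.isnan(m.path_length[2])
        assert m.degree[2] == 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("batch", range(4))
    def test_random_graphs_match_enumeration(self, batch):
        """Every metric agrees exactly with exhaustive simple-path
        enumeration on random graphs of up to 8 nodes (50 per batch)."""
        rng = np.random.default_rng(1000 + batch)
        for _ in range(50):
            n = int(rng.integers(2, 9))
            p = rng.uniform(0.15, 0.9)
            A = (rng.uniform(size=(n, n)) < p).astype(int)
            A = np.triu(A, 1)
            A = A + A.T
            m = node_metrics(net(A))
            bf = graph_metrics_bf(A)
            assert np.array_equal(m.degree, bf["degree"])
            assert np.allclose(m.clustering, bf["clustering"], atol=1e-12)
            assert np.allclose(m.path_length, bf["path_length"],
                               atol=1e-12, equal_nan=True)
            assert np.allclose(m.local_efficiency, bf["local_efficiency"], atol=1e-12)
            assert np.allclose(m.betweenness, bf["betweenness"], atol=1e-9)
            # invariants along the way
            assert np.all((m.local_efficiency >= 0) & (m.local_efficiency <= 1))
            assert np.all(m.betweenness[m.degree <= 1] == 0)
            assert m.degree.sum() % 2 == 0

    def test_isomorphism_invariance(self, rng):
        n = 7
        A = (rng.uniform(size=(n, n)) < 0.4).astype(int)
        A = np.triu(A, 1)
        A = A + A.T
        perm = rng.permutation(n)
        P = np.eye(n, dtype=int)[perm]
        m1 = node_metrics(net(A))
        m2 = node_metrics(net(P @ A @ P.T))
        for key in ("degree", "clustering", "path_length", "local_efficiency",
                    "betweenness"):
            assert np.allclose(m1.by_key({"degree": "K", "clustering": "C",
                                          "path_length": "L",
                                          "local_efficiency": "E",
                                          "betweenness": "BC"}[key])[perm],
                               m2.by_key({"degree": "K", "clustering": "C",
                                          "path_length": "L",
                                          "local_efficiency": "E",
                                          "betweenness": "BC"}[key]),
                               atol=1e-9, equal_nan=True)


class TestGlobalPathLength:
    def test_disconnected_cliques_exclude_cross_pairs(self):
        A = np.zeros((6, 6), dtype=int)
        A[np.ix_([0, 1, 2], [0, 1, 2])] = complete(3)
        A[np.ix_([3, 4, 5], [3, 4, 5])] = complete(3)
        L, excluded = global_path_length(net(A), return_excluded=True)
        L_bf, excl_bf = global_path_length_bf(A, range(6))
        assert L == pytest.approx(L_bf)
        assert excluded == excl_bf == 18  # 3x3 cross pairs, both directions

    def test_subset_restriction(self):
        A = complete(4)
        assert global_path_length(net(A), nodes=[0, 1]) == pytest.approx(1.0)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            global_path_length(net(complete(3)), nodes=[0])

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            global_path_length(net(complete(3)), nodes=[])


class TestHemisphereSummary:
    def mirror_names(self):
        return LEFT_KEY_15 + RIGHT_KEY_15

    def test_mirror_symmetric_network_zero_differences(self, rng):
        """A network whose right block mirrors the left gives zero
        left-minus-right differences."""
        B = (rng.uniform(size=(15, 15)) < 0.3).astype(int)
        B = np.triu(B, 1)
        B = B + B.T
        A = np.zeros((30, 30), dtype=int)
        A[:15, :15] = B
        A[15:, 15:] = B
        network = net(A, names=self.mirror_names())
        hs = hemisphere_summary(node_metrics(network), network)
        for d in (hs.KD, hs.CD, hs.LD, hs.ED, hs.BCD):
            assert d == pytest.approx(0.0, abs=1e-12)

    def test_left_clique_positive_degree_difference(self):
        A = np.zeros((30, 30), dtype=int)
        A[:15, :15] = complete(15)
        network = net(A, names=self.mirror_names())
        hs = hemisphere_summary(node_metrics(network), network)
        assert hs.KD > 0
        assert hs.KL == pytest.approx(14.0)
        assert hs.KR == pytest.approx(0.0)

    def test_default_electrode_sets(self):
        assert LEFT_KEY_15 == ("F5", "F3", "F1", "FC5", "FC3", "FC1",
                               "C5", "C3", "C1", "CP5", "CP3", "CP1",
                               "P5", "P3", "P1")
        assert RIGHT_KEY_15 == ("F6", "F4", "F2", "FC6", "FC4", "FC2",
                                "C6", "C4", "C2", "CP6", "CP4", "CP2",
                                "P6", "P4", "P2")

    def test_wrong_set_size_rejected(self):
        network = net(complete(30), names=self.mirror_names())
        with pytest.raises(ValueError, match="15"):
            hemisphere_summary(node_metrics(network), network,
                               left=LEFT_KEY_15[:10], right=RIGHT_KEY_15)


def test_asymmetric_adjacency_rejected():
    A = np.zeros((3, 3), dtype=int)
    A[0, 1] = 1
    with pytest.raises(ValueError, match="symmetric"):
        BinaryNetwork(A, ("a", "b", "c"), fraction=1.0)


def test_self_loop_rejected():
    A = np.eye(3, dtype=int)
    with pytest.raises(ValueError, match="diagonal"):
        BinaryNetwork(A, ("a", "b", "c"), fraction=1.0)
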