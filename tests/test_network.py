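"""Adjacency construction, graph metrics against brute-force oracles,
degree-sequence realization, and export round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_betweenness
from grangernet.granger import GrangerPairResult
from grangernet.network import (CausalNetwork, betweenness_centrality,
                                build_adjacency, centrality_report,
                                degree_centralities, density, export_graph,
                                hub_report, read_edgelist,
                                realize_degree_sequence, round2)


def result(cause, effect, wald, p):
    theta = np.array([0.1, wald / 10.0])
    return GrangerPairResult(cause=cause, effect=effect, lag_order=1,
                             theta_within=theta, theta_hpj=theta, wald=wald,
                             df=1, p_value=p, n_effective=48,
                             variance_mode="clustered")


class TestBuildAdjacency:
    def test_all_insignificant_gives_zero_matrix(self):
        rs = [result("a", "b", 2.0, 0.2), result("b", "a", 1.0, 0.5)]
        net = build_adjacency(rs, alpha=0.05)
        assert net.n_edges == 0

    def test_single_significant_edge_wald_weight(self):
        rs = [result("x", "y", 7.1, 0.008), result("y", "x", 0.5, 0.6)]
        net = build_adjacency(rs, alpha=0.05, weight_mode="wald")
        assert net.edges() == [("x", "y", 7.1)]

    def test_one_minus_p_weights_bounded(self):
        rs = [result("x", "y", 7.1, 0.008), result("y", "x", 9.0, 0.001)]
        net = build_adjacency(rs, alpha=0.05, weight_mode="one_minus_p")
        for _, _, w in net.edges():
            assert 0.95 < w <= 1.0

    def test_duplicate_pair_rejected(self):
        rs = [result("x", "y", 1.0, 0.5), result("x", "y", 2.0, 0.4)]
        with pytest.raises(ValueError, match="duplicate"):
            build_adjacency(rs)

    def test_missing_pair_warned_as_absent(self):
        warnings = []
        rs = [result("x", "y", 7.0, 0.01)]
        net = build_adjacency(rs, nodes=("x", "y", "z"), warn=warnings.append)
        assert net.n_edges == 1
        assert len(warnings) == 5   # 6 ordered pairs, 1 covered

    def test_self_loop_and_negative_weight_invariants(self):
        with pytest.raises(ValueError, match="self-loops"):
            CausalNetwork(("a", "b"), np.array([[1.0, 0], [0, 0]]))
        with pytest.raises(ValueError, match="non-negative"):
            CausalNetwork(("a", "b"), np.array([[0, -1.0], [0, 0]]))


class TestMetrics:
    def test_degree_centrality_published_extremes(self):
        # 5 of 7 incoming edges -> 0.71; 6 of 7 -> 0.86 (2 dp)
        w = np.zeros((8, 8))
        w[1:6, 0] = 1.0
        net = CausalNetwork(tuple("abcdefgh"), w)
        indeg, _ = degree_centralities(net)["a"]
        assert round2(indeg) == pytest.approx(0.71)
        w[6, 0] = 1.0
        indeg, _ = degree_centralities(CausalNetwork(tuple("abcdefgh"), w))["a"]
        assert round2(indeg) == pytest.approx(0.86)

    def test_isolated_node_zero(self):
        net = CausalNetwork(("a", "b", "c"),
                            np.array([[0, 1.0, 0], [0, 0, 0], [0, 0, 0]]))
        assert degree_centralities(net)["c"] == (0.0, 0.0)

    def test_betweenness_path_and_complete(self):
        path = CausalNetwork(("a", "b", "c"),
                             np.array([[0, 1.0, 0], [0, 0, 1.0], [0, 0, 0]]))
        assert betweenness_centrality(path)["b"] == pytest.approx(0.5)
        n = 5
        complete = CausalNetwork(tuple(f"n{i}" for i in range(n)),
                                 np.ones((n, n)) - np.eye(n))
        assert all(v == 0 for v in betweenness_centrality(complete).values())

    def test_betweenness_matches_bruteforce_on_random_digraphs(self):
        rng = np.random.default_rng(0)
        nodes = tuple(f"n{i}" for i in range(8))
        for _ in range(25):
            adj = (rng.random((8, 8)) < 0.25).astype(float)
            np.fill_diagonal(adj, 0)
            net = CausalNetwork(nodes, adj)
            mine = betweenness_centrality(net)
            oracle = brute_force_betweenness(adj)
            assert np.allclose([mine[v] for v in nodes], oracle, atol=1e-12)

    def test_density_examples(self):
        nodes = tuple(f"n{i}" for i in range(8))
        w = np.zeros((8, 8))
        idx = [(j, k) for j in range(8) for k in range(8) if j != k][:26]
        for j, k in idx:
            w[j, k] = 1.0
        assert round2(density(CausalNetwork(nodes, w))) == pytest.approx(0.46)
        assert density(CausalNetwork(nodes, np.zeros((8, 8)))) == 0.0
        full = np.ones((8, 8)) - np.eye(8)
        assert density(CausalNetwork(nodes, full)) == 1.0

    @given(st.integers(0, 2 ** 30))
    @settings(max_examples=30, deadline=None)
    def test_degree_conservation(self, seed):
        # sum of in-counts == sum of out-counts == edge count; density is
        # the mean of either centrality
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        adj = (rng.random((n, n)) < 0.3).astype(float)
        np.fill_diagonal(adj, 0)
        net = CausalNetwork(tuple(f"n{i}" for i in range(n)), adj)
        deg = degree_centralities(net)
        in_counts = sum(d[0] for d in deg.values()) * (n - 1)
        out_counts = sum(d[1] for d in deg.values()) * (n - 1)
        assert in_counts == pytest.approx(net.n_edges)
        assert out_counts == pytest.approx(net.n_edges)
        assert density(net) == pytest.approx(
            np.mean([d[0] for d in deg.values()]))


class TestRealizeDegreeSequence:
    def test_single_edge(self):
        net = realize_degree_sequence([1, 0], [0, 1])
        assert net.edges() == [("v0", "v1", 1.0)]

    def test_two_cycle_forced(self):
        net = realize_degree_sequence([1, 1], [1, 1])
        assert {(c, e) for c, e, _ in net.edges()} == {("v0", "v1"), ("v1", "v0")}

    @pytest.mark.parametrize("out_deg,in_deg,n_edges,dens", [
        ([4, 2, 3, 5, 2, 5, 1, 4], [3, 3, 4, 2, 5, 4, 2, 3], 26, 0.46),
        ([3, 5, 4, 4, 4, 2, 3, 2], [6, 3, 2, 1, 5, 4, 4, 2], 27, 0.48),
        ([2, 1, 4, 0, 1, 1, 2, 2], [3, 1, 2, 3, 0, 2, 0, 2], 13, 0.23),
    ])
    def test_diet_condition_sequences(self, out_deg, in_deg, n_edges, dens):
        net = realize_degree_sequence(out_deg, in_deg)
        b = net.binary()
        assert np.array_equal(b.sum(axis=1), out_deg)
        assert np.array_equal(b.sum(axis=0), in_deg)
        assert net.n_edges == n_edges
        assert round2(density(net)) == pytest.approx(dens)

    @pytest.mark.parametrize("out_deg,in_deg,match", [
        ([2, 0], [0, 1], "sum"),
        ([2, 0], [0, 2], "outside"),
        ([1, 1, 0], [2, 0, 0], "stubs"),   # v0 cannot receive from itself twice
    ])
    def test_infeasible_sequences_explained(self, out_deg, in_deg, match):
        with pytest.raises(ValueError, match=match):
            realize_degree_sequence(out_deg, in_deg)

    def test_deterministic(self):
        a = realize_degree_sequence([1, 2, 0], [1, 1, 1])
        b = realize_degree_sequence([1, 2, 0], [1, 1, 1])
        assert np.array_equal(a.weights, b.weights)


class TestReports:
    def test_all_zero_graph_full_tie(self):
        net = CausalNetwork(("a", "b", "c"), np.zeros((3, 3)))
        hubs = hub_report(centrality_report(net))
        for metric in hubs.values():
            assert metric["tie"] and set(metric["nodes"]) == {"a", "b", "c"}
            assert metric["value"] == 0

    def test_single_edge_source_and_sink(self):
        net = CausalNetwork(("src", "snk"), np.array([[0, 2.0], [0, 0]]))
        hubs = hub_report(centrality_report(net))
        assert hubs["outdegree_centrality"]["nodes"] == ["src"]
        assert hubs["indegree_centrality"]["nodes"] == ["snk"]

    def test_top_indegree_matches_recount(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            adj = (rng.random((8, 8)) < 0.3).astype(float)
            np.fill_diagonal(adj, 0)
            net = CausalNetwork(tuple(f"n{i}" for i in range(8)), adj)
            hubs = hub_report(centrality_report(net))
            top = hubs["indegree_centrality"]["nodes"][0]
            col = list(net.nodes).index(top)
            assert adj[:, col].sum() == adj.sum(axis=0).max()


class TestExport:
    def test_edgelist_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        w = rng.random((5, 5)) * (rng.random((5, 5)) < 0.4)
        np.fill_diagonal(w, 0)
        net = CausalNetwork(tuple("abcde"), w)
        path = str(tmp_path / "edges.tsv")
        export_graph(net, path, "edgelist-tsv")
        back = read_edgelist(path, nodes=net.nodes)
        assert np.array_equal(back.weights, net.weights)

    def test_empty_graph_header_only(self, tmp_path):
        net = CausalNetwork(("a", "b"), np.zeros((2, 2)))
        path = str(tmp_path / "edges.tsv")
        export_graph(net, path, "edgelist-tsv")
        assert open(path).read() == "cause\teffect\tweight\n"

    def test_graphml_round_trip_via_networkx(self, tmp_path):
        import networkx as nx

        net = CausalNetwork(("a", "b"), np.array([[0, 1.5], [0, 0]]))
        path = str(tmp_path / "g.graphml")
        export_graph(net, path, "graphml")
        g = nx.read_graphml(path)
        assert g["a"]["b"]["weight"] == 1.5

    def test_dot_is_syntactically_plausible(self, tmp_path):
        net = CausalNetwork(("alpha Klotho", "PTH"),
                            np.array([[0, 3.25], [0, 0]]))
        path = str(tmp_path / "g.dot")
        export_graph(net, path, "dot")
        text = open(path).read()
        assert text.startswith("digraph") and text.rstrip().endswith("}")
        assert '"alpha Klotho" -> "PTH"' in text

    def test_unknown_format_rejected(self, tmp_path):
        net = CausalNetwork(("a", "b"), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="format"):
            export_graph(net, str(tmp_path / "x"), "gexf")
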