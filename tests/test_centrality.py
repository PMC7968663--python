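"""Centrality measures against independent oracles and networkx cross-checks."""

import random
import warnings

import networkx as nx
import numpy as np
import pytest

from dtnet.centrality import (
    Sense,
    all_pairs_distances,
    betweenness_centrality,
    closeness_centrality,
    degree_centrality,
    eigenvector_centrality,
    top_k,
)

from conftest import (
    brute_force_betweenness,
    floyd_warshall,
    net_from_pairs,
    random_directed_pairs,
)


class TestDegreeCentrality:
    def test_star_center_is_one(self):
        net = net_from_pairs([("c", f"t{i}") for i in range(5)])
        scores = degree_centrality(net, "total")
        assert scores.values["c"] == 1.0
        assert all(v == pytest.approx(1 / 5) for n, v in scores.values.items()
                   if n != "c")

    def test_hand_counted_four_node_fixture(self):
        net = net_from_pairs([("a", "b"), ("a", "c"), ("d", "b")])
        scores = degree_centrality(net, "in")
        assert scores.values == {
            "a": 0.0, "b": pytest.approx(2 / 3), "c": pytest.approx(1 / 3),
            "d": 0.0,
        }

    def test_values_lie_in_unit_interval(self):
        rng = random.Random(5)
        net = net_from_pairs(random_directed_pairs(rng, 12, 30))
        for direction in ("in", "out", "total"):
            for v in degree_centrality(net, direction).values.values():
                assert 0.0 <= v <= 1.0

    def test_too_small_graph_raises(self):
        from dtnet.graph_core import DrugTargetNetwork

        net = DrugTargetNetwork()
        net.add_node("x", "drug")
        with pytest.raises(ValueError):
            degree_centrality(net)


class TestDistances:
    def test_undirected_path(self):
        net = net_from_pairs([("a", "b"), ("b", "c")])
        oracle = all_pairs_distances(net, Sense.UNDIRECTED)
        assert oracle.d[("a", "c")] == 2

    def test_directed_unreachability(self):
        net = net_from_pairs([("d", "t")])
        oracle = all_pairs_distances(net, Sense.DIRECTED_OUT)
        assert ("t", "d") not in oracle.d
        assert oracle.d[("d", "t")] == 1

    @pytest.mark.parametrize("sense", list(Sense))
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_floyd_warshall(self, sense, seed):
        rng = random.Random(seed)
        net = net_from_pairs(random_directed_pairs(rng, 15, 35))
        adjacency = {
            Sense.DIRECTED_OUT: net.out_adj,
            Sense.DIRECTED_IN: net.in_adj,
            Sense.UNDIRECTED: {n: net.undirected_neighbors(n) for n in net.roles},
        }[sense]
        assert all_pairs_distances(net, sense).d == floyd_warshall(net, adjacency)


class TestCloseness:
    def test_undirected_star_center(self):
        net = net_from_pairs([("c", f"t{i}") for i in range(5)])
        scores = closeness_centrality(net, Sense.UNDIRECTED)
        assert scores.values["c"] == pytest.approx(1.0)

    def test_disconnected_graph_matches_direct_oracle(self):
        net = net_from_pairs(
            [("a", "b"), ("b", "c"), ("x", "y"), ("p", "q"), ("q", "r"),
             ("r", "s")]
        )
        scores = closeness_centrality(net, Sense.UNDIRECTED)
        oracle = all_pairs_distances(net, Sense.UNDIRECTED)
        n = net.n_nodes
        for v in net.nodes:
            dists = [d for (u, w), d in oracle.d.items() if w == v and u != v]
            if not dists:
                assert scores.values[v] == 0.0
                continue
            expected = (len(dists) / sum(dists)) * (len(dists) / (n - 1))
            assert scores.values[v] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_networkx_wf_closeness(self, seed):
        """Incoming-sense closeness equals networkx's wf-improved closeness."""
        rng = random.Random(seed)
        net = net_from_pairs(random_directed_pairs(rng, 12, 25))
        scores = closeness_centrality(net, Sense.DIRECTED_IN)
        g = net.to_networkx()
        expected = nx.closeness_centrality(g, wf_improved=True)
        for node, value in expected.items():
            assert scores.values[node] == pytest.approx(value, abs=1e-12)

    def test_relabeling_invariance(self):
        pairs = [("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")]
        mapping = {"a": "w", "b": "x", "c": "y", "d": "z"}
        relabeled = [(mapping[u], mapping[v]) for u, v in pairs]
        s1 = closeness_centrality(net_from_pairs(pairs), Sense.UNDIRECTED)
        s2 = closeness_centrality(net_from_pairs(relabeled), Sense.UNDIRECTED)
        for old, new in mapping.items():
            assert s1.values[old] == pytest.approx(s2.values[new])


class TestBetweenness:
    def test_path_interior_vertex(self):
        net = net_from_pairs([("a", "b"), ("b", "c")])
        scores = betweenness_centrality(net, Sense.UNDIRECTED)
        assert scores.values["b"] == pytest.approx(1.0)
        assert scores.values["a"] == scores.values["c"] == 0.0

    @pytest.mark.parametrize("sense", [Sense.DIRECTED_OUT, Sense.UNDIRECTED])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_equals_exhaustive_path_enumeration(self, sense, seed):
        """Brandes accumulation equals explicit shortest-path enumeration."""
        rng = random.Random(40 + seed)
        n = rng.randint(5, 9)
        net = net_from_pairs(random_directed_pairs(rng, n, rng.randint(n, 3 * n)))
        adjacency = (
            net.out_adj
            if sense is Sense.DIRECTED_OUT
            else {v: net.undirected_neighbors(v) for v in net.roles}
        )
        expected_raw = brute_force_betweenness(net, adjacency)
        scale = 1.0 / ((net.n_nodes - 1) * (net.n_nodes - 2))
        scores = betweenness_centrality(net, sense)
        for node in net.nodes:
            assert scores.values[node] == pytest.approx(
                expected_raw[node] * scale, abs=1e-12
            )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_networkx(self, seed):
        rng = random.Random(seed)
        net = net_from_pairs(random_directed_pairs(rng, 14, 40))
        g = net.to_networkx()
        expected = nx.betweenness_centrality(g, normalized=True)
        scores = betweenness_centrality(net, Sense.DIRECTED_OUT)
        for node, value in expected.items():
            assert scores.values[node] == pytest.approx(value, abs=1e-12)


class TestEigenvector:
    def test_triangle_symmetry(self):
        net = net_from_pairs([("a", "b"), ("b", "c"), ("c", "a")])
        scores = eigenvector_centrality(net)
        for v in "abc":
            assert scores.values[v] == pytest.approx(1 / np.sqrt(3))

    def test_matches_dense_eigendecomposition(self):
        rng = random.Random(9)
        pairs = random_directed_pairs(rng, 12, 30)
        net = net_from_pairs(pairs)
        from dtnet.graph_core import extract_component, weak_components

        decomposition = weak_components(net)
        giant = extract_component(net, 0, decomposition)
        nodes = giant.nodes
        index = {v: i for i, v in enumerate(nodes)}
        b = np.zeros((len(nodes), len(nodes)))
        for u, v in giant.edges():
            b[index[u], index[v]] = b[index[v], index[u]] = 1.0
        eigenvalues, eigenvectors = np.linalg.eigh(b)
        lead = np.abs(eigenvectors[:, -1])
        lead /= np.linalg.norm(lead)
        scores = eigenvector_centrality(net, tol=1e-14)
        for v in nodes:
            assert scores.values[v] == pytest.approx(lead[index[v]], abs=1e-8)
        # residual check ||Bx - lambda x||_inf
        x = np.array([scores.values[v] for v in nodes])
        lam = scores.parameters["lambda"]
        assert np.max(np.abs(b @ x - lam * x)) < 1e-6
        # nodes outside the giant component score 0
        outside = set(net.nodes) - set(nodes)
        for v in outside:
            assert scores.values[v] == 0.0

    def test_unit_norm(self):
        rng = random.Random(2)
        net = net_from_pairs(random_directed_pairs(rng, 10, 20))
        scores = eigenvector_centrality(net)
        norm = np.linalg.norm(list(scores.values.values()))
        assert norm == pytest.approx(1.0, abs=1e-9)


class TestTopK:
    def test_ties_break_lexicographically(self):
        from dtnet.centrality import CentralityScores

        scores = CentralityScores(
            metric="x", values={"b": 1.0, "a": 1.0, "c": 1.0}, normalization=""
        )
        assert top_k(scores, 3) == [("a", 1.0), ("b", 1.0), ("c", 1.0)]

    def test_k_exceeding_size_warns_and_truncates(self):
        from dtnet.centrality import CentralityScores

        scores = CentralityScores(
            metric="x", values={"a": 2.0, "b": 1.0}, normalization=""
        )
        with pytest.warns(UserWarning):
            result = top_k(scores, 5)
        assert result == [("a", 2.0), ("b", 1.0)]

    def test_full_ranking_is_permutation(self):
        rng = random.Random(8)
        net = net_from_pairs(random_directed_pairs(rng, 10, 18))
        scores = degree_centrality(net, "total")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ranked = top_k(scores, net.n_nodes)
        assert sorted(n for n, _ in ranked) == net.nodes
        values = [v for _, v in ranked]
        assert values == sorted(values, reverse=True)
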