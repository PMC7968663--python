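"""Degree statistics, power-law fits and clustering coefficients."""

import random
from itertools import combinations

import numpy as np
import pytest

from dtnet.topology import (
    DegreeDistribution,
    Which,
    clustering,
    degrees,
    empirical_distribution,
    fit_power_law,
    mean_degree,
)

from conftest import clique_edges, net_from_pairs, random_bipartite_pairs, random_directed_pairs


def exact_power_law_distribution(gamma: float, k_max: int = 100):
    k = np.arange(1, k_max + 1)
    p = k.astype(float) ** -gamma
    p /= p.sum()
    return DegreeDistribution(
        support=k, probability=p, which=Which.TOTAL,
        n_observed=10**6, n_zero=0,
    )


class TestDegrees:
    def test_hand_enumerated_fixture(self):
        net = net_from_pairs(
            [("a", "b"), ("a", "c"), ("b", "c"), ("d", "c"), ("d", "a")]
        )
        deg = degrees(net)
        assert deg.loc["a", "k_out"] == 2
        assert deg.loc["a", "k_in"] == 1
        assert deg.loc["c", "k_in"] == 3
        assert deg.loc["c", "k_out"] == 0
        assert deg.loc["d", "k_total"] == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_handshake_identity(self, seed):
        """Sum of in-degrees equals sum of out-degrees equals |E|."""
        rng = random.Random(seed)
        net = net_from_pairs(
            random_directed_pairs(rng, rng.randint(3, 20), rng.randint(2, 40))
        )
        deg = degrees(net)
        assert deg["k_in"].sum() == deg["k_out"].sum() == net.n_edges

    def test_mean_degree(self):
        assert mean_degree(net_from_pairs([("a", "b")])) == 1.0
        k33 = net_from_pairs(
            [(f"d{i}", f"t{j}") for i in range(3) for j in range(3)]
        )
        assert mean_degree(k33) == 3.0

    def test_mean_degree_empty_graph_raises(self):
        from dtnet.graph_core import DrugTargetNetwork

        with pytest.raises(ValueError):
            mean_degree(DrugTargetNetwork())


class TestEmpiricalDistribution:
    def test_direct_count(self):
        net = net_from_pairs([("a", "t1"), ("b", "t1"), ("c", "t1"), ("c", "t2")])
        # out-degrees over all 6 nodes: a=1 b=1 c=2, targets 0
        dist = empirical_distribution(degrees(net), "out")
        assert dist.support.tolist() == [1, 2]
        assert dist.probability.tolist() == [2 / 3, 1 / 3]
        assert dist.n_zero == 2

    def test_regular_graph_single_support_point(self):
        net = net_from_pairs(
            [(f"d{i}", f"t{j}") for i in range(3) for j in range(3)]
        )
        dist = empirical_distribution(degrees(net), "total")
        assert dist.support.tolist() == [3]
        assert dist.probability.tolist() == [1.0]

    def test_all_zero_degrees_raise(self):
        net = net_from_pairs([("a", "b")])
        deg = degrees(net)
        with pytest.raises(ValueError):
            empirical_distribution(deg, "out", nodes={"b"})

    def test_role_restricted_normalization(self):
        net = net_from_pairs([("a", "t1"), ("b", "t1")])
        drugs = set(net.drug_nodes())
        dist = empirical_distribution(degrees(net), "out", nodes=drugs)
        assert dist.n_observed == 2
        assert dist.probability.tolist() == [1.0]


class TestFitPowerLaw:
    def test_exact_law_recovered_to_machine_precision(self):
        fit = fit_power_law(exact_power_law_distribution(2.0))
        assert abs(fit.gamma - 2.0) < 1e-9
        assert fit.r_squared > 1 - 1e-12
        # A anchors the fitted curve at the first support point
        assert np.isclose(fit.A * 1.0 ** -fit.gamma,
                          exact_power_law_distribution(2.0).probability[0])

    @pytest.mark.parametrize("gamma", [1.5, 2.0, 2.5])
    def test_mle_bias_small_on_zipf_samples(self, gamma):
        """Discrete MLE recovers the exponent within 0.05 at n = 1e5."""
        rng = np.random.default_rng(12345)
        sample = rng.zipf(gamma, size=100_000)
        values, counts = np.unique(sample, return_counts=True)
        dist = DegreeDistribution(
            support=values, probability=counts / sample.size,
            which=Which.TOTAL, n_observed=sample.size, n_zero=0,
        )
        fit = fit_power_law(dist, method="mle")
        assert abs(fit.gamma - gamma) < 0.05

    def test_mle_with_finite_k_max(self):
        rng = np.random.default_rng(7)
        from dtnet.synthetic import sample_truncated_power_law

        sample = sample_truncated_power_law(rng, 1.8, 50, 50_000)
        values, counts = np.unique(sample, return_counts=True)
        dist = DegreeDistribution(
            support=values, probability=counts / sample.size,
            which=Which.TOTAL, n_observed=sample.size, n_zero=0,
        )
        fit = fit_power_law(dist, method="mle", k_max=50)
        assert abs(fit.gamma - 1.8) < 0.05

    def test_insufficient_support_raises(self):
        dist = DegreeDistribution(
            support=np.array([1, 2]), probability=np.array([0.5, 0.5]),
            which=Which.TOTAL, n_observed=10, n_zero=0,
        )
        with pytest.raises(ValueError):
            fit_power_law(dist)

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError):
            fit_power_law(exact_power_law_distribution(2.0), method="bayes")


class TestClustering:
    def test_triangle_is_fully_clustered(self):
        net = net_from_pairs([("a", "b"), ("b", "c"), ("c", "a")])
        profile = clustering(net)
        assert profile.per_node["C"].tolist() == [1.0, 1.0, 1.0]
        assert profile.mean_c == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_bipartite_graph_has_zero_clustering(self, seed):
        """Strictly two-sided graphs contain no triangles."""
        rng = random.Random(seed)
        net = net_from_pairs(random_bipartite_pairs(rng, 8, 8, 20))
        assert clustering(net).mean_c == 0.0

    def test_low_degree_nodes_score_zero(self):
        net = net_from_pairs([("a", "b")])
        profile = clustering(net)
        assert profile.per_node["C"].tolist() == [0.0, 0.0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_cubic_brute_force(self, seed):
        """C_i equals linked-neighbor-pairs / (k_i choose 2) by enumeration."""
        rng = random.Random(100 + seed)
        net = net_from_pairs(random_directed_pairs(rng, 20, 45))
        profile = clustering(net)
        for node in net.nodes:
            nb = sorted(net.undirected_neighbors(node) - {node})
            k = len(nb)
            expected = 0.0
            if k >= 2:
                linked = sum(
                    1
                    for u, v in combinations(nb, 2)
                    if v in net.undirected_neighbors(u)
                )
                expected = linked / (k * (k - 1) / 2)
                assert profile.per_node.loc[node, "E_i"] == linked
                assert linked <= k * (k - 1) / 2
            assert profile.per_node.loc[node, "C"] == pytest.approx(expected)

    def test_c_of_k_curve_is_grouped_mean(self):
        net = net_from_pairs(clique_edges("abc") + [("c", "d")])
        profile = clustering(net)
        # a and b have k=2 with C=1; c has k=3 with C=1/3; d has k=1, C=0
        assert profile.c_of_k[2] == 1.0
        assert profile.c_of_k[3] == pytest.approx(1 / 3)
        assert profile.c_of_k[1] == 0.0
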