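"""Tests for the weighted DAG, K-shortest-paths ranking and PIS."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mccsp
from mccsp import (
    ConfigurationError,
    DegenerateInputError,
    DirectedNetwork,
    NetworkStructureError,
    WeightedNetwork,
    compute_pis,
    enumerate_all_simple_paths,
    estimate_weighted_network,
    k_shortest_paths,
    pathway_effect,
    rank_pathways,
    weight_transform,
)
from mccsp.network import count_paths

from conftest import random_dag


def brute_force_ranking(net, strengths, K):
    """Oracle: enumerate every simple path, sort by (total weight, nodes)."""
    w = WeightedNetwork.from_strengths(net, strengths)
    paths = []
    for p in enumerate_all_simple_paths(net):
        total = sum(w.weight[e] for e in zip(p[:-1], p[1:]))
        if math.isfinite(total):
            paths.append((total, p))
    paths.sort()
    return [p for _, p in paths[:K]]


class TestWeightTransform:
    def test_analytic_values(self):
        assert weight_transform(1.0) == 0.0
        assert weight_transform(0.5) == pytest.approx(math.log(2))

    def test_strictly_decreasing(self):
        rs = np.linspace(0.01, 1.5, 50)
        ws = [weight_transform(r) for r in rs]
        assert all(a > b for a, b in zip(ws[:-1], ws[1:]))

    def test_nonpositive_rejected(self):
        with pytest.raises(DegenerateInputError):
            weight_transform(0.0)


class TestDirectedNetwork:
    def test_cycle_rejected(self):
        with pytest.raises(NetworkStructureError, match="cycle"):
            DirectedNetwork("ABC", [("A", "B"), ("B", "C"), ("C", "A")], "A", "C")

    def test_duplicate_edges_rejected(self):
        with pytest.raises(NetworkStructureError, match="duplicate"):
            DirectedNetwork("AB", [("A", "B"), ("A", "B")], "A", "B")

    def test_source_with_incoming_edge_rejected(self):
        with pytest.raises(NetworkStructureError, match="incoming"):
            DirectedNetwork("ABC", [("A", "B"), ("B", "C"), ("A", "C")], "B", "C")

    def test_undeclared_node_rejected(self):
        with pytest.raises(NetworkStructureError, match="undeclared"):
            DirectedNetwork("AB", [("A", "X")], "A", "B")

    def test_declaration_order_is_canonicalised(self):
        a = DirectedNetwork(["A", "B", "C"], [("A", "B"), ("B", "C")], "A", "C")
        b = DirectedNetwork(["C", "B", "A"], [("B", "C"), ("A", "B")], "A", "C")
        assert a == b


class TestKShortestPaths:
    def test_single_path_returned_for_large_k(self):
        net = DirectedNetwork("ABC", [("A", "B"), ("B", "C")], "A", "C")
        w = WeightedNetwork.from_strengths(net, {("A", "B"): 0.5, ("B", "C"): 0.5})
        paths = k_shortest_paths(w, 3)
        assert [p.nodes for p in paths] == [("A", "B", "C")]
        assert paths[0].effect == pytest.approx(0.25)

    def test_parallel_paths_ranked_by_effect_product(self):
        net = DirectedNetwork("SMNT", [("S", "M"), ("M", "T"), ("S", "N"), ("N", "T")],
                              "S", "T")
        w = WeightedNetwork.from_strengths(net, {
            ("S", "M"): 0.9, ("M", "T"): 0.9,   # effect 0.81
            ("S", "N"): 0.95, ("N", "T"): 0.8,  # effect 0.76
        })
        paths = k_shortest_paths(w, 2)
        assert paths[0].nodes == ("S", "M", "T")
        assert paths[0].effect == pytest.approx(0.81)
        assert paths[1].effect == pytest.approx(0.76)

    def test_equal_weight_tie_broken_lexicographically(self):
        net = DirectedNetwork("SABT", [("S", "A"), ("A", "T"), ("S", "B"), ("B", "T")],
                              "S", "T")
        w = WeightedNetwork.from_strengths(net, {e: 0.5 for e in net.edges})
        paths = k_shortest_paths(w, 2)
        assert [p.nodes for p in paths] == [("S", "A", "T"), ("S", "B", "T")]

    def test_no_finite_path_gives_empty_result(self):
        net = DirectedNetwork("ABC", [("A", "B"), ("B", "C")], "A", "C")
        w = WeightedNetwork.from_strengths(net, {("A", "B"): 0.0, ("B", "C"): 0.9})
        assert k_shortest_paths(w, 3) == []

    def test_matches_exhaustive_enumeration_on_random_dags(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            net, strengths = random_dag(rng, int(rng.integers(4, 13)))
            k = int(rng.integers(1, 8))
            w = WeightedNetwork.from_strengths(net, strengths)
            ours = [p.nodes for p in k_shortest_paths(w, k)]
            assert ours == brute_force_ranking(net, strengths, k)

    def test_negative_weights_from_raw_mi_handled(self):
        # strengths above 1 (raw MI) give negative log-reciprocal weights
        net = DirectedNetwork("SMNT", [("S", "M"), ("M", "T"), ("S", "N"), ("N", "T")],
                              "S", "T")
        strengths = {("S", "M"): 1.8, ("M", "T"): 1.5,
                     ("S", "N"): 0.9, ("N", "T"): 0.9}
        w = WeightedNetwork.from_strengths(net, strengths)
        assert w.weight[("S", "M")] < 0
        paths = k_shortest_paths(w, 2)
        assert paths[0].nodes == ("S", "M", "T")
        assert paths == sorted(paths, key=lambda p: p.total_weight)


class TestEnumeration:
    def test_chain_has_one_path(self):
        net = DirectedNetwork("ABC", [("A", "B"), ("B", "C")], "A", "C")
        assert enumerate_all_simple_paths(net) == [("A", "B", "C")]

    def test_fan_fixture_has_six_paths(self, fan_net):
        paths = enumerate_all_simple_paths(fan_net)
        assert len(paths) == 6
        assert count_paths(fan_net) == 6
        assert all(p[0] == "APOEg" and p[-1] == "AD" for p in paths)

    def test_count_matches_recursive_dfs(self):
        def dfs_count(g, u, sink):
            if u == sink:
                return 1
            return sum(dfs_count(g, v, sink) for v in g.successors(u))

        rng = np.random.default_rng(1)
        for _ in range(20):
            net, _ = random_dag(rng, int(rng.integers(4, 14)))
            g = net.graph()
            n_paths = dfs_count(g, net.source, net.sink)
            assert len(enumerate_all_simple_paths(net)) == n_paths
            assert count_paths(net) == n_paths


class TestEffectsAndPIS:
    def test_effect_is_product_and_log_identity(self):
        net = DirectedNetwork("ABCD", [("A", "B"), ("B", "C"), ("C", "D")], "A", "D")
        w = WeightedNetwork.from_strengths(net, {e: 0.5 for e in net.edges})
        chain = ("A", "B", "C", "D")
        assert pathway_effect(chain, w) == pytest.approx(0.125)
        total = sum(w.weight[e] for e in zip(chain[:-1], chain[1:]))
        assert pathway_effect(chain, w) == pytest.approx(math.exp(-total), abs=1e-10)

    def test_missing_edge_is_structural_error(self):
        net = DirectedNetwork("ABC", [("A", "B"), ("B", "C")], "A", "C")
        w = WeightedNetwork.from_strengths(net, {("A", "B"): 0.5, ("B", "C"): 0.5})
        with pytest.raises(NetworkStructureError):
            pathway_effect(("A", "C"), w)

    def test_pis_spot_values(self):
        assert compute_pis([2.0, 1.0, 0.5]) == pytest.approx([2.0, 1.0, 0.5])

    @given(st.integers(0, 500))
    def test_pis_median_unit_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        q = int(rng.integers(1, 12)) * 2 + 1  # odd Q
        effects = rng.uniform(0.01, 2.0, size=q)
        pis = compute_pis(effects)
        q50 = np.median(effects)
        assert pis[np.argsort(effects)[q // 2]] == pytest.approx(1.0)
        assert np.all((pis > 1) == (effects > q50))
        assert compute_pis(effects * 7.3) == pytest.approx(pis)

    def test_all_zero_effects_degenerate(self):
        with pytest.raises(DegenerateInputError):
            compute_pis([0.0, 0.0, 0.0])


class TestEstimation:
    def test_missing_column_listed(self, fan_net):
        rng = np.random.default_rng(0)
        data = {n: rng.standard_normal(50) for n in fan_net.nodes if n != "MAPT"}
        with pytest.raises(ConfigurationError, match="MAPT"):
            estimate_weighted_network(data, fan_net, "pearson")

    def test_deterministic_linear_chain_has_unit_strengths(self):
        net = DirectedNetwork("ABC", [("A", "B"), ("B", "C")], "A", "C")
        x = np.linspace(-1, 1, 30)
        data = {"A": x, "B": 2 * x + 1, "C": -x}
        w = estimate_weighted_network(data, net, "pearson")
        assert all(w.strength[e] == pytest.approx(1.0) for e in net.edges)
        assert all(w.weight[e] == pytest.approx(0.0, abs=1e-12) for e in net.edges)

    def test_exactly_uncorrelated_edge_dropped_from_search(self):
        net = DirectedNetwork("AB", [("A", "B")], "A", "B")
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0] * 4)
        data = {"A": x, "B": x ** 2}  # Pearson exactly 0 by symmetry
        w = estimate_weighted_network(data, net, "pearson")
        assert w.weight[("A", "B")] == math.inf
        assert k_shortest_paths(w, 1) == []

    def test_strengths_match_direct_estimator_calls(self, fan_net):
        data = mccsp.simulate_fan_data(n=80, seed=3)
        w = estimate_weighted_network(data, fan_net, "pearson")
        for (a, b) in fan_net.edges:
            direct = abs(mccsp.pearson(data[a], data[b]))
            assert w.strength[(a, b)] == pytest.approx(direct, abs=1e-12)


class TestRankPathways:
    def test_planted_strong_path_ranked_first_by_every_method(self, fan_net):
        planted = ("APOEg", "APOEe", "GRIN2A", "CAPN2", "MAPT", "AD")
        strengths = {e: 0.15 for e in fan_net.edges}
        for e in zip(planted[:-1], planted[1:]):
            strengths[e] = 0.9
        data = mccsp.simulate_fan_data(n=400, seed=5, strengths=strengths)
        for method in mccsp.METHOD_NAMES:
            ranking = rank_pathways(data, fan_net, method, K=1)
            assert ranking.pathways[0].nodes == planted, method

    def test_pearson_and_mcc_agree_on_linear_data(self, fan_net):
        # well-separated path effects so estimator noise cannot reorder them
        strengths = {
            ("APOEg", "APOEe"): 0.6,
            ("APOEe", "GRIN2A"): 0.9, ("APOEe", "CACNA1C"): 0.4,
            ("GRIN2A", "CAPN2"): 0.85, ("GRIN2A", "MAPK1"): 0.55,
            ("GRIN2A", "NOS1"): 0.7,
            ("CACNA1C", "CAPN2"): 0.5, ("CACNA1C", "MAPK1"): 0.35,
            ("CACNA1C", "NOS1"): 0.3,
            ("CAPN2", "MAPT"): 0.9, ("MAPK1", "CASP3"): 0.8,
            ("MAPT", "AD"): 0.8, ("CASP3", "AD"): 0.6, ("NOS1", "AD"): 0.7,
        }
        data = mccsp.simulate_fan_data(n=500, seed=6, strengths=strengths)
        top_p = [p.nodes for p in rank_pathways(data, fan_net, "pearson", K=4).pathways]
        top_m = [p.nodes for p in rank_pathways(data, fan_net, "mcc", K=4).pathways]
        assert top_p == top_m

    def test_pis_attached_and_consistent(self, fan_net):
        data = mccsp.simulate_fan_data(n=200, seed=7)
        ranking = rank_pathways(data, fan_net, "pearson")
        assert ranking.n_total_paths == 6
        assert len(ranking.pathways) == 6
        effects = [p.effect for p in ranking.pathways]
        assert effects == sorted(effects, reverse=True)
        for p in ranking.pathways:
            assert p.pis == pytest.approx(p.effect / ranking.q50)
            assert (p.pis > 1) == (p.effect > ranking.q50)

    def test_invariant_to_declaration_order(self, fan_net):
        data = mccsp.simulate_fan_data(n=100, seed=8)
        shuffled = DirectedNetwork(list(fan_net.nodes)[::-1],
                                   list(fan_net.edges)[::-1],
                                   fan_net.source, fan_net.sink)
        a = rank_pathways(data, fan_net, "spearman", K=3)
        b = rank_pathways(data, shuffled, "spearman", K=3)
        assert a == b
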