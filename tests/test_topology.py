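import math

import networkx as nx
import numpy as np
import pytest

from conftest import as_network
from netpharm.topology import (
    PAPER_THRESHOLDS,
    ScreenThresholds,
    compute_betweenness,
    compute_closeness,
    compute_coreness,
    compute_degree,
    derive_median_thresholds,
    hub_subnetwork,
    profile_topology,
    screen_network,
    select_hubs,
    select_major_hubs,
)
import oracles


class TestDegree:
    def test_path(self, path3):
        assert compute_degree(path3) == {0: 1, 1: 2, 2: 1}

    def test_complete_graph(self):
        assert set(compute_degree(as_network(nx.complete_graph(4))).values()) == {3}

    def test_matches_adjacency_row_sums(self):
        g = nx.gnm_random_graph(12, 20, seed=2)
        net = as_network(g)
        rows = nx.to_numpy_array(g, nodelist=sorted(g)).sum(axis=1)
        assert [compute_degree(net)[v] for v in sorted(g)] == list(rows.astype(int))


class TestBetweenness:
    def test_path_midpoint(self, path3):
        assert compute_betweenness(path3, normalized=False)[1] == pytest.approx(1.0)
        assert compute_betweenness(path3, normalized=True)[1] == pytest.approx(1.0)

    def test_four_cycle(self):
        net = as_network(nx.cycle_graph(4))
        raw = compute_betweenness(net, normalized=False)
        norm = compute_betweenness(net, normalized=True)
        assert all(v == pytest.approx(0.5) for v in raw.values())
        assert all(v == pytest.approx(1 / 6) for v in norm.values())

    def test_vertex_transitive_graphs_are_constant(self):
        for g in (nx.cycle_graph(7), nx.complete_graph(5), nx.circular_ladder_graph(4)):
            values = list(compute_betweenness(as_network(g)).values())
            assert max(values) - min(values) < 1e-12

    def test_tiny_graphs_normalise_to_zero(self):
        net = as_network(nx.path_graph(2))
        assert set(compute_betweenness(net, normalized=True).values()) == {0.0}


class TestCloseness:
    def test_star_center(self):
        assert compute_closeness(as_network(nx.star_graph(3)))[0] == pytest.approx(1.0)

    def test_path_endpoint(self, path3):
        assert compute_closeness(path3)[0] == pytest.approx(2 / 3)

    def test_two_disjoint_triangles_wf_scaled(self):
        g = nx.disjoint_union(nx.cycle_graph(3), nx.cycle_graph(3))
        values = compute_closeness(as_network(g))
        assert all(v == pytest.approx(0.4) for v in values.values())

    def test_isolated_node_scores_zero(self):
        g = nx.path_graph(3)
        g.add_node("iso")
        assert compute_closeness(as_network(g))["iso"] == 0.0

    def test_harmonic_alternative(self, path3):
        # endpoint: (1 + 1/2) / (n-1) = 0.75
        values = compute_closeness(path3, disconnected_rule="harmonic")
        assert values[0] == pytest.approx(0.75)

    def test_unknown_rule_is_error(self, path3):
        with pytest.raises(ValueError):
            compute_closeness(path3, disconnected_rule="bogus")


class TestCoreness:
    def test_complete_graph(self):
        assert set(compute_coreness(as_network(nx.complete_graph(4))).values()) == {3}

    def test_star_is_one_core(self):
        assert set(compute_coreness(as_network(nx.star_graph(9))).values()) == {1}

    def test_triangle_with_pendant(self):
        g = nx.cycle_graph(3)
        g.add_edge(2, "pendant")
        coreness = compute_coreness(as_network(g))
        assert coreness["pendant"] == 1 and coreness[0] == coreness[1] == coreness[2] == 2

    def test_coreness_never_exceeds_degree(self):
        for seed in range(5):
            net = as_network(nx.gnm_random_graph(25, 60, seed=seed))
            degree, coreness = compute_degree(net), compute_coreness(net)
            assert all(coreness[v] <= degree[v] for v in degree)


class TestProfile:
    def test_triangle_profile(self, triangle):
        profile = profile_topology(triangle)
        assert list(profile.table["degree"]) == [2, 2, 2]
        assert list(profile.table["betweenness"]) == [0, 0, 0]
        assert list(profile.table["closeness"]) == [1, 1, 1]
        assert list(profile.table["coreness"]) == [2, 2, 2]

    def test_empty_graph_gives_empty_profile(self):
        from netpharm.network import InteractionNetwork

        assert len(profile_topology(InteractionNetwork())) == 0

    def test_profile_equals_per_metric_oracles(self):
        net = as_network(nx.gnm_random_graph(18, 40, seed=4))
        profile = profile_topology(net)
        deg = oracles.brute_degree(net.graph)
        bet = oracles.brute_betweenness(net.graph)
        clo = oracles.brute_closeness_wf(net.graph)
        cor = oracles.brute_coreness(net.graph)
        for node in net.graph.nodes:
            row = profile.table.loc[node]
            assert row["degree"] == deg[node]
            assert row["betweenness"] == pytest.approx(bet[node], abs=1e-12)
            assert row["closeness"] == pytest.approx(clo[node], abs=1e-12)
            assert row["coreness"] == cor[node]

    def test_handshake_lemma(self):
        net = as_network(nx.gnm_random_graph(30, 77, seed=9))
        profile = profile_topology(net)
        assert profile.table["degree"].sum() == 2 * net.n_edges


class TestHubSelection:
    def test_regular_graph_has_no_hubs(self):
        profile = profile_topology(as_network(nx.cycle_graph(8)))
        assert select_hubs(profile) == set()

    def test_degrees_1_1_1_3_5(self):
        g = nx.Graph()
        # star-ish construction realising degree sequence [5,3,1,1,1,...]
        g.add_edges_from([("h", x) for x in "abcde"] + [("a", "b"), ("a", "c")])
        profile = profile_topology(as_network(g))
        degrees = profile.table["degree"]
        cutoff = 2 * degrees.median()
        expected = set(degrees.index[degrees > cutoff])
        assert select_hubs(profile, hub_factor=2.0) == expected

    def test_strict_inequality_at_cutoff(self):
        # degrees [1, 1, 2]: median 1, cutoff 2, degree-2 node is NOT a hub
        profile = profile_topology(as_network(nx.path_graph(3)))
        assert select_hubs(profile, hub_factor=2.0) == set()


class TestHubSubnetwork:
    def test_path_induces_single_edge(self):
        net = as_network(nx.path_graph(4))
        sub = hub_subnetwork(net, {1, 2})
        assert sub.node_ids == {1, 2} and sub.n_edges == 1

    def test_all_nodes_is_identity(self, triangle):
        sub = hub_subnetwork(triangle, triangle.node_ids)
        assert sub.node_ids == triangle.node_ids and sub.n_edges == triangle.n_edges

    def test_foreign_ids_are_error(self, triangle):
        with pytest.raises(ValueError):
            hub_subnetwork(triangle, {"nope"})

    def test_matches_brute_force_edge_filter(self):
        g = nx.gnm_random_graph(20, 50, seed=6)
        net = as_network(g)
        hubs = set(range(0, 20, 2))
        sub = hub_subnetwork(net, hubs)
        expected = {frozenset(e) for e in g.edges if e[0] in hubs and e[1] in hubs}
        assert {frozenset(e) for e in sub.graph.edges} == expected


class TestThresholds:
    def test_median_of_2_4_6(self):
        g = nx.Graph()  # degrees: a:1, b:2, c:3, d:2... build explicit
        profile = profile_topology(as_network(nx.path_graph(4)))
        thresholds = derive_median_thresholds(profile)
        assert thresholds.degree_min == profile.table["degree"].median()
        assert thresholds.mode == "median_derived"

    def test_all_equal_metric_empties_strict_filter(self, triangle):
        profile = profile_topology(triangle)
        thresholds = derive_median_thresholds(profile)
        selected, _ = select_major_hubs(profile, thresholds)
        assert selected == set()

    def test_empty_profile_is_error(self):
        from netpharm.network import InteractionNetwork

        with pytest.raises(ValueError):
            derive_median_thresholds(profile_topology(InteractionNetwork()))

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ScreenThresholds(1, 1, 1, 1, hub_factor=0)
        with pytest.raises(ValueError):
            ScreenThresholds(math.nan, 1, 1, 1)

    def test_paper_preset_records_printed_cutoffs(self):
        assert (
            PAPER_THRESHOLDS.degree_min,
            PAPER_THRESHOLDS.betweenness_min,
            PAPER_THRESHOLDS.closeness_min,
            PAPER_THRESHOLDS.coreness_min,
        ) == (4, 0.0002, 0.3919, 5)
        assert PAPER_THRESHOLDS.mode == "explicit"


class TestMajorHubs:
    def test_zero_thresholds_keep_all_nonzero_profiles(self):
        net = as_network(nx.path_graph(5))
        profile = profile_topology(net)
        thresholds = ScreenThresholds(0, -1, 0, 0)
        selected, _ = select_major_hubs(profile, thresholds)
        # endpoints have betweenness 0 but closeness/degree/coreness > 0;
        # betweenness_min=-1 admits them
        assert selected == {n for n in net.graph.nodes if profile.table.loc[n, "degree"] > 0}

    def test_raising_any_threshold_never_grows_selection(self):
        net = as_network(nx.gnm_random_graph(25, 70, seed=8))
        profile = profile_topology(net)
        base = ScreenThresholds(1, 0.0, 0.1, 1)
        selected_base, _ = select_major_hubs(profile, base)
        for field, bump in [("degree_min", 2), ("betweenness_min", 0.01),
                            ("closeness_min", 0.2), ("coreness_min", 2)]:
            import dataclasses

            raised = dataclasses.replace(base, **{field: getattr(base, field) + bump})
            selected, _ = select_major_hubs(profile, raised)
            assert selected <= selected_base

    def test_subset_chain_on_full_screen(self):
        g = nx.barabasi_albert_graph(120, 2, seed=3)
        net = as_network(g)
        result = screen_network(net)
        assert result.major_hub_ids <= result.hub_ids <= net.node_ids

    def test_screen_on_hubless_graph_is_empty(self, triangle):
        result = screen_network(triangle)
        assert result.hub_ids == set() and result.major_hub_ids == set()

    def test_full_network_profiling_mode(self):
        g = nx.barabasi_albert_graph(60, 2, seed=5)
        result = screen_network(as_network(g), profile_graph="full")
        assert result.hub_profile.graph_label == "full"
        assert set(result.hub_profile.table.index) == result.hub_ids
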