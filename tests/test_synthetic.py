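import json

import networkx as nx
import numpy as np
import pytest

from netpharm import io as npio
from netpharm.enrichment import enrich
from netpharm.synthetic import (
    ParameterError,
    SyntheticConfig,
    generate_gene_sets,
    generate_ppi,
    generate_study_fixture,
    generate_target_sets,
    write_dataset,
)

TINY = dict(
    n_targets_herb_a=2, n_targets_herb_b=3, n_overlap=1, n_disease_targets=2,
    disease_sources=(("d", 2),), n_planted_hubs=0, n_pathways=0,
    n_planted_pathways=0, pathway_size_range=(1, 2),
)


def _graph(edge_frame):
    g = nx.Graph()
    g.add_edges_from(edge_frame[["protein_a", "protein_b"]].itertuples(index=False, name=None))
    return g


class TestConfig:
    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ParameterError):
            SyntheticConfig(n_nodes=4, n_edges=7, **TINY)

    def test_overlap_exceeding_set_size_rejected(self):
        with pytest.raises(ParameterError):
            SyntheticConfig(n_targets_herb_a=5, n_targets_herb_b=10, n_overlap=6)

    def test_mismatched_disease_split_rejected(self):
        with pytest.raises(ParameterError):
            SyntheticConfig(n_disease_targets=10, disease_sources=(("a", 3), ("b", 3)))


class TestPPI:
    def test_four_nodes_six_edges_forces_complete_graph(self):
        frame, _ = generate_ppi(SyntheticConfig(n_nodes=4, n_edges=6, seed=1, **TINY))
        g = _graph(frame)
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 6
        assert nx.is_isomorphic(g, nx.complete_graph(4))

    def test_handshake_lemma(self):
        cfg = SyntheticConfig(n_nodes=1000, n_edges=1100, seed=7,
                              n_targets_herb_a=10, n_targets_herb_b=10, n_overlap=0,
                              n_disease_targets=5, disease_sources=(("d", 5),),
                              n_planted_hubs=3, n_pathways=5, n_planted_pathways=1,
                              pathway_size_range=(3, 10))
        frame, _ = generate_ppi(cfg)
        degrees = _graph(frame).degree()
        assert sum(d for _, d in degrees) == 2200

    def test_planted_hubs_exceed_twice_median_degree(self):
        cfg = SyntheticConfig(n_nodes=200, n_edges=400, seed=3,
                              n_targets_herb_a=20, n_targets_herb_b=30, n_overlap=5,
                              n_disease_targets=10, disease_sources=(("d", 10),),
                              n_planted_hubs=5, n_pathways=5, n_planted_pathways=1,
                              pathway_size_range=(3, 10))
        frame, planted = generate_ppi(cfg)
        degrees = dict(_graph(frame).degree())
        median = np.median(list(degrees.values()))
        assert len(planted) == 5
        assert all(degrees[h] > 2 * median for h in planted)

    def test_simple_graph_no_loops_no_duplicates(self, small_config):
        frame, _ = generate_ppi(small_config)
        pairs = list(frame.itertuples(index=False, name=None))
        assert all(a != b for a, b in pairs)
        assert len({tuple(sorted(p)) for p in pairs}) == len(pairs)

    def test_median_degree_is_one_under_study_shape(self, small_config):
        frame, _ = generate_ppi(small_config)
        degrees = [d for _, d in _graph(frame).degree()]
        assert np.median(degrees) == 1.0

    def test_erdos_renyi_topology_option(self):
        cfg = SyntheticConfig(n_nodes=300, n_edges=600, topology="erdos_renyi", seed=2,
                              n_targets_herb_a=10, n_targets_herb_b=10, n_overlap=0,
                              n_disease_targets=5, disease_sources=(("d", 5),),
                              n_planted_hubs=0, n_pathways=0, n_planted_pathways=0,
                              pathway_size_range=(2, 5))
        frame, _ = generate_ppi(cfg)
        assert len(frame) == 600


class TestTargetSets:
    def test_cardinalities_exact_with_study_defaults(self, small_config):
        a, b, disease = generate_target_sets([f"P{i:05d}" for i in range(1, 1401)], small_config)
        assert len(a) == 60 and len(b) == 100
        assert len(a.ids & b.ids) == 30
        assert len(disease) == 40

    def test_inclusion_exclusion_on_printed_sizes(self):
        cfg = SyntheticConfig(seed=0)  # 175 / 348 / 106
        nodes = [f"P{i:05d}" for i in range(1, 601)]
        a, b, _ = generate_target_sets(nodes, cfg)
        assert len(a.ids | b.ids) == 175 + 348 - 106

    def test_zero_overlap_gives_disjoint_sets(self, small_config):
        cfg = SyntheticConfig(**{**small_config.__dict__, "n_overlap": 0})
        a, b, _ = generate_target_sets([f"N{i}" for i in range(500)], cfg)
        assert not (a.ids & b.ids)

    def test_determinism(self, small_config):
        cfg = SyntheticConfig(**{**small_config.__dict__, "seed": 11})
        nodes = [f"N{i}" for i in range(500)]
        first = generate_target_sets(nodes, cfg)
        second = generate_target_sets(nodes, cfg)
        for x, y in zip(first, second):
            assert x.ids == y.ids

    def test_planted_hubs_land_in_herb_union(self, small_config):
        nodes = [f"N{i}" for i in range(500)]
        planted = [f"N{i}" for i in range(10)]
        a, b, _ = generate_target_sets(nodes, small_config, planted_hubs=planted)
        assert set(planted) <= (a.ids | b.ids)

    def test_infeasible_union_rejected(self):
        cfg = SyntheticConfig(n_nodes=30, n_edges=40, n_targets_herb_a=20,
                              n_targets_herb_b=20, n_overlap=15, n_disease_targets=5,
                              disease_sources=(("d", 5),), n_planted_hubs=0,
                              n_pathways=0, n_planted_pathways=0, pathway_size_range=(2, 5))
        with pytest.raises(ParameterError):
            generate_target_sets([f"N{i}" for i in range(10)], cfg)


class TestGeneSets:
    def test_zero_pathways_gives_empty_annotation(self, small_config):
        cfg = SyntheticConfig(**{**small_config.__dict__, "n_pathways": 0, "n_planted_pathways": 0})
        annotation, planted = generate_gene_sets([f"N{i}" for i in range(100)], cfg)
        assert len(annotation) == 0 and planted == []

    def test_full_planting_fraction_stays_in_neighbourhood(self, small_config):
        dataset = generate_study_fixture(
            SyntheticConfig(**{**small_config.__dict__, "planted_pathway_fraction": 1.0})
        )
        graph = dataset.ppi_graph
        neighbourhood = set(dataset.truth["planted_hubs"])
        for hub in dataset.truth["planted_hubs"]:
            neighbourhood.update(graph.neighbors(hub))
        for name in dataset.truth["planted_pathways"]:
            members = dataset.gene_sets.pathways[name]
            assert members <= neighbourhood or len(neighbourhood) < len(members)

    def test_planted_pathways_enrich_on_true_hub_set(self, small_config):
        dataset = generate_study_fixture(small_config)
        results = {r.name: r for r in enrich(dataset.truth["planted_hubs"], dataset.gene_sets)}
        planted_p = [results[n].p_value for n in dataset.truth["planted_pathways"]]
        other_p = [r.p_value for n, r in results.items()
                   if n not in dataset.truth["planted_pathways"]]
        assert max(planted_p) < np.median(other_p)

    def test_sizes_within_configured_range(self, small_config):
        dataset = generate_study_fixture(small_config)
        lo, hi = small_config.pathway_size_range
        assert all(lo <= len(m) <= hi for m in dataset.gene_sets.pathways.values())


class TestFixtureBundle:
    def test_round_trip_through_ingest_is_lossless(self, small_config, tmp_path):
        dataset = generate_study_fixture(small_config)
        paths = write_dataset(dataset, tmp_path)
        herb_a = npio.read_target_table(paths["herb_a"], "herb_a")
        disease = npio.read_target_table(paths["disease"], "disease")
        ppi = npio.read_edge_list(paths["ppi"])
        annotation = npio.read_gene_sets(paths["gene_sets"])
        assert herb_a.ids == dataset.herb_a.ids
        assert disease.ids == dataset.disease.ids
        assert set(ppi.edges) == {
            tuple(sorted(e)) for e in dataset.ppi_edges.itertuples(index=False, name=None)
        }
        assert annotation.pathways == dataset.gene_sets.pathways

    def test_truth_sets_are_subsets_of_their_universes(self, small_config):
        dataset = generate_study_fixture(small_config)
        nodes = set(dataset.ppi_graph.nodes)
        assert set(dataset.truth["planted_hubs"]) <= nodes
        assert set(dataset.truth["planted_pathways"]) <= set(dataset.gene_sets.pathways)
        for ts in (dataset.herb_a, dataset.herb_b, dataset.disease):
            assert ts.ids <= nodes

    def test_different_seeds_differ(self, small_config):
        one = generate_study_fixture(SyntheticConfig(**{**small_config.__dict__, "seed": 1}))
        two = generate_study_fixture(SyntheticConfig(**{**small_config.__dict__, "seed": 2}))
        assert not one.ppi_edges.equals(two.ppi_edges)

    def test_identical_seed_serialises_byte_identically(self, small_config, tmp_path):
        paths_a = write_dataset(generate_study_fixture(small_config), tmp_path / "a")
        paths_b = write_dataset(generate_study_fixture(small_config), tmp_path / "b")
        for key in paths_a:
            assert paths_a[key].read_bytes() == paths_b[key].read_bytes(), key
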