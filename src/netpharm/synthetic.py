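"""Synthetic study-shaped data with planted ground truth.

The generator emulates the shape of a published herb-formula screen:

* a sparse PPI union whose **median degree is ~1** (so the twofold-median
  hub cutoff is 2), built as a preferential-attachment core surrounded by
  degree-1 leaves — the heavy-tailed profile typical of merged public PPI
  databases;
* two overlapping herb target sets (defaults 175 and 348 with 106 shared)
  and a disease target set (default 90, split 75 + 15 across two labelled
  sources, emulating a drug database and a disease-gene catalogue);
* pathway annotations with **planted enrichment**: a few pathways draw most
  of their members, degree-weighted, from the neighbourhoods of the planted
  hubs, so a correct screen followed by over-representation analysis must
  recover them;
* **planted hubs**: nodes wired, post hoc, to enough high-degree core
  partners that they are unambiguous major hubs; the extra edges are
  balanced by removing edges between unplanted well-connected nodes so the
  configured edge count is exact.

All randomness flows from ``SyntheticConfig.seed`` through
``numpy.random.SeedSequence``; identical configs give identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import PathwayAnnotation, TargetRecord, TargetSet, write_gene_sets

__all__ = [
    "ParameterError",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_ppi",
    "generate_target_sets",
    "generate_gene_sets",
    "generate_study_fixture",
    "write_dataset",
]


class ParameterError(ValueError):
    """Raised when a synthetic configuration is infeasible."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic study.

    Defaults reproduce the shape of the gastritis formula screen: a
    5559-node / 21567-edge PPI union with median degree 1, herb target
    sets of 175 and 348 sharing 106 ids, and 90 disease targets split
    75 / 15 across two sources.
    """

    n_nodes: int = 5559
    n_edges: int = 21567
    topology: str = "scale_free"          # or "erdos_renyi"
    attachment_m: int = 1                 # edges attached per new core node
    leaf_fraction: float = 0.55           # fraction of nodes kept at degree 1
    n_targets_herb_a: int = 175
    n_targets_herb_b: int = 348
    n_overlap: int = 106
    n_disease_targets: int = 90
    disease_sources: tuple[tuple[str, int], ...] = (
        ("drug_database", 75),
        ("disease_gene_catalog", 15),
    )
    n_planted_hubs: int = 20
    hub_boost_quantile: float = 0.97      # planted-hub degree target within the core
    n_pathways: int = 50
    n_planted_pathways: int = 5
    pathway_size_range: tuple[int, int] = (10, 60)
    planted_pathway_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes <= 0:
            raise ParameterError("n_nodes must be positive")
        max_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if not (0 <= self.n_edges <= max_edges):
            raise ParameterError(
                f"n_edges={self.n_edges} infeasible for n_nodes={self.n_nodes} (max {max_edges})"
            )
        if self.topology not in ("scale_free", "erdos_renyi"):
            raise ParameterError(f"unknown topology {self.topology!r}")
        for name in ("n_targets_herb_a", "n_targets_herb_b", "n_overlap",
                     "n_disease_targets", "n_planted_hubs", "n_pathways",
                     "n_planted_pathways"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.n_overlap > min(self.n_targets_herb_a, self.n_targets_herb_b):
            raise ParameterError("n_overlap exceeds a herb target set size")
        union = self.n_targets_herb_a + self.n_targets_herb_b - self.n_overlap
        if union > self.n_nodes or self.n_disease_targets > self.n_nodes:
            raise ParameterError("target sets larger than the node universe")
        if self.n_planted_hubs > self.n_nodes:
            raise ParameterError("n_planted_hubs exceeds n_nodes")
        if self.n_planted_pathways > self.n_pathways:
            raise ParameterError("n_planted_pathways exceeds n_pathways")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi):
            raise ParameterError("pathway_size_range must satisfy 0 < lo <= hi")
        if hi > self.n_nodes:
            raise ParameterError("pathway sizes exceed the node universe")
        if not 0.0 <= self.planted_pathway_fraction <= 1.0:
            raise ParameterError("planted_pathway_fraction must lie in [0, 1]")
        if not 0.0 <= self.leaf_fraction < 1.0:
            raise ParameterError("leaf_fraction must lie in [0, 1)")
        if sum(n for _, n in self.disease_sources) != self.n_disease_targets:
            raise ParameterError("disease_sources counts must sum to n_disease_targets")


def _node_name(i: int) -> str:
    return f"P{i + 1:05d}"


def _spawn_rngs(seed: int) -> tuple[np.random.Generator, ...]:
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _feasible_leaf_count(config: SyntheticConfig) -> int:
    """Largest leaf count <= leaf_fraction*n that leaves a buildable core."""
    n = config.n_nodes
    n_leaves = int(round(config.leaf_fraction * n))
    while n_leaves > 0:
        n_core = n - n_leaves
        m_core = config.n_edges - n_leaves
        if n_core >= 1 and n_core - 1 <= m_core <= n_core * (n_core - 1) // 2:
            return n_leaves
        n_leaves -= 1
    return 0


def _preferential_core(n_core: int, m_core: int, m_attach: int,
                       rng: np.random.Generator) -> tuple[nx.Graph, list[int]]:
    """Connected preferential-attachment graph with exactly m_core edges.

    Returns the graph on integer nodes 0..n_core-1 and the degree-weighted
    stub list used for later leaf attachment.
    """
    g = nx.Graph()
    g.add_nodes_from(range(n_core))
    stubs: list[int] = [0]
    for i in range(1, n_core):
        budget_left = m_core - g.number_of_edges() - (n_core - 1 - i)
        k = max(1, min(m_attach, i, budget_left))
        chosen: set[int] = set()
        while len(chosen) < k:
            pick = int(stubs[rng.integers(len(stubs))])
            if pick != i:
                chosen.add(pick)
        for j in chosen:
            g.add_edge(i, j)
            stubs.extend((i, j))
    # densify preferentially up to the exact edge budget
    attempts = 0
    while g.number_of_edges() < m_core:
        u = int(stubs[rng.integers(len(stubs))])
        v = int(stubs[rng.integers(len(stubs))])
        attempts += 1
        if u == v or g.has_edge(u, v):
            if attempts > 50 * max(m_core, 10):
                # dense regime: fall back to uniform sampling of non-edges
                non_edges = list(nx.non_edges(g))
                need = m_core - g.number_of_edges()
                idx = rng.choice(len(non_edges), size=need, replace=False)
                for i in np.atleast_1d(idx):
                    u, v = non_edges[int(i)]
                    g.add_edge(u, v)
                    stubs.extend((u, v))
                break
            continue
        g.add_edge(u, v)
        stubs.extend((u, v))
    return g, stubs


def _plant_hubs(g: nx.Graph, core: list[str], planted: list[str],
                quantile: float, rng: np.random.Generator) -> None:
    """Boost planted nodes to unambiguous hub degree at constant edge count."""
    degrees = dict(g.degree())
    overall_median = float(np.median(list(degrees.values())))
    core_degrees = np.array([degrees[n] for n in core], dtype=float)
    target = max(2 * overall_median + 3,
                 float(np.quantile(core_degrees, quantile)) if len(core) else 0.0)
    added = 0
    core_arr = np.array(core)
    all_nodes = np.array(sorted(g.nodes))
    for hub in planted:
        attempts = 0
        while g.degree(hub) < target:
            # widen the partner pool if the core is nearly saturated
            pool = core_arr if attempts < 20 * len(core_arr) else all_nodes
            partner = str(pool[rng.integers(len(pool))])
            attempts += 1
            if partner == hub or g.has_edge(hub, partner):
                if attempts > 20 * len(core_arr) + 20 * len(all_nodes):
                    break  # saturated: hub is already maximally connected
                continue
            g.add_edge(hub, partner)
            added += 1
    planted_set = set(planted)
    min_keep = 3
    while added > 0:
        candidates = [
            (u, v) for u, v in g.edges
            if u not in planted_set and v not in planted_set
            and g.degree(u) >= min_keep and g.degree(v) >= min_keep
        ]
        if not candidates:
            if min_keep > 2:
                min_keep = 2
                continue
            raise ParameterError(
                "cannot balance planted-hub edges: graph too small/sparse for n_planted_hubs"
            )
        take = min(added, len(candidates))
        idx = rng.choice(len(candidates), size=take, replace=False)
        for i in np.atleast_1d(idx):
            u, v = candidates[int(i)]
            # degrees shift as we delete; re-check to avoid stranding nodes
            if g.degree(u) >= min_keep and g.degree(v) >= min_keep and not (u in planted_set or v in planted_set):
                g.remove_edge(u, v)
                added -= 1
            if added == 0:
                break


def _generate_ppi_graph(config: SyntheticConfig,
                        rng: np.random.Generator) -> tuple[nx.Graph, list[str]]:
    n = config.n_nodes
    names = [_node_name(i) for i in range(n)]
    if config.topology == "erdos_renyi":
        g_int = nx.gnm_random_graph(n, config.n_edges, seed=int(rng.integers(2**31 - 1)))
        g = nx.relabel_nodes(g_int, dict(enumerate(names)))
        core = [node for node, deg in g.degree() if deg >= 1] or names
    elif config.n_edges < n - 1 and _feasible_leaf_count(config) == 0:
        # below tree density: preferential growth cannot apply, sample uniformly
        g_int = nx.gnm_random_graph(n, config.n_edges, seed=int(rng.integers(2**31 - 1)))
        g = nx.relabel_nodes(g_int, dict(enumerate(names)))
        core = [node for node, deg in g.degree() if deg >= 1] or names
    else:
        n_leaves = _feasible_leaf_count(config)
        n_core = n - n_leaves
        m_core = config.n_edges - n_leaves
        core_int, stubs = _preferential_core(n_core, m_core, config.attachment_m, rng)
        g = nx.relabel_nodes(core_int, {i: names[i] for i in range(n_core)})
        for leaf_idx in range(n_core, n):
            if stubs:
                anchor_idx = int(stubs[rng.integers(len(stubs))])
            else:  # degenerate: edgeless core
                anchor_idx = int(rng.integers(n_core))
            g.add_edge(names[leaf_idx], names[anchor_idx])
            stubs.append(anchor_idx)  # leaves reinforce their anchor's weight
        core = names[:n_core]
    g.add_nodes_from(names)  # keep isolated nodes in the universe

    planted: list[str] = []
    if config.n_planted_hubs > 0 and config.n_edges > 0:
        pool = core if len(core) >= config.n_planted_hubs else names
        planted = [str(x) for x in rng.choice(np.array(pool), size=config.n_planted_hubs, replace=False)]
        _plant_hubs(g, core, planted, config.hub_boost_quantile, rng)
    if g.number_of_edges() != config.n_edges:
        raise AssertionError(
            f"generator bug: produced {g.number_of_edges()} edges, wanted {config.n_edges}"
        )
    return g, sorted(planted)


def generate_ppi(config: SyntheticConfig) -> tuple[pd.DataFrame, list[str]]:
    """Generate the synthetic PPI edge table and the planted hub ids.

    The edge table has columns ``protein_a`` / ``protein_b`` with each
    unordered pair stored once in sorted orientation.
    """
    rng_ppi, _, _ = _spawn_rngs(config.seed)
    g, planted = _generate_ppi_graph(config, rng_ppi)
    rows = sorted(tuple(sorted(e)) for e in g.edges)
    frame = pd.DataFrame(rows, columns=["protein_a", "protein_b"])
    return frame, planted


def generate_target_sets(
    ppi_nodes,
    config: SyntheticConfig,
    planted_hubs=(),
    rng: np.random.Generator | None = None,
) -> tuple[TargetSet, TargetSet, TargetSet]:
    """Sample herb A, herb B and disease target sets from the node universe.

    |A|, |B| and |A∩B| match the config exactly; planted hubs are always
    placed inside A∪B so the remedy's putative targets include the nodes
    whose topological prominence was planted.  Disease targets are drawn
    uniformly (they may overlap the herb sets) and split across the
    configured source labels with disjoint ids.
    """
    if rng is None:
        _, rng, _ = _spawn_rngs(config.seed)
    nodes = sorted(str(n) for n in ppi_nodes)
    a, b, o = config.n_targets_herb_a, config.n_targets_herb_b, config.n_overlap
    union_size = a + b - o
    if union_size > len(nodes):
        raise ParameterError("herb target union exceeds available nodes")

    planted = [h for h in sorted(set(map(str, planted_hubs))) if h in set(nodes)]
    rest = [n for n in nodes if n not in set(planted)]
    rng.shuffle(planted)
    rng.shuffle(rest)
    ordered = planted + rest
    union = ordered[:union_size]
    rng.shuffle(union)
    shared = union[:o]
    a_only = union[o:o + (a - o)]
    b_only = union[o + (a - o):]

    def _as_set(ids, label, tag):
        ts = TargetSet()
        for i in ids:
            ts.add(TargetRecord(id=i, symbol=i, sources=(label,), tag=tag))
        return ts

    herb_a = _as_set(shared + a_only, "simulated_herb_a", "herb_a")
    herb_b = _as_set(shared + b_only, "simulated_herb_b", "herb_b")

    disease_ids = [str(x) for x in rng.choice(np.array(nodes), size=config.n_disease_targets, replace=False)]
    disease = TargetSet()
    start = 0
    for label, count in config.disease_sources:
        for i in disease_ids[start:start + count]:
            disease.add(TargetRecord(id=i, symbol=i, sources=(label,), tag="disease"))
        start += count
    return herb_a, herb_b, disease


def generate_gene_sets(
    ppi_nodes,
    config: SyntheticConfig,
    graph: nx.Graph | None = None,
    planted_hubs=(),
    rng: np.random.Generator | None = None,
) -> tuple[PathwayAnnotation, list[str]]:
    """Sample pathway annotations over the node universe.

    Planted pathways draw ``planted_pathway_fraction`` of their members,
    degree-weighted, from the planted hubs and their neighbourhoods; all
    other members — and all non-planted pathways — are sampled uniformly.
    """
    if rng is None:
        _, _, rng = _spawn_rngs(config.seed)
    nodes = np.array(sorted(str(n) for n in ppi_nodes))
    lo, hi = config.pathway_size_range
    if hi > len(nodes):
        raise ParameterError("pathway size range exceeds the universe")

    planted_set = [h for h in sorted(set(map(str, planted_hubs))) if h in set(nodes)]
    pool: list[str] = []
    weights: np.ndarray | None = None
    if planted_set and graph is not None:
        members: set[str] = set(planted_set)
        for h in planted_set:
            if h in graph:
                members.update(map(str, graph.neighbors(h)))
        pool = sorted(members)
        deg = np.array([graph.degree(p) if p in graph else 0 for p in pool], dtype=float)
        weights = deg + 1.0
        weights /= weights.sum()
    elif planted_set:
        pool = planted_set

    pathways: dict[str, frozenset[str]] = {}
    planted_names: list[str] = []
    for idx in range(config.n_pathways):
        name = f"PW_{idx + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        if idx < config.n_planted_pathways and pool:
            n_core_members = min(int(round(config.planted_pathway_fraction * size)), len(pool))
            # build the pathway around the planted hubs themselves, then fill
            # from their interactor neighbourhood, favouring high-degree nodes
            hubs_in = list(planted_set[: n_core_members])
            core_members = set(hubs_in)
            n_fill = n_core_members - len(core_members)
            if n_fill > 0:
                fill_pool = [p for p in pool if p not in core_members]
                if weights is not None:
                    w = np.array([weights[pool.index(p)] for p in fill_pool])
                    w = w / w.sum()
                    fill = rng.choice(np.array(fill_pool), size=n_fill, replace=False, p=w)
                else:
                    fill = rng.choice(np.array(fill_pool), size=n_fill, replace=False)
                core_members |= set(map(str, fill))
            outside = nodes[~np.isin(nodes, sorted(core_members))]
            extra = rng.choice(outside, size=size - len(core_members), replace=False)
            pathways[name] = frozenset(core_members) | frozenset(map(str, extra))
            planted_names.append(name)
        else:
            pathways[name] = frozenset(map(str, rng.choice(nodes, size=size, replace=False)))
    annotation = PathwayAnnotation(pathways=pathways, universe=frozenset(map(str, nodes)))
    return annotation, planted_names


@dataclass
class SyntheticDataset:
    """One generated study: inputs plus planted ground truth."""

    config: SyntheticConfig
    ppi_edges: pd.DataFrame
    herb_a: TargetSet
    herb_b: TargetSet
    disease: TargetSet
    gene_sets: PathwayAnnotation
    truth: dict = field(default_factory=dict)

    @property
    def ppi_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.ppi_edges[["protein_a", "protein_b"]].itertuples(index=False, name=None))
        return g


def generate_study_fixture(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a complete study bundle (PPI, targets, pathways, truth)."""
    config = config or SyntheticConfig()
    rng_ppi, rng_targets, rng_sets = _spawn_rngs(config.seed)
    graph, planted = _generate_ppi_graph(config, rng_ppi)
    herb_a, herb_b, disease = generate_target_sets(
        graph.nodes, config, planted_hubs=planted, rng=rng_targets
    )
    gene_sets, planted_pathways = generate_gene_sets(
        graph.nodes, config, graph=graph, planted_hubs=planted, rng=rng_sets
    )
    rows = sorted(tuple(sorted(e)) for e in graph.edges)
    frame = pd.DataFrame(rows, columns=["protein_a", "protein_b"])
    return SyntheticDataset(
        config=config,
        ppi_edges=frame,
        herb_a=herb_a,
        herb_b=herb_b,
        disease=disease,
        gene_sets=gene_sets,
        truth={"planted_hubs": planted, "planted_pathways": planted_pathways},
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Serialise a dataset in the formats the ingest layer reads.

    Writes ``ppi.tsv`` (2-column edge list), three target TSVs, a GMT file
    and ``truth.json``; returns the path of each artifact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppi": out / "ppi.tsv",
        "herb_a": out / "herb_a_targets.tsv",
        "herb_b": out / "herb_b_targets.tsv",
        "disease": out / "disease_targets.tsv",
        "gene_sets": out / "pathways.gmt",
        "truth": out / "truth.json",
        "config": out / "synthetic_config.json",
    }
    dataset.ppi_edges.to_csv(paths["ppi"], sep="\t", index=False)
    dataset.herb_a.to_frame().to_csv(paths["herb_a"], sep="\t", index=False)
    dataset.herb_b.to_frame().to_csv(paths["herb_b"], sep="\t", index=False)
    dataset.disease.to_frame().to_csv(paths["disease"], sep="\t", index=False)
    write_gene_sets(dataset.gene_sets.pathways, paths["gene_sets"])
    paths["truth"].write_text(json.dumps(dataset.truth, indent=2, sort_keys=True))
    paths["config"].write_text(json.dumps(asdict(dataset.config), indent=2, sort_keys=True))
    return paths
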