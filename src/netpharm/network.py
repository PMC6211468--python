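"""Assembly of the putative-target / disease-target / linker network.

The interaction network joins two seed sets — putative targets of the
remedy's ingredients and known therapeutic targets of the disease — through
a merged protein–protein interaction (PPI) map.  Nodes carry one of four
exclusive class labels:

* ``putative`` — putative target only,
* ``disease``  — known therapeutic target only,
* ``both``     — in both seed sets,
* ``linker``   — an interactional protein connecting seeds without being one.

The default expansion rule admits the seeds plus their first PPI neighbours
and every PPI edge between admitted nodes.  Which interactional proteins a
published network of this kind admits is rarely stated precisely; the rule
is therefore configurable (``seed_only``, ``first_neighbor``, ``full``) and
the choice is logged with the build.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import EdgeTable, TargetSet

logger = logging.getLogger(__name__)

NODE_CLASSES = ("putative", "disease", "both", "linker")
EXPANSION_RULES = ("seed_only", "first_neighbor", "full")


@dataclass
class InteractionNetwork:
    """Simple undirected graph whose nodes carry a ``node_class`` attribute."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def node_ids(self) -> set[str]:
        return set(self.graph.nodes)

    def node_class(self, node_id: str) -> str:
        return self.graph.nodes[node_id].get("node_class", "linker")

    def class_counts(self) -> dict[str, int]:
        counts = Counter(data.get("node_class", "linker") for _, data in self.graph.nodes(data=True))
        return {cls: counts.get(cls, 0) for cls in NODE_CLASSES}

    def induced(self, node_ids) -> "InteractionNetwork":
        """Vertex-induced subnetwork, labels carried over."""
        return InteractionNetwork(graph=self.graph.subgraph(node_ids).copy())


def build_interaction_network(
    putative: TargetSet,
    disease: TargetSet,
    ppi: EdgeTable,
    expansion_rule: str = "first_neighbor",
) -> InteractionNetwork:
    """Assemble the labelled interaction network from seeds and a PPI map.

    Parameters
    ----------
    putative, disease
        Seed target sets.  Their union must be non-empty.
    ppi
        Normalised merged PPI edge table.
    expansion_rule
        ``seed_only``: nodes are exactly the seeds; ``first_neighbor``
        (default): seeds plus their direct PPI partners; ``full``: seeds
        plus every PPI node.  In all modes the edge set is the PPI edges
        induced on the admitted nodes, and isolated seeds are retained as
        degree-0 nodes.
    """
    if expansion_rule not in EXPANSION_RULES:
        raise ValueError(f"unknown expansion_rule {expansion_rule!r} (expected one of {EXPANSION_RULES})")
    seeds = putative.ids | disease.ids
    if not seeds:
        raise ValueError("empty seed union: no putative or disease targets given")

    ppi_graph = ppi.to_graph()
    if expansion_rule == "seed_only":
        nodes = set(seeds)
    elif expansion_rule == "first_neighbor":
        nodes = set(seeds)
        for seed in seeds:
            if seed in ppi_graph:
                nodes.update(ppi_graph.neighbors(seed))
    else:  # full
        nodes = set(seeds) | set(ppi_graph.nodes)

    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    graph.add_edges_from(
        (a, b) for a, b in ppi_graph.edges if a in nodes and b in nodes
    )
    network = InteractionNetwork(graph=graph)
    classify_nodes(network, putative, disease)
    counts = network.class_counts()
    logger.info(
        "built network (%s): %d nodes, %d edges, classes %s",
        expansion_rule, network.n_nodes, network.n_edges, counts,
    )
    return network


def classify_nodes(network: InteractionNetwork, putative: TargetSet, disease: TargetSet) -> InteractionNetwork:
    """Label every node putative / disease / both / linker (total partition)."""
    for node in network.graph.nodes:
        in_p = node in putative
        in_d = node in disease
        if in_p and in_d:
            cls = "both"
        elif in_p:
            cls = "putative"
        elif in_d:
            cls = "disease"
        else:
            cls = "linker"
        network.graph.nodes[node]["node_class"] = cls
    return network


def network_summary(network: InteractionNetwork) -> dict:
    """Deterministic count record: sizes, class counts, components, median degree."""
    degrees = [d for _, d in network.graph.degree()]
    return {
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
        "class_counts": network.class_counts(),
        "n_components": nx.number_connected_components(network.graph) if network.n_nodes else 0,
        "median_degree": float(np.median(degrees)) if degrees else 0.0,
    }
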