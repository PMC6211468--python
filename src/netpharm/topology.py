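"""Topological profiling and the two-stage hub / major-hub screen.

The screen proceeds in two stages:

1. **Hubs** — nodes whose degree strictly exceeds ``hub_factor`` (default 2)
   times the median degree of *all* nodes in the network.  On a sparse PPI
   union with median degree 1 this reduces to "keep degree > 2".
2. **Major hubs** — the hub-induced subnetwork is profiled with four
   topological parameters (degree, betweenness, closeness, coreness) and a
   hub is retained only if it strictly exceeds the threshold on *all four*.
   Thresholds are either the medians of the profiled graph
   (``median_derived``) or explicit values (``explicit``); the published
   cutoffs degree > 4, betweenness > 0.0002, closeness > 0.3919,
   coreness > 5 are available as the ``paper`` preset.

Conventions
-----------
* Betweenness uses fractional shortest-path counting with endpoints
  excluded; normalised values divide by ``(n-1)(n-2)/2``.
* Closeness is component-restricted with Wasserman–Faust scaling,
  ``((r-1)/(n-1)) * ((r-1)/sum_d)`` for a node in a component of size
  ``r``; isolated nodes score 0.  Harmonic closeness is available as an
  alternative for disconnected graphs.
* Coreness is the k-core shell index from iterative degree pruning.
* Medians over an even count are the mean of the two central order
  statistics, and every filter is a strict ``>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .network import NODE_CLASSES, InteractionNetwork

METRICS = ("degree", "betweenness", "closeness", "coreness")


def compute_degree(network: InteractionNetwork) -> dict[str, int]:
    """Number of links incident to each node."""
    return dict(network.graph.degree())


def compute_betweenness(network: InteractionNetwork, normalized: bool = True) -> dict[str, float]:
    """Fraction of pairwise shortest paths running through each node.

    Shortest-path multiplicities are counted fractionally and endpoints are
    excluded.  With ``normalized`` the raw sums divide by ``(n-1)(n-2)/2``;
    graphs with fewer than three nodes normalise to all zeros.
    """
    graph = network.graph
    if normalized and graph.number_of_nodes() < 3:
        return {node: 0.0 for node in graph.nodes}
    return nx.betweenness_centrality(graph, normalized=normalized)


def compute_closeness(network: InteractionNetwork, disconnected_rule: str = "wf") -> dict[str, float]:
    """Inverse mean shortest-path distance to reachable nodes.

    ``wf`` (default) applies Wasserman–Faust component scaling so values
    are comparable across components of a disconnected graph; ``harmonic``
    returns the normalised harmonic mean of distances instead.  Isolated
    nodes score 0 under both rules.
    """
    graph = network.graph
    if disconnected_rule == "wf":
        return nx.closeness_centrality(graph, wf_improved=True)
    if disconnected_rule == "harmonic":
        n = graph.number_of_nodes()
        scale = 1.0 / (n - 1) if n > 1 else 0.0
        return {node: value * scale for node, value in nx.harmonic_centrality(graph).items()}
    raise ValueError(f"unknown disconnected_rule {disconnected_rule!r} (expected wf or harmonic)")


def compute_coreness(network: InteractionNetwork) -> dict[str, int]:
    """Shell index of the k-core decomposition (iterative degree pruning)."""
    return nx.core_number(network.graph)


@dataclass
class TopologyProfile:
    """The four per-node topological parameters of one graph.

    ``table`` is indexed by node id with columns degree / betweenness /
    closeness / coreness; ``graph_label`` records which graph was profiled
    (full network vs hub subnetwork).
    """

    table: pd.DataFrame
    graph_label: str = "full"
    normalized: bool = True
    disconnected_rule: str = "wf"

    def __len__(self) -> int:
        return len(self.table)

    @property
    def node_ids(self) -> set[str]:
        return set(self.table.index)

    def medians(self) -> dict[str, float]:
        if self.table.empty:
            raise ValueError("cannot take medians of an empty profile")
        return {metric: float(self.table[metric].median()) for metric in METRICS}


def profile_topology(
    network: InteractionNetwork,
    graph_label: str = "full",
    normalized: bool = True,
    disconnected_rule: str = "wf",
) -> TopologyProfile:
    """Compute all four topological parameters on the same graph."""
    nodes = sorted(network.graph.nodes)
    if not nodes:
        table = pd.DataFrame(columns=list(METRICS))
        return TopologyProfile(table=table, graph_label=graph_label,
                               normalized=normalized, disconnected_rule=disconnected_rule)
    degree = compute_degree(network)
    betweenness = compute_betweenness(network, normalized=normalized)
    closeness = compute_closeness(network, disconnected_rule=disconnected_rule)
    coreness = compute_coreness(network)
    table = pd.DataFrame(
        {
            "degree": [degree[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "coreness": [coreness[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    return TopologyProfile(table=table, graph_label=graph_label,
                           normalized=normalized, disconnected_rule=disconnected_rule)


@dataclass(frozen=True)
class ScreenThresholds:
    """Cutoffs for the major-hub filter (all strict ``>``)."""

    degree_min: float
    betweenness_min: float
    closeness_min: float
    coreness_min: float
    hub_factor: float = 2.0
    mode: str = "explicit"

    def __post_init__(self):
        if self.hub_factor <= 0:
            raise ValueError("hub_factor must be positive")
        for name in ("degree_min", "betweenness_min", "closeness_min", "coreness_min"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def as_dict(self) -> dict:
        return {
            "degree_min": self.degree_min,
            "betweenness_min": self.betweenness_min,
            "closeness_min": self.closeness_min,
            "coreness_min": self.coreness_min,
            "hub_factor": self.hub_factor,
            "mode": self.mode,
        }


#: Explicit cutoffs of a published herb-formula screen (normalised centralities).
PAPER_THRESHOLDS = ScreenThresholds(
    degree_min=4, betweenness_min=0.0002, closeness_min=0.3919, coreness_min=5,
    hub_factor=2.0, mode="explicit",
)


def select_hubs(profile: TopologyProfile, hub_factor: float = 2.0) -> set[str]:
    """Nodes whose degree strictly exceeds ``hub_factor`` x the median degree."""
    if profile.table.empty:
        return set()
    cutoff = hub_factor * float(profile.table["degree"].median())
    return set(profile.table.index[profile.table["degree"] > cutoff])


def hub_subnetwork(network: InteractionNetwork, hub_ids: set[str]) -> InteractionNetwork:
    """Vertex-induced subgraph on the hub set (direct interactions among hubs)."""
    missing = hub_ids - network.node_ids
    if missing:
        raise ValueError(f"{len(missing)} hub ids not in network (e.g. {sorted(missing)[:3]})")
    return network.induced(hub_ids)


def derive_median_thresholds(profile: TopologyProfile, hub_factor: float = 2.0) -> ScreenThresholds:
    """Thresholds at the medians of the four metrics over the profiled graph."""
    med = profile.medians()
    return ScreenThresholds(
        degree_min=med["degree"],
        betweenness_min=med["betweenness"],
        closeness_min=med["closeness"],
        coreness_min=med["coreness"],
        hub_factor=hub_factor,
        mode="median_derived",
    )


@dataclass
class HubScreenResult:
    """Outcome of the two-stage screen."""

    hub_ids: set[str]
    hub_network: InteractionNetwork
    hub_profile: TopologyProfile
    major_hub_ids: set[str]
    thresholds_used: ScreenThresholds
    class_counts: dict[str, int] = field(default_factory=dict)

    def to_frame(self, full_profile: TopologyProfile | None = None) -> pd.DataFrame:
        """Per-node table over the hub subnetwork (class, metrics, flags)."""
        table = self.hub_profile.table.copy()
        table["node_class"] = [
            self.hub_network.node_class(n) for n in table.index
        ]
        table["is_hub"] = True
        table["is_major_hub"] = [n in self.major_hub_ids for n in table.index]
        return table


def select_major_hubs(
    profile: TopologyProfile,
    thresholds: ScreenThresholds,
    network: InteractionNetwork | None = None,
) -> tuple[set[str], dict[str, int]]:
    """Nodes strictly exceeding all four thresholds, plus per-class counts."""
    t = profile.table
    if t.empty:
        return set(), {cls: 0 for cls in NODE_CLASSES}
    mask = (
        (t["degree"] > thresholds.degree_min)
        & (t["betweenness"] > thresholds.betweenness_min)
        & (t["closeness"] > thresholds.closeness_min)
        & (t["coreness"] > thresholds.coreness_min)
    )
    selected = set(t.index[mask])
    counts = {cls: 0 for cls in NODE_CLASSES}
    if network is not None:
        for node in selected:
            counts[network.node_class(node)] += 1
    return selected, counts


def screen_network(
    network: InteractionNetwork,
    hub_factor: float = 2.0,
    thresholds: ScreenThresholds | None = None,
    profile_graph: str = "hub_subnetwork",
    disconnected_rule: str = "wf",
) -> HubScreenResult:
    """Run the full two-stage screen on a labelled network.

    With ``thresholds=None`` the cutoffs are the medians of the four metrics
    over the profiled graph (``median_derived``); passing explicit
    :class:`ScreenThresholds` reproduces a fixed published cutoff instead.
    ``profile_graph`` selects whether the four metrics are evaluated on the
    hub-induced subnetwork (default) or the full network (sensitivity mode).
    """
    if profile_graph not in ("hub_subnetwork", "full"):
        raise ValueError(f"unknown profile_graph {profile_graph!r}")
    degrees = compute_degree(network)
    if not degrees:
        raise ValueError("cannot screen an empty network")
    median_degree = float(np.median(list(degrees.values())))
    hubs = {n for n, d in degrees.items() if d > hub_factor * median_degree}
    sub = hub_subnetwork(network, hubs)
    profiled = network if profile_graph == "full" else sub
    profile = profile_topology(profiled, graph_label=profile_graph, disconnected_rule=disconnected_rule)
    if profile_graph == "full":
        profile = TopologyProfile(
            table=profile.table.loc[sorted(hubs)], graph_label="full",
            normalized=profile.normalized, disconnected_rule=disconnected_rule,
        )
    if thresholds is None:
        if len(profile) == 0:
            thresholds = ScreenThresholds(0, 0, 0, 0, hub_factor=hub_factor, mode="median_derived")
        else:
            thresholds = derive_median_thresholds(profile, hub_factor=hub_factor)
    else:
        thresholds = replace(thresholds, hub_factor=hub_factor)
    major, counts = select_major_hubs(profile, thresholds, network=network)
    return HubScreenResult(
        hub_ids=hubs,
        hub_network=sub,
        hub_profile=profile,
        major_hub_ids=major,
        thresholds_used=thresholds,
        class_counts=counts,
    )
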