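import networkx as nx
import pytest

from netpharm.network import InteractionNetwork
from netpharm.synthetic import SyntheticConfig

#: Scaled-down study: same edge density and leaf fraction as the full-size
#: default (5559 nodes / 21567 edges), small enough to screen in ~1 s.
SMALL_STUDY = dict(
    n_nodes=1400,
    n_edges=5430,
    n_targets_herb_a=60,
    n_targets_herb_b=100,
    n_overlap=30,
    n_disease_targets=40,
    disease_sources=(("drug_database", 32), ("disease_gene_catalog", 8)),
    n_planted_hubs=8,
    n_pathways=30,
    n_planted_pathways=3,
    pathway_size_range=(8, 30),
)


@pytest.fixture
def small_config():
    return SyntheticConfig(seed=5, **SMALL_STUDY)


def as_network(graph: nx.Graph) -> InteractionNetwork:
    net = InteractionNetwork(graph=graph.copy())
    for node in net.graph.nodes:
        net.graph.nodes[node].setdefault("node_class", "linker")
    return net


@pytest.fixture
def triangle():
    return as_network(nx.cycle_graph(3))


@pytest.fixture
def path3():
    return as_network(nx.path_graph(3))
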