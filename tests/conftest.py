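import numpy as np
import pytest

from ddinet.core import DDISet, PPIRecord, Protein, ProteinCatalog
from ddinet.dataset import LabeledDataset
from ddinet.synthetic import WorldConfig, generate_world


@pytest.fixture
def tiny_catalog() -> ProteinCatalog:
    """Four human + two bacterial proteins with hand-picked domains/tissues."""
    return ProteinCatalog([
        Protein("H1", "human", ("PF00001", "PF00002"), "trpA", frozenset({"gut"})),
        Protein("H2", "human", ("PF00003",), "trpB", frozenset({"brain"})),
        Protein("H3", "human", ("PF00001",), "abcX", frozenset({"gut", "liver"})),
        Protein("H4", "human", ("PF00004",), "abcY", frozenset({"kidney"})),
        Protein("B1", "strain_01", ("PF00002", "PF00003"), "yopM"),
        Protein("B2", "strain_02", ("PF00005",), "yopN"),
    ])


@pytest.fixture
def tiny_positives() -> LabeledDataset:
    return LabeledDataset([
        PPIRecord("H1", "B1", label="positive", source="exp"),
        PPIRecord("H2", "B1", label="positive", source="exp"),
        PPIRecord("H1", "H3", label="positive", source="exp"),
    ])


@pytest.fixture(scope="session")
def small_world():
    """A scaled-down synthetic world for fast unit tests."""
    return generate_world(WorldConfig(
        n_domains=25, n_human=60, n_strains=3, proteins_per_strain=15,
        n_positive_ppis=300, n_negative_ppis=300, n_interactome_pairs=80,
        seed=7,
    ))


@pytest.fixture(scope="session")
def default_world():
    """The default study conditions (used by end-to-end checks)."""
    return generate_world(WorldConfig(seed=11))


def random_graph(rng: np.random.Generator, n: int, p: float):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(i, j)
    return g
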