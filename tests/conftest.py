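import networkx as nx
import pytest

from domino_ami import fixtures, slicer
from domino_ami.model_io import GeneNetwork


@pytest.fixture(scope="session")
def planted():
    """Default planted world (seed 42): one active 20-gene community."""
    return fixtures.planted_default(42)


@pytest.fixture(scope="session")
def planted_slices(planted):
    return slicer.build_slices(planted.network)


@pytest.fixture()
def two_cliques_bridge():
    """Two 6-cliques joined by a single bridge edge."""
    g = nx.Graph()
    a = [f"a{i}" for i in range(6)]
    b = [f"b{i}" for i in range(6)]
    g.add_edges_from((u, v) for i, u in enumerate(a) for v in a[i + 1:])
    g.add_edges_from((u, v) for i, u in enumerate(b) for v in b[i + 1:])
    g.add_edge(a[0], b[0])
    return GeneNetwork(g)
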