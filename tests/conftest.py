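import itertools

import pytest

from herbnetpharm.graph import InteractionGraph
from herbnetpharm.io import load_cassiae_semen_compounds


@pytest.fixture
def triangle() -> InteractionGraph:
    return InteractionGraph(edges=[("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3() -> InteractionGraph:
    return InteractionGraph(edges=[("A", "B"), ("B", "C")])


@pytest.fixture
def star4() -> InteractionGraph:
    """Star with centre ``hub`` and 4 leaves."""
    return InteractionGraph(edges=[("hub", f"L{i}") for i in range(4)])


def complete_graph(n: int) -> InteractionGraph:
    nodes = [chr(ord("A") + i) for i in range(n)]
    return InteractionGraph(edges=list(itertools.combinations(nodes, 2)))


@pytest.fixture
def k4() -> InteractionGraph:
    return complete_graph(4)


@pytest.fixture
def k5() -> InteractionGraph:
    return complete_graph(5)


@pytest.fixture
def k6_minus_edge() -> InteractionGraph:
    g = complete_graph(6)
    g_edges = [e for e in g.edges() if e != ("A", "B")]
    return InteractionGraph(nodes=g.nodes, edges=g_edges)


@pytest.fixture
def herb_compounds():
    """A fresh copy of the packaged 13-row Cassiae semen compound table
    (records are mutable: the screen sets ``is_active``)."""
    return load_cassiae_semen_compounds()
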