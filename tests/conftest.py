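import networkx as nx
import pytest

from veriset import fixtures as fx
from veriset import ontology as onto


@pytest.fixture(scope="session")
def world():
    """Small deterministic fixture world shared across the suite."""
    return fx.generate_world(seed=7, n_terms=30, n_genes=120, n_sets=10, n_negative=2)


@pytest.fixture(scope="session")
def encoder():
    return fx.ToyEncoder()


@pytest.fixture()
def diamond_tail_graph():
    """Six-node DAG: A -> {B, C} -> D -> E -> F (diamond plus a tail).

    Hand-enumerated ancestor distances from A: B=1, C=1, D=2, E=3, F=4.
    """
    g = nx.MultiDiGraph()
    for n in "ABCDEF":
        g.add_node(n, name=f"term {n}")
    g.add_edge("A", "B", key="is_a")
    g.add_edge("A", "C", key="part_of")
    g.add_edge("B", "D", key="regulates")
    g.add_edge("C", "D", key="is_a")
    g.add_edge("D", "E", key="positively_regulates")
    g.add_edge("E", "F", key="negatively_regulates")
    return onto.from_networkx(g)
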