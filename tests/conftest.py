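import networkx as nx
import numpy as np
import pytest

from mllayout.graph_model import Graph, build_graph
from mllayout.semsim_eval import AnnotationMap, OntologyDAG


def graph_from_edges(edges, weights=None, level=0):
    """Build a Graph directly, optionally with explicit node weights."""
    g = nx.Graph()
    g.add_edges_from(edges)
    nx.set_node_attributes(g, 1, "weight")
    if weights:
        for v, w in weights.items():
            g.nodes[v]["weight"] = w
    return Graph(g, level=level)


def random_connected_graph(n, p, seed):
    """Erdos-Renyi graph resampled until connected (small n only)."""
    rng = np.random.default_rng(seed)
    while True:
        g = nx.erdos_renyi_graph(n, p, seed=int(rng.integers(0, 2**31 - 1)))
        if g.number_of_nodes() >= 2 and nx.is_connected(g):
            return build_graph([(str(u), str(v)) for u, v in g.edges])


@pytest.fixture
def triangle():
    return build_graph([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def eight_node_network():
    """Connected 8-node, 10-edge network in which the matched pairs
    (N2,N3), (N4,N8) and (N6,N7) are all edges — a miniature of the dense
    sub-networks the coarsening phase is designed for."""
    return build_graph(
        [
            ("N1", "N2"), ("N2", "N3"), ("N1", "N3"), ("N3", "N4"), ("N4", "N8"),
            ("N8", "N7"), ("N6", "N7"), ("N5", "N6"), ("N5", "N7"), ("N2", "N6"),
        ]
    )


@pytest.fixture
def toy_ontology():
    """Six-term DAG with two branches and one multi-parent term.

            root
           /    \\
          b1     b2
         /  \\   /
        t1   t2 (t2 is_a b1 and is_a b2)
        |
        t3
    """
    terms = ["root", "b1", "b2", "t1", "t2", "t3"]
    edges = [("b1", "root"), ("b2", "root"), ("t1", "b1"), ("t2", "b1"), ("t2", "b2"), ("t3", "t1")]
    return OntologyDAG(terms, edges)


@pytest.fixture
def toy_annotations(toy_ontology):
    ann = {
        "gene1": {"t1"},
        "gene2": {"t2"},
        "gene3": {"t3"},
        "gene4": {"b2"},
    }
    return AnnotationMap(ann, toy_ontology)
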