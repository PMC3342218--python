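"""Core undirected graph model with node weights.

A :class:`Graph` is a simple undirected graph whose nodes carry positive
integer weights.  At hierarchy level 0 every weight is 1; a metanode produced
by coarsening weighs the number of original nodes it represents, so the total
weight is conserved across hierarchy levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

logger = logging.getLogger(__name__)

NodeId = str


class GraphModelError(ValueError):
    """Raised for malformed graph inputs (empty edge lists, unknown nodes...)."""


class Graph:
    """Simple undirected graph with positive integer node weights.

    Parameters
    ----------
    nx_graph : networkx.Graph
        Backing graph; each node must carry a ``weight`` attribute (>= 1).
    level : int
        Hierarchy level; 0 for an original input graph.
    """

    def __init__(self, nx_graph: nx.Graph, level: int = 0):
        self._g = nx_graph
        self.level = int(level)

    # -- basic accessors ---------------------------------------------------
    @property
    def nx(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> list[NodeId]:
        return list(self._g.nodes)

    @property
    def edges(self) -> list[tuple[NodeId, NodeId]]:
        return [tuple(sorted(e)) for e in self._g.edges]

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def node_weight(self, v: NodeId) -> int:
        return self._g.nodes[v]["weight"]

    @property
    def total_weight(self) -> int:
        return sum(w for _, w in self._g.nodes(data="weight"))

    def degree(self, v: NodeId) -> int:
        return self._g.degree[v]

    def neighbors(self, v: NodeId) -> list[NodeId]:
        return list(self._g.neighbors(v))

    def has_edge(self, u: NodeId, v: NodeId) -> bool:
        return self._g.has_edge(u, v)

    def __contains__(self, v: NodeId) -> bool:
        return v in self._g

    def __eq__(self, other) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return (
            self.level == other.level
            and set(self._g.nodes) == set(other._g.nodes)
            and {frozenset(e) for e in self._g.edges} == {frozenset(e) for e in other._g.edges}
            and all(self.node_weight(v) == other.node_weight(v) for v in self._g.nodes)
        )

    def __repr__(self) -> str:
        return f"Graph(n={self.n_nodes}, m={self.n_edges}, level={self.level})"

    def copy(self) -> "Graph":
        return Graph(self._g.copy(), self.level)


@dataclass(frozen=True)
class NetworkSummary:
    """Topological summary of a network: the standard density / degree /
    clustering-coefficient statistics reported for interaction networks."""

    n_nodes: int
    n_edges: int
    density: float
    mean_node_degree: float
    sd_node_degree: float
    mean_clustering_coefficient: float

    def as_tsv_row(self) -> str:
        return (
            f"{self.n_nodes}\t{self.n_edges}\t{self.density:.3f}\t"
            f"{self.mean_node_degree:.4g}\t{self.sd_node_degree:.4g}\t"
            f"{self.mean_clustering_coefficient:.3f}"
        )


def build_graph(edge_pairs) -> Graph:
    """Build a level-0 graph from an iterable of node-id pairs.

    Node identifiers are coerced to strings (gene symbols and ORF names
    coexist in interaction files, so ids are opaque strings throughout).
    Duplicate edges and self-loops are dropped with a log entry, since
    interaction files routinely contain both.
    """
    g = nx.Graph()
    n_selfloops = 0
    n_pairs = 0
    for pair in edge_pairs:
        u, v = str(pair[0]), str(pair[1])
        n_pairs += 1
        if u == v:
            n_selfloops += 1
            continue
        g.add_edge(u, v)
    if n_pairs == 0:
        raise GraphModelError("empty edge list: cannot build a graph with no edges")
    if n_selfloops:
        logger.warning("dropped %d self-loop(s) while building graph", n_selfloops)
    dupes = n_pairs - n_selfloops - g.number_of_edges()
    if dupes:
        logger.info("collapsed %d duplicate edge(s)", dupes)
    nx.set_node_attributes(g, 1, "weight")
    return Graph(g, level=0)


def largest_connected_component(g: Graph) -> Graph:
    """Induced subgraph on the largest connected component.

    Ties in component size are broken by the lexicographically smallest
    member node id, so repeated runs always pick the same component.
    """
    if g.n_nodes == 0:
        raise GraphModelError("cannot take the largest component of an empty graph")
    comps = list(nx.connected_components(g.nx))
    comps.sort(key=lambda c: (-len(c), min(c)))
    sub = g.nx.subgraph(comps[0]).copy()
    return Graph(sub, level=g.level)


def clustering_coefficient(g: Graph, v: NodeId) -> float:
    """Local clustering coefficient of ``v``: edges among its neighbors
    divided by the maximum possible number of such edges; 0 when deg <= 1."""
    if v not in g:
        raise GraphModelError(f"unknown node: {v!r}")
    return nx.clustering(g.nx, v)


def clustering_coefficients(g: Graph) -> dict[NodeId, float]:
    """Clustering coefficient of every node (degree <= 1 nodes score 0)."""
    return nx.clustering(g.nx)
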