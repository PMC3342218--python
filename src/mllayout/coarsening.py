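"""Graph coarsening by randomized weighted edge matching.

Phase 1 of the multilevel method builds a hierarchy of increasingly coarser
graphs G_0, G_1, ..., G_L.  Each step finds a maximal independent set of
edges (a maximal matching) by visiting nodes in random order and pairing each
unmatched node with its unmatched neighbor of smallest weight, then contracts
every matched pair into a metanode whose weight is the sum of its members.
Finding a maximum matching is NP-hard in the weighted formulation used here;
the greedy randomized scheme deliberately settles for maximal, non-optimal
matchings.  Coarsening stops when at most two nodes remain, so a connected
input ends at a coarsest graph of two nodes and one edge.

The ``degree_modified`` weighting scores a candidate partner u by
w(u) * (1 + deg(u)) instead of w(u) alone, penalizing high-degree hubs so
that star-like structures are not swallowed into a single heavy metanode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph_model import Graph, GraphModelError, NodeId

WEIGHTINGS = ("original", "degree_modified")


@dataclass(frozen=True)
class Matching:
    """A maximal matching: disjoint matched pairs plus leftover singletons."""

    pairs: frozenset[frozenset]
    singletons: frozenset

    def covered_nodes(self) -> set:
        out = set(self.singletons)
        for p in self.pairs:
            out |= set(p)
        return out


@dataclass
class GraphHierarchy:
    """The coarsening hierarchy G_0 .. G_L with per-level parent maps.

    ``parent_maps[i]`` sends every node of ``levels[i]`` to its metanode in
    ``levels[i + 1]``.
    """

    levels: list[Graph] = field(default_factory=list)
    parent_maps: list[dict[NodeId, NodeId]] = field(default_factory=list)

    @property
    def depth(self) -> int:
        """The index L of the coarsest graph."""
        return len(self.levels) - 1

    def members(self, level: int, metanode: NodeId) -> set[NodeId]:
        """Nodes of ``levels[level - 1]`` merged into ``metanode``."""
        return {v for v, p in self.parent_maps[level - 1].items() if p == metanode}


def _score(g: Graph, u: NodeId, weighting: str) -> float:
    if weighting == "original":
        return g.node_weight(u)
    return g.node_weight(u) * (1 + g.degree(u))


def match_nodes(g: Graph, weighting: str = "degree_modified", rng_seed: int = 0) -> Matching:
    """Greedy maximal matching over a random visit order.

    Visits nodes in an order shuffled by ``rng_seed``; each still-unmatched
    node is paired with its unmatched neighbor minimizing the weighting score,
    ties broken by smallest node id.  Nodes with no unmatched neighbor are
    left as singletons and carry over to the next level unchanged.
    """
    if weighting not in WEIGHTINGS:
        raise ValueError(f"weighting must be one of {WEIGHTINGS}, got {weighting!r}")
    if g.n_nodes == 0:
        raise GraphModelError("cannot match an empty graph")
    rng = np.random.default_rng(rng_seed)
    order = sorted(g.nodes)
    rng.shuffle(order)
    matched: dict[NodeId, NodeId] = {}
    pairs = set()
    for v in order:
        if v in matched:
            continue
        candidates = [u for u in g.neighbors(v) if u not in matched]
        if not candidates:
            continue
        best = min(candidates, key=lambda u: (_score(g, u, weighting), u))
        matched[v] = best
        matched[best] = v
        pairs.add(frozenset((v, best)))
    singletons = frozenset(v for v in g.nodes if v not in matched)
    return Matching(pairs=frozenset(pairs), singletons=singletons)


def contract(g: Graph, m: Matching) -> tuple[Graph, dict[NodeId, NodeId]]:
    """Contract a matching into the next-level graph.

    Each matched pair becomes one metanode weighing the sum of its members;
    singletons carry over with their weight.  Edges are projected onto the
    metanodes: parallel edges collapse and the intra-pair edge disappears.
    Metanodes are named after their lexicographically smallest member, which
    keeps ids stable and runs reproducible.
    """
    if m.covered_nodes() != set(g.nodes):
        raise GraphModelError("matching does not cover exactly the nodes of the graph")
    parent: dict[NodeId, NodeId] = {}
    weights: dict[NodeId, int] = {}
    for pair in m.pairs:
        a, b = sorted(pair)
        if not g.has_edge(a, b):
            raise GraphModelError(f"matched pair ({a}, {b}) is not an edge")
        parent[a] = parent[b] = a
        weights[a] = g.node_weight(a) + g.node_weight(b)
    for v in m.singletons:
        parent[v] = v
        weights[v] = g.node_weight(v)
    coarse = nx.Graph()
    for meta, w in weights.items():
        coarse.add_node(meta, weight=w)
    for u, v in g.edges:
        pu, pv = parent[u], parent[v]
        if pu != pv:
            coarse.add_edge(pu, pv)
    return Graph(coarse, level=g.level + 1), parent


def build_hierarchy(g: Graph, weighting: str = "degree_modified", rng_seed: int = 0) -> GraphHierarchy:
    """Repeat match + contract until at most two nodes remain.

    Requires a connected input (extract the largest component first); a
    connected graph with >= 2 nodes always yields at least one matched pair,
    so progress is guaranteed, but a zero-pair level is guarded anyway.
    """
    if g.n_nodes < 2:
        raise GraphModelError("hierarchy needs a graph with at least 2 nodes")
    if not nx.is_connected(g.nx):
        raise GraphModelError(
            "input graph is disconnected; extract the largest connected component first"
        )
    rng = np.random.default_rng(rng_seed)
    hierarchy = GraphHierarchy(levels=[g])
    current = g
    while current.n_nodes > 2:
        level_seed = int(rng.integers(0, 2**31 - 1))
        m = match_nodes(current, weighting=weighting, rng_seed=level_seed)
        if not m.pairs:  # cannot occur on a connected graph; guard regardless
            break
        coarse, parent = contract(current, m)
        hierarchy.levels.append(coarse)
        hierarchy.parent_maps.append(parent)
        current = coarse
    return hierarchy
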