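"""Topological summary statistics for interaction networks.

Reproduces the usual summary row for a network: node and edge counts,
density D = 2m / (n(n-1)), mean node degree MND = 2m / n with its standard
deviation, and the mean clustering coefficient (MCC) averaged over all nodes,
counting degree <= 1 nodes as 0.
"""

from __future__ import annotations

import numpy as np

from .graph_model import Graph, GraphModelError, NetworkSummary, clustering_coefficients


def density(n_nodes: int, n_edges: int) -> float:
    """Edge density of a simple undirected graph, 2m / (n(n-1))."""
    if n_nodes < 2:
        raise GraphModelError("density needs at least 2 nodes")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def mean_node_degree(g: Graph) -> float:
    """Mean degree 2m / n."""
    if g.n_nodes == 0:
        raise GraphModelError("mean degree of an empty graph is undefined")
    return 2.0 * g.n_edges / g.n_nodes


def sd_node_degree(g: Graph, sample: bool = False) -> float:
    """Standard deviation of the degree sequence.

    Population SD by default; ``sample=True`` uses the n-1 denominator.
    """
    degrees = np.array([g.degree(v) for v in g.nodes], dtype=float)
    if degrees.size <= 1:
        return 0.0
    return float(np.std(degrees, ddof=1 if sample else 0))


def mean_clustering_coefficient(g: Graph) -> float:
    """Average local clustering coefficient over all nodes."""
    ccs = clustering_coefficients(g)
    return float(np.mean(list(ccs.values()))) if ccs else 0.0


def summarize(g: Graph) -> NetworkSummary:
    """All six summary statistics for a non-empty graph."""
    if g.n_nodes == 0:
        raise GraphModelError("cannot summarize an empty graph")
    return NetworkSummary(
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
        density=density(g.n_nodes, g.n_edges) if g.n_nodes >= 2 else 0.0,
        mean_node_degree=mean_node_degree(g),
        sd_node_degree=sd_node_degree(g),
        mean_clustering_coefficient=mean_clustering_coefficient(g),
    )
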