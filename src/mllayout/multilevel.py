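"""Multilevel layout orchestration: uncoarsening with per-level refinement.

Phase 2 of the multilevel method.  The coarsest graph (two nodes when the
input is connected) is placed at random on the canvas; walking back down the
hierarchy, the members of each metanode start at the metanode's final
position and are refined with the node-weighted force engine before the next
finer level is expanded.  Clustering coefficients are computed once on the
original graph and carried up to metanodes as the weight-weighted mean of
their members', so the modulation at coarse levels reflects the density of
the original neighborhoods.  If a refined layout grows wider than the width
limit, coordinates and spring length are rescaled together, which preserves
the geometry while guarding against coordinate underflow on extreme graphs.
"""

from __future__ import annotations

from dataclasses import replace

import networkx as nx
import numpy as np

from .coarsening import build_hierarchy
from .forcelayout import ForceParams, Layout, refine_level
from .graph_model import Graph, GraphModelError, NodeId, clustering_coefficients

MIN_SPRING_LENGTH = 1e-3  # floor guarding against inter-node distance underflow
CANVAS_FACTOR = 10.0  # coarsest-level canvas is a square of side 10 * k


def _propagate_cc(hierarchy, cc0: dict[NodeId, float]) -> list[dict[NodeId, float]]:
    """CC per level: metanode CC is the weight-weighted mean of its members'."""
    maps = [cc0]
    for lvl, parent in enumerate(hierarchy.parent_maps):
        fine = hierarchy.levels[lvl]
        cc_fine = maps[-1]
        num: dict[NodeId, float] = {}
        den: dict[NodeId, float] = {}
        for v, p in parent.items():
            w = fine.node_weight(v)
            num[p] = num.get(p, 0.0) + w * cc_fine[v]
            den[p] = den.get(p, 0.0) + w
        maps.append({p: num[p] / den[p] for p in num})
    return maps


def auto_downscale(current: Layout, p: ForceParams) -> tuple[Layout, ForceParams]:
    """Shrink layout and spring length together when the extent is too wide.

    If the bounding-box width or height exceeds ``p.width_limit``, all
    coordinates and the spring length are multiplied by
    width_limit / max(extent) — a pure similarity transform.  The spring
    length never drops below ``MIN_SPRING_LENGTH``.
    """
    x0, y0, x1, y1 = current.bounding_box()
    extent = max(x1 - x0, y1 - y0)
    if extent <= p.width_limit:
        return current, p
    s = p.width_limit / extent
    new_k = max(p.spring_length * s, MIN_SPRING_LENGTH)
    scaled = Layout(
        {v: (x * s, y * s) for v, (x, y) in current.positions.items()},
        new_k,
        dict(current.metadata),
    )
    return scaled, replace(p, spring_length=new_k)


def random_layout(g: Graph, p: ForceParams, rng_seed: int = 0) -> Layout:
    """Uniform random placement on the canvas — the null reference layout."""
    rng = np.random.default_rng(rng_seed)
    half = CANVAS_FACTOR * p.spring_length / 2.0
    ids = sorted(g.nodes)
    pts = rng.uniform(-half, half, size=(len(ids), 2))
    return Layout(
        {v: (float(pts[i, 0]), float(pts[i, 1])) for i, v in enumerate(ids)},
        p.spring_length,
        {"seed": rng_seed, "method": "random"},
    )


def multilevel_layout(
    g: Graph,
    p: ForceParams | None = None,
    weighting: str = "degree_modified",
    rng_seed: int = 0,
    clustering: bool = True,
) -> Layout:
    """Full multilevel layout of a connected graph.

    Builds the coarsening hierarchy, places the coarsest graph uniformly at
    random within the canvas, and refines level by level: members of a
    metanode are expanded at the metanode's final position (pass-through
    nodes inherit their own), the force engine refines the level, and the
    layout is auto-downscaled if it grew too wide.  ``clustering=True``
    (the default) enables the CC modulation; ``clustering=False`` runs the
    plain node-weighted engine.
    """
    if p is None:
        p = ForceParams()
    if g.n_nodes < 2:
        raise GraphModelError("layout needs at least 2 nodes")
    if not nx.is_connected(g.nx):
        raise GraphModelError(
            "input graph is disconnected; extract the largest connected component first"
        )
    rng = np.random.default_rng(rng_seed)
    hier_seed = int(rng.integers(0, 2**31 - 1))
    hierarchy = build_hierarchy(g, weighting=weighting, rng_seed=hier_seed)

    if clustering:
        cc_maps = _propagate_cc(hierarchy, clustering_coefficients(g))
        work = p
    else:
        cc_maps = None
        work = replace(p, cc_alpha=0.0, cc_beta=0.0)

    half = CANVAS_FACTOR * work.spring_length / 2.0
    coarsest = hierarchy.levels[-1]
    ids = sorted(coarsest.nodes)
    pts = rng.uniform(-half, half, size=(len(ids), 2))
    layout = Layout(
        {v: (float(pts[i, 0]), float(pts[i, 1])) for i, v in enumerate(ids)},
        work.spring_length,
        {},
    )

    iteration_counts: list[int] = []
    for level in range(hierarchy.depth, -1, -1):
        graph_i = hierarchy.levels[level]
        if level < hierarchy.depth:
            parent = hierarchy.parent_maps[level]
            layout = Layout(
                {v: layout.positions[parent[v]] for v in graph_i.nodes},
                work.spring_length,
                layout.metadata,
            )
        cc_map = cc_maps[level] if cc_maps is not None else None
        level_seed = int(rng.integers(0, 2**31 - 1))
        layout = refine_level(graph_i, layout, work, cc_map=cc_map, rng_seed=level_seed)
        iteration_counts.append(layout.metadata["iterations"])
        layout, work = auto_downscale(layout, work)

    layout.metadata.update(
        {
            "seed": rng_seed,
            "depth": hierarchy.depth,
            "iterations_per_level": iteration_counts,  # coarsest first
            "weighting": weighting,
            "clustering": clustering,
            "method": "mll-c" if clustering else "mll",
        }
    )
    return layout


def single_level_layout(
    g: Graph, p: ForceParams | None = None, rng_seed: int = 0
) -> Layout:
    """Plain force-directed layout: one refinement of G_0 from random start.

    This is the single-level baseline the multilevel variants are compared
    against — the hierarchy depth is forced to 0 and the clustering gains to
    zero, leaving the classic weighted spring embedder.
    """
    if p is None:
        p = ForceParams()
    if g.n_nodes < 2:
        raise GraphModelError("layout needs at least 2 nodes")
    work = replace(p, cc_alpha=0.0, cc_beta=0.0)
    rng = np.random.default_rng(rng_seed)
    init = random_layout(g, work, rng_seed=int(rng.integers(0, 2**31 - 1)))
    layout = refine_level(g, init, work, cc_map=None, rng_seed=int(rng.integers(0, 2**31 - 1)))
    layout, _ = auto_downscale(layout, work)
    layout.metadata.update({"seed": rng_seed, "depth": 0, "method": "fdl"})
    return layout


def repeat_layout(
    g: Graph,
    p: ForceParams | None = None,
    n_runs: int = 10,
    base_seed: int = 0,
    weighting: str = "degree_modified",
    clustering: bool = True,
) -> list[Layout]:
    """Independent layouts with seeds base_seed .. base_seed + n_runs - 1,
    for replicate averaging and SEM downstream."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    return [
        multilevel_layout(
            g, p, weighting=weighting, rng_seed=base_seed + i, clustering=clustering
        )
        for i in range(n_runs)
    ]
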