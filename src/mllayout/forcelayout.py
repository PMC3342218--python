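"""Node-weighted force-directed placement with clustering-coefficient modulation.

The force model is the classic spring-embedder of the Fruchterman-Reingold
family.  For a natural spring length k, two nodes at distance d repel with
magnitude C * w * k^2 / d (w the weight of the repelling node, C a user
multiplier) and connected nodes attract with magnitude d^2 / k.  Node weights
make metanodes representing many original nodes push harder, which is what
keeps coarse-level layouts honest about the mass they stand for.

The clustering option modulates both forces by local clustering coefficients
(CC): the attraction of an edge grows with the mean CC of its endpoints and
the repulsion between non-adjacent nodes grows with the larger of their CCs,
so dense modules contract internally and push away from each other.  With
both gains at zero the engine is the plain node-weighted spring embedder.

Each refinement sweep computes all displacements simultaneously from the
current positions, caps each node's move by the current temperature, and
cools geometrically; iteration stops when the largest move falls below
tolerance * k or the iteration budget is exhausted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graph_model import Graph, NodeId
from .spatial_index import build_index


@dataclass
class Layout:
    """2-D positions for one graph, plus the scale and provenance metadata."""

    positions: dict[NodeId, tuple[float, float]]
    spring_length: float
    metadata: dict = field(default_factory=dict)

    def as_array(self, ids: list[NodeId]) -> np.ndarray:
        return np.asarray([self.positions[i] for i in ids], dtype=float)

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y); zeros for an empty layout."""
        if not self.positions:
            return (0.0, 0.0, 0.0, 0.0)
        pts = np.asarray(list(self.positions.values()), dtype=float)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        return (float(lo[0]), float(lo[1]), float(hi[0]), float(hi[1]))

    def copy(self) -> "Layout":
        return Layout(dict(self.positions), self.spring_length, dict(self.metadata))


@dataclass
class ForceParams:
    """Tunable parameters of the layout engine.

    spring_length : float
        Natural spring length k, the target edge length and global scale
        of the layout (layout units).
    repulsion_multiplier : float
        C; larger values increase the effect of the repulsive force.
    tolerance : float
        Convergence control; refinement stops once the largest per-node move
        in a sweep drops below tolerance * k.  Higher values converge faster.
    cc_alpha, cc_beta : float
        Clustering gains on attraction and repulsion; 0 disables the
        clustering modulation entirely.
    cutoff_factor : float
        Repulsion beyond cutoff_factor * k * sqrt(w) is truncated when a
        spatial index backend is used; the brute backend applies no cutoff.
    max_iterations : int
        Sweep budget per refinement level.
    cooling_factor : float
        Geometric temperature decay per sweep, in (0, 1).
    width_limit : float
        Auto-downscaling threshold on the bounding-box extent.
    """

    spring_length: float = 100.0
    repulsion_multiplier: float = 0.2
    tolerance: float = 0.01
    cc_alpha: float = 1.0
    cc_beta: float = 1.0
    cutoff_factor: float = 3.0
    max_iterations: int = 300
    cooling_factor: float = 0.95
    width_limit: float = 1e6
    spatial_backend: str = "grid"

    def __post_init__(self):
        if self.spring_length <= 0:
            raise ValueError("spring_length must be positive")
        if self.repulsion_multiplier <= 0:
            raise ValueError("repulsion_multiplier must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not 0 < self.cooling_factor < 1:
            raise ValueError("cooling_factor must be in (0, 1)")


def repulsive_force(d: float, k: float, C: float, w_other: float = 1.0) -> float:
    """Repulsion magnitude C * w * k^2 / d at distance d > 0."""
    return C * w_other * k * k / d


def attractive_force(d: float, k: float) -> float:
    """Attraction magnitude d^2 / k between connected nodes."""
    return d * d / k


def cc_modulate(
    f_attr: float,
    f_rep: float,
    cc_u: float,
    cc_v: float,
    cc_alpha: float,
    cc_beta: float,
    adjacent: bool,
) -> tuple[float, float]:
    """Apply the clustering-coefficient modulation to one force pair.

    Adjacent pairs get their attraction scaled by 1 + alpha * mean(CC);
    non-adjacent pairs get their repulsion scaled by 1 + beta * max(CC).
    With both gains zero the forces pass through unchanged.
    """
    if adjacent:
        f_attr = f_attr * (1.0 + cc_alpha * 0.5 * (cc_u + cc_v))
    else:
        f_rep = f_rep * (1.0 + cc_beta * max(cc_u, cc_v))
    return f_attr, f_rep


def _jitter_coincident(pos: np.ndarray, k: float, rng: np.random.Generator) -> np.ndarray:
    """Separate exactly coincident points by 1e-4 * k in seeded directions.

    Uncoarsening co-places the members of a metanode, so every level starts
    with coincident pairs; without this the repulsion direction is undefined.
    """
    seen: dict[tuple[float, float], int] = {}
    pos = pos.copy()
    for i in range(len(pos)):
        key = (pos[i, 0], pos[i, 1])
        if key in seen:
            theta = rng.uniform(0.0, 2.0 * np.pi)
            pos[i] += 1e-4 * k * np.array([np.cos(theta), np.sin(theta)])
        else:
            seen[key] = i
    return pos


def _pairwise_repulsion(pos, w, cc, adj_matrix, p: ForceParams):
    """Full O(n^2) repulsion displacement (no cutoff)."""
    k, C = p.spring_length, p.repulsion_multiplier
    delta = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt(np.sum(delta * delta, axis=2))
    np.fill_diagonal(d, np.inf)
    d = np.maximum(d, 1e-12 * k)  # jitter keeps true zeros out; belt and braces
    mag = C * w[None, :] * k * k / d
    if p.cc_beta != 0.0:
        factor = 1.0 + p.cc_beta * np.maximum(cc[:, None], cc[None, :])
        mag = np.where(adj_matrix, mag, mag * factor)
    return np.sum(delta / d[:, :, None] * mag[:, :, None], axis=1)


def _indexed_repulsion(pos, w, cc, neighbor_sets, p: ForceParams):
    """Repulsion truncated at cutoff_factor * k * sqrt(w_i), via the index."""
    k, C = p.spring_length, p.repulsion_multiplier
    n = len(pos)
    index = build_index({i: pos[i] for i in range(n)}, backend=p.spatial_backend)
    disp = np.zeros_like(pos)
    for i in range(n):
        radius = p.cutoff_factor * k * np.sqrt(w[i])
        others = index.query_indices(pos[i], radius)
        others = others[others != i]
        if others.size == 0:
            continue
        delta = pos[i] - pos[others]
        d = np.sqrt(np.sum(delta * delta, axis=1))
        d = np.maximum(d, 1e-12 * k)
        mag = C * w[others] * k * k / d
        if p.cc_beta != 0.0:
            nonadj = ~np.isin(others, neighbor_sets[i])
            factor = 1.0 + p.cc_beta * np.maximum(cc[i], cc[others])
            mag = np.where(nonadj, mag * factor, mag)
        disp[i] = np.sum(delta / d[:, None] * mag[:, None], axis=0)
    return disp


def sweep(pos, w, cc, edge_idx, adj_matrix, neighbor_sets, p: ForceParams, temperature):
    """One simultaneous displacement step; returns (new positions, max move)."""
    k = p.spring_length
    if p.spatial_backend == "brute":
        disp = _pairwise_repulsion(pos, w, cc, adj_matrix, p)
    else:
        disp = _indexed_repulsion(pos, w, cc, neighbor_sets, p)
    ei, ej = edge_idx
    if ei.size:
        delta = pos[ei] - pos[ej]
        d = np.sqrt(np.sum(delta * delta, axis=1))
        safe = np.maximum(d, 1e-12 * k)
        mag = d * d / k
        if p.cc_alpha != 0.0:
            mag = mag * (1.0 + p.cc_alpha * 0.5 * (cc[ei] + cc[ej]))
        pull = delta / safe[:, None] * mag[:, None]
        np.add.at(disp, ei, -pull)
        np.add.at(disp, ej, pull)
    lengths = np.sqrt(np.sum(disp * disp, axis=1))
    scale = np.ones_like(lengths)
    moving = lengths > 0
    scale[moving] = np.minimum(1.0, temperature / lengths[moving])
    new_pos = pos + disp * scale[:, None]
    max_move = float(np.max(lengths * scale)) if len(lengths) else 0.0
    return new_pos, max_move


def refine_level(
    g: Graph,
    initial: Layout,
    p: ForceParams,
    cc_map: dict[NodeId, float] | None = None,
    rng_seed: int = 0,
) -> Layout:
    """Refine one hierarchy level from an initial placement.

    Iterates displacement sweeps until the largest per-node move falls below
    tolerance * k or ``max_iterations`` is reached (the latter returns the
    current layout with a logged warning rather than failing).  With
    ``cc_map`` given and non-zero gains the clustering modulation is active;
    pass ``None`` (or zero gains) for the plain node-weighted embedder.
    """
    ids = sorted(g.nodes)
    missing = [v for v in ids if v not in initial.positions]
    if missing:
        raise ValueError(f"initial layout misses {len(missing)} node(s), e.g. {missing[0]!r}")
    rng = np.random.default_rng(rng_seed)
    pos = initial.as_array(ids)
    k = p.spring_length
    pos = _jitter_coincident(pos, k, rng)

    w = np.asarray([g.node_weight(v) for v in ids], dtype=float)
    if cc_map is None:
        cc = np.zeros(len(ids))
    else:
        cc = np.asarray([cc_map.get(v, 0.0) for v in ids], dtype=float)
    pos_of = {v: i for i, v in enumerate(ids)}
    ei = np.asarray([pos_of[u] for u, v in g.edges], dtype=int)
    ej = np.asarray([pos_of[v] for u, v in g.edges], dtype=int)
    adj_matrix = None
    neighbor_sets = None
    if p.spatial_backend == "brute":
        adj_matrix = np.zeros((len(ids), len(ids)), dtype=bool)
        if ei.size:
            adj_matrix[ei, ej] = True
            adj_matrix[ej, ei] = True
    else:
        neighbor_sets = [
            np.asarray(sorted(pos_of[u] for u in g.neighbors(v)), dtype=int) for v in ids
        ]

    lo, hi = pos.min(axis=0), pos.max(axis=0)
    diag = float(np.sqrt(np.sum((hi - lo) ** 2)))
    # floored at k: a freshly expanded level can start almost fully coincident,
    # and a temperature tied to its tiny extent would freeze refinement
    temperature = max(0.1 * diag, k)

    iterations = 0
    for iterations in range(1, p.max_iterations + 1):
        pos, max_move = sweep(pos, w, cc, (ei, ej), adj_matrix, neighbor_sets, p, temperature)
        temperature *= p.cooling_factor
        if max_move < p.tolerance * k:
            break
    else:  # pragma: no cover - depends on parameters
        logging.getLogger(__name__).warning(
            "refinement did not converge in %d iterations (level %d)",
            p.max_iterations,
            g.level,
        )

    meta = dict(initial.metadata)
    meta.update({"seed": rng_seed, "level": g.level, "iterations": iterations})
    return Layout({v: (float(pos[i, 0]), float(pos[i, 1])) for i, v in enumerate(ids)}, k, meta)
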