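"""Exact metric indexes over 2-D node positions.

During force refinement, the repulsion acting on a node is summed over the
nodes inside a cutoff ball, so the engine needs fast exact radius queries.
Three interchangeable backends share one contract — a radius query returns
exactly the set of points within Euclidean distance r of the query (closed
ball), no false positives and no misses:

``mtree``
    A metric tree: internal nodes store a pivot point and a covering radius,
    and a subtree is pruned whenever dist(query, pivot) > r + covering
    radius.  Works from distances alone, i.e. in any metric space.
``grid``
    Uniform bucket grid over the bounding box; candidate cells overlapping
    the ball are gathered and filtered exactly.
``brute``
    Vectorized exhaustive scan; the reference the others are tested against.

All backends are rebuilt from scratch when positions change; at the network
sizes this engine targets, a rebuild is far cheaper than a refinement sweep.
"""

from __future__ import annotations

import numpy as np

BACKENDS = ("brute", "grid", "mtree")

_LEAF_CAPACITY = 16  # max points in an M-tree leaf


class SpatialIndexError(ValueError):
    pass


class _BaseIndex:
    def __init__(self, positions: dict):
        self.ids = list(positions.keys())
        if self.ids:
            self.points = np.asarray([positions[i] for i in self.ids], dtype=float)
            if not np.all(np.isfinite(self.points)):
                raise SpatialIndexError("non-finite coordinate in positions")
        else:
            self.points = np.empty((0, 2), dtype=float)

    def query(self, q, r: float) -> set:
        if r < 0:
            raise SpatialIndexError("radius must be non-negative")
        if len(self.ids) == 0:
            return set()
        return self._query(np.asarray(q, dtype=float), float(r))

    def query_indices(self, q, r: float) -> np.ndarray:
        """Integer positions (into the insertion order) of the hits."""
        if r < 0:
            raise SpatialIndexError("radius must be non-negative")
        if len(self.ids) == 0:
            return np.empty(0, dtype=int)
        return self._query_idx(np.asarray(q, dtype=float), float(r))

    def _query(self, q, r):
        return {self.ids[i] for i in self._query_idx(q, r)}


class BruteIndex(_BaseIndex):
    """Exhaustive scan; exact by construction and the oracle for the others."""

    def _query_idx(self, q, r):
        d2 = np.sum((self.points - q) ** 2, axis=1)
        return np.flatnonzero(d2 <= r * r)


class GridIndex(_BaseIndex):
    """Uniform bucket grid with exact post-filtering."""

    def __init__(self, positions: dict, cell_size: float | None = None):
        super().__init__(positions)
        n = len(self.ids)
        if n == 0:
            return
        self._origin = self.points.min(axis=0)
        extent = self.points.max(axis=0) - self._origin
        if cell_size is None:
            # aim for O(1) points per cell on uniform data
            span = max(float(extent.max()), 1e-12)
            cell_size = span / max(1.0, np.sqrt(n))
        self._cell = float(max(cell_size, 1e-12))
        cells = np.floor((self.points - self._origin) / self._cell).astype(np.int64)
        self._buckets: dict[tuple[int, int], list[int]] = {}
        for i, (cx, cy) in enumerate(cells):
            self._buckets.setdefault((int(cx), int(cy)), []).append(i)

    def _query_idx(self, q, r):
        lo = np.floor((q - r - self._origin) / self._cell).astype(np.int64)
        hi = np.floor((q + r - self._origin) / self._cell).astype(np.int64)
        cand: list[int] = []
        n_cells = (int(hi[0]) - int(lo[0]) + 1) * (int(hi[1]) - int(lo[1]) + 1)
        if n_cells > len(self._buckets):
            # huge ball relative to the occupied cells: scan buckets instead
            for (cx, cy), members in self._buckets.items():
                if lo[0] <= cx <= hi[0] and lo[1] <= cy <= hi[1]:
                    cand.extend(members)
        else:
            for cx in range(int(lo[0]), int(hi[0]) + 1):
                for cy in range(int(lo[1]), int(hi[1]) + 1):
                    cand.extend(self._buckets.get((cx, cy), ()))
        if not cand:
            return np.empty(0, dtype=int)
        idx = np.asarray(cand, dtype=int)
        d2 = np.sum((self.points[idx] - q) ** 2, axis=1)
        return idx[d2 <= r * r]


class _MTreeNode:
    __slots__ = ("pivot", "radius", "children", "leaf_idx")

    def __init__(self, pivot, radius, children=None, leaf_idx=None):
        self.pivot = pivot
        self.radius = radius
        self.children = children
        self.leaf_idx = leaf_idx


class MTreeIndex(_BaseIndex):
    """Metric tree with pivot/covering-radius pruning.

    Built by recursive binary partitioning: the subtree pivot is its first
    point, remaining points are split at the median distance to the pivot.
    A subtree is visited only if the query ball can intersect its covering
    ball, which is what makes the query sub-linear on clustered data while
    remaining exact.
    """

    def __init__(self, positions: dict, leaf_capacity: int = _LEAF_CAPACITY):
        super().__init__(positions)
        self._leaf_capacity = int(leaf_capacity)
        if len(self.ids):
            self._root = self._build(np.arange(len(self.ids)))
        else:
            self._root = None

    def _build(self, idx: np.ndarray) -> _MTreeNode:
        pivot = self.points[idx[0]]
        d = np.sqrt(np.sum((self.points[idx] - pivot) ** 2, axis=1))
        radius = float(d.max())
        if len(idx) <= self._leaf_capacity:
            return _MTreeNode(pivot, radius, leaf_idx=idx)
        med = np.median(d)
        near = idx[d <= med]
        far = idx[d > med]
        if len(near) == 0 or len(far) == 0:  # all at identical distance
            return _MTreeNode(pivot, radius, leaf_idx=idx)
        return _MTreeNode(pivot, radius, children=[self._build(near), self._build(far)])

    def _query_idx(self, q, r):
        hits: list[np.ndarray] = []
        stack = [self._root]
        while stack:
            node = stack.pop()
            if np.sqrt(np.sum((q - node.pivot) ** 2)) > r + node.radius:
                continue  # query ball cannot reach this subtree
            if node.leaf_idx is not None:
                d2 = np.sum((self.points[node.leaf_idx] - q) ** 2, axis=1)
                hits.append(node.leaf_idx[d2 <= r * r])
            else:
                stack.extend(node.children)
        if not hits:
            return np.empty(0, dtype=int)
        return np.concatenate(hits)


_BACKEND_CLASSES = {"brute": BruteIndex, "grid": GridIndex, "mtree": MTreeIndex}


def build_index(positions: dict, backend: str = "grid") -> _BaseIndex:
    """Build an exact radius-query index over ``{node_id: (x, y)}``."""
    if backend not in _BACKEND_CLASSES:
        raise SpatialIndexError(f"unknown backend {backend!r}; choose from {BACKENDS}")
    return _BACKEND_CLASSES[backend](positions)


def range_query(ix: _BaseIndex, q, r: float) -> set:
    """All indexed node ids within Euclidean distance ``r`` of ``q``."""
    return ix.query(q, r)
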