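"""Class-aware weighted pixel graphs and heuristic root reconstruction.

Each segmentation class (first-order, second-order) is converted into an
8-connected pixel lattice whose traversal weights favour root centerlines:
the Euclidean distance transform of the class mask is normalized to [0, 1]
per connected component, then mapped linearly so that pixels at the root
edge cost 0.1 per step, pixels on the centerline 0.01, and off-class
pixels 10.0.  Diagonal steps pay an extra sqrt(2) factor.

Roots are recovered as minimal-cost paths: A* (f = g + h, with a scaled
Manhattan heuristic) from each first-order tip to the seed when a single
seed is present, uniform-cost (Dijkstra) search to the nearest seed when
there are several, and Dijkstra searches from each second-order tip ending
on any pixel of an already-extracted first-order path.
"""

from __future__ import annotations

import heapq
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Plant, Root, RootSystem
from .postprocess import FeatureSet
from .targets import ClassMaps

__all__ = [
    "PixelGraph",
    "distance_map",
    "weight_map",
    "astar",
    "dijkstra_to_set",
    "reconstruct",
    "ON_CLASS_MIN",
    "ON_CLASS_MAX",
    "OFF_CLASS_WEIGHT",
]

logger = logging.getLogger(__name__)

#: traversal cost of an on-class pixel at the root centerline
ON_CLASS_MIN = 0.01
#: traversal cost of an on-class pixel at the root edge
ON_CLASS_MAX = 0.1
#: traversal cost of any pixel outside the class being traversed
OFF_CLASS_WEIGHT = 10.0

_SQRT2 = math.sqrt(2.0)


@dataclass
class PixelGraph:
    """Per-pixel traversal costs for one class, with 8-way connectivity."""

    weights: np.ndarray  # (H, W) float
    on_class_range: tuple[float, float] = (ON_CLASS_MIN, ON_CLASS_MAX)
    off_class_weight: float = OFF_CLASS_WEIGHT
    diagonal_factor: float = _SQRT2

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape


def distance_map(mask: np.ndarray) -> np.ndarray:
    """Normalized distance-to-background transform of a binary class mask.

    Foreground pixels receive their Euclidean distance to the nearest
    background pixel, normalized to [0, 1] *per connected component* (each
    component's maximum maps to 1) so thin and thick roots in one image
    both retain a full-range centering signal.  Background pixels are 0.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return np.zeros(m.shape, dtype=np.float64)
    dist = ndimage.distance_transform_edt(m)
    labels, n = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    if n:
        comp_max = ndimage.maximum(dist, labels, index=np.arange(1, n + 1))
        scale = np.ones(n + 1)
        scale[1:] = np.maximum(comp_max, 1e-9)
        dist = dist / scale[labels]
    return dist


def weight_map(dist: np.ndarray, mask: np.ndarray) -> PixelGraph:
    """Convert a normalized distance map into per-pixel traversal weights.

    On-class pixels: linear from 0.1 at the root edge (dist -> 0) down to
    0.01 on the centerline (dist = 1).  Off-class pixels: 10.0.
    """
    m = np.asarray(mask).astype(bool)
    w = np.full(m.shape, OFF_CLASS_WEIGHT, dtype=np.float64)
    w[m] = ON_CLASS_MAX - (ON_CLASS_MAX - ON_CLASS_MIN) * np.asarray(dist)[m]
    return PixelGraph(weights=w)


def class_graph(mask: np.ndarray) -> PixelGraph:
    """Distance map + weight map in one step."""
    return weight_map(distance_map(mask), mask)


def _search(
    graph: PixelGraph,
    start: tuple[int, int],
    goals: set[tuple[int, int]],
    use_heuristic: bool,
) -> tuple[list[tuple[int, int]], float]:
    """Shared A*/uniform-cost search core.

    Stepping onto pixel q costs weights[q], multiplied by sqrt(2) for
    diagonal steps.  The heuristic is the Manhattan distance to the goal
    scaled by (minimum step weight)/sqrt(2) — the largest constant that
    keeps it admissible and consistent on an 8-connected lattice, where a
    diagonal step can shrink the Manhattan distance by 2 while costing
    only sqrt(2) times the minimum weight.  Ties on f break FIFO.
    """
    h_grid, w_grid = graph.shape
    weights = graph.weights
    if not goals:
        raise ValueError("goal set must be non-empty")
    sx, sy = start
    if not (0 <= sx < w_grid and 0 <= sy < h_grid):
        raise ValueError(f"start {start} outside the grid")

    if start in goals:
        return [start], 0.0

    goal_idx = {gy * w_grid + gx for gx, gy in goals}
    goal_arr = np.array(list(goals), dtype=np.int64)
    h_scale = graph.on_class_range[0] / graph.diagonal_factor

    def heuristic(x: int, y: int) -> float:
        if not use_heuristic:
            return 0.0
        d = np.abs(goal_arr[:, 0] - x) + np.abs(goal_arr[:, 1] - y)
        return h_scale * float(d.min())

    size = h_grid * w_grid
    g = np.full(size, np.inf, dtype=np.float64)
    parent = np.full(size, -1, dtype=np.int64)
    closed = np.zeros(size, dtype=bool)

    start_idx = sy * w_grid + sx
    g[start_idx] = 0.0
    counter = 0
    heap = [(heuristic(sx, sy), counter, start_idx)]
    neigh = [
        (-1, -1, _SQRT2), (0, -1, 1.0), (1, -1, _SQRT2),
        (-1, 0, 1.0), (1, 0, 1.0),
        (-1, 1, _SQRT2), (0, 1, 1.0), (1, 1, _SQRT2),
    ]

    reached = -1
    while heap:
        _, _, idx = heapq.heappop(heap)
        if closed[idx]:
            continue
        closed[idx] = True
        if idx in goal_idx:
            reached = idx
            break
        y, x = divmod(idx, w_grid)
        gi = g[idx]
        for dx, dy, factor in neigh:
            nx, ny = x + dx, y + dy
            if not (0 <= nx < w_grid and 0 <= ny < h_grid):
                continue
            nidx = ny * w_grid + nx
            if closed[nidx]:
                continue
            ng = gi + factor * weights[ny, nx]
            if ng < g[nidx]:
                g[nidx] = ng
                parent[nidx] = idx
                counter += 1
                heapq.heappush(heap, (ng + heuristic(nx, ny), counter, nidx))
    if reached < 0:  # unreachable cannot occur on a finite fully-weighted grid
        raise RuntimeError("search exhausted the grid without reaching a goal")

    path = []
    idx = reached
    while idx >= 0:
        y, x = divmod(idx, w_grid)
        path.append((x, y))
        idx = parent[idx]
    path.reverse()  # recorded goal -> start via parents; reverse to start -> goal
    return path, float(g[reached])


def astar(
    graph: PixelGraph, start: tuple[int, int], goals: set | list | tuple
) -> tuple[list[tuple[int, int]], float]:
    """Minimal-cost 8-connected path from ``start`` to the first goal closed.

    Uses f = g + h with an admissible scaled-Manhattan heuristic, so the
    returned cost is optimal (equal to an exhaustive Dijkstra's).
    """
    return _search(graph, tuple(start), {tuple(p) for p in goals}, True)


def dijkstra_to_set(
    graph: PixelGraph, start: tuple[int, int], goal_set: set | list | tuple
) -> tuple[list[tuple[int, int]], float]:
    """Uniform-cost search terminating at the first settled goal.

    With multiple goals this returns the cheapest path from ``start`` to
    *any* member of the set.
    """
    return _search(graph, tuple(start), {tuple(p) for p in goal_set}, False)


def _off_class_fraction(
    graph: PixelGraph, path: list[tuple[int, int]], cost: float
) -> float:
    if cost <= 0 or len(path) < 2:
        return 0.0
    off = 0.0
    prev = path[0]
    for q in path[1:]:
        step = graph.weights[q[1], q[0]]
        if step >= graph.off_class_weight:
            diag = (q[0] != prev[0]) and (q[1] != prev[1])
            off += step * (graph.diagonal_factor if diag else 1.0)
        prev = q
    return off / cost


def reconstruct(
    class_maps: ClassMaps,
    features: FeatureSet,
    scale: float = 1.0,
    mask_threshold: float = 0.5,
) -> RootSystem:
    """Rebuild the root architecture from class maps and localized features.

    One candidate plant is created per detected seed.  Each first-order tip
    is traced to the seed set on the first-order graph (A* for a single
    seed, Dijkstra-to-set otherwise) and assigned to the plant whose seed
    it reaches.  Each second-order tip is traced on the second-order graph
    to any pixel of an extracted first-order path and attached to the
    owning root at the reached pixel.  Plants that attract no first-order
    root are removed.  Paths are found tip -> seed and reversed so
    polylines run base -> tip; all coordinates are finally multiplied by
    ``scale`` (native resolution / map resolution).
    """
    if not features.seeds:
        warnings.warn("no seeds detected; returning an empty architecture")
        return RootSystem()

    seeds = [(int(round(s[0])), int(round(s[1]))) for s in features.seeds]
    plants = [Plant(seed=np.array(s, dtype=float)) for s in seeds]
    seed_set = set(seeds)
    seed_owner = {s: i for i, s in enumerate(seeds)}

    graph1 = class_graph(np.asarray(class_maps.order1) > mask_threshold)

    pixel_owner: dict[tuple[int, int], Root] = {}
    for tip in features.tips1:
        start = (int(round(tip[0])), int(round(tip[1])))
        if len(seeds) == 1:
            path, cost = astar(graph1, start, seed_set)
        else:
            path, cost = dijkstra_to_set(graph1, start, seed_set)
        frac = _off_class_fraction(graph1, path, cost)
        if frac > 0.3:
            logger.warning(
                "first-order path from %s: %.0f%% of cost on off-class pixels",
                start, 100 * frac,
            )
        if len(path) < 2:
            continue
        reached = path[-1]
        owner = seed_owner.get(reached)
        if owner is None:  # settled a non-goal pixel; cannot happen
            continue
        base_to_tip = np.asarray(path[::-1], dtype=float)
        root = Root(order=1, points=base_to_tip)
        plants[owner].roots.append(root)
        for p in path:
            pixel_owner.setdefault(p, root)

    if pixel_owner:
        graph2 = class_graph(np.asarray(class_maps.order2) > mask_threshold)
        goal_set = set(pixel_owner)
        for tip in features.tips2:
            start = (int(round(tip[0])), int(round(tip[1])))
            path, cost = dijkstra_to_set(graph2, start, goal_set)
            frac = _off_class_fraction(graph2, path, cost)
            if frac > 0.3:
                logger.warning(
                    "second-order path from %s: %.0f%% of cost on off-class pixels",
                    start, 100 * frac,
                )
            if len(path) < 2:
                continue
            attach_px = path[-1]
            parent = pixel_owner[attach_px]
            base_to_tip = np.asarray(path[::-1], dtype=float)
            root = Root(
                order=2,
                points=base_to_tip,
                parent=parent,
                attachment=base_to_tip[0].copy(),
            )
            owner_plant = next(
                pl for pl in plants if any(r is parent for r in pl.roots)
            )
            owner_plant.roots.append(root)

    rs = RootSystem(plants=[p for p in plants if p.roots_of_order(1)])
    if scale != 1.0:
        rs = rs.scaled(scale)
    return rs
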