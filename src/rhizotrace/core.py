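"""Core domain types for root system architectures.

A :class:`RootSystem` is the central in-memory container of the package: a
scene of one or more plants, each owning a seed location and an ordered set
of roots.  Roots are polylines in image pixel coordinates (origin top-left,
x right, y down, so depth increases with y).  First-order roots emerge from
the seed; second-order (lateral) roots emerge from a first-order root and
carry a reference to their parent plus the attachment point on the parent
polyline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Root",
    "Plant",
    "RootSystem",
    "ArchitectureParams",
    "polyline_length",
    "point_to_polyline_distance",
    "project_to_polyline",
    "resample_polyline",
]


def polyline_length(points: np.ndarray) -> float:
    """Arc length of an (N, 2) polyline."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def point_to_polyline_distance(point, points: np.ndarray) -> float:
    """Euclidean distance from ``point`` to the nearest location on a polyline.

    Uses exact point-to-segment projections, not just vertex distances.
    """
    p = np.asarray(point, dtype=float)
    pts = np.asarray(points, dtype=float)
    if len(pts) == 1:
        return float(np.linalg.norm(p - pts[0]))
    a = pts[:-1]
    b = pts[1:]
    ab = b - a
    denom = np.maximum(np.sum(ab * ab, axis=1), 1e-12)
    t = np.clip(np.sum((p - a) * ab, axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(proj - p, axis=1)))


def project_to_polyline(point, polyline: np.ndarray) -> np.ndarray:
    """Closest point on a polyline to ``point`` (exact segment projection)."""
    pts = np.asarray(polyline, dtype=float)
    p = np.asarray(point, dtype=float)
    if len(pts) == 1:
        return pts[0].copy()
    a, b = pts[:-1], pts[1:]
    ab = b - a
    denom = np.maximum(np.sum(ab * ab, axis=1), 1e-12)
    t = np.clip(np.sum((p - a) * ab, axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return proj[np.argmin(np.linalg.norm(proj - p, axis=1))]


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arc-length spacing.

    Endpoints are always preserved.  ``step`` is the target spacing in the
    polyline's own units (pixels here).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return pts.copy()
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return pts[[0, -1]].copy()
    n = max(int(np.ceil(total / step)), 1)
    targets = np.linspace(0.0, total, n + 1)
    x = np.interp(targets, s, pts[:, 0])
    y = np.interp(targets, s, pts[:, 1])
    return np.stack([x, y], axis=1)


@dataclass(eq=False)
class Root:
    """A single root: an ordered polyline running base -> tip.

    order 1 roots have no parent; order 2 roots reference their parent
    (an order-1 :class:`Root`) and the attachment point on its polyline.
    """

    order: int
    points: np.ndarray  # (N, 2) float, N >= 2
    parent: "Root | None" = None
    attachment: np.ndarray | None = None  # (2,) point on parent polyline
    spline: np.ndarray | None = None  # optional smoothed geometry, (M, 2)

    @property
    def tip(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)[-1]

    @property
    def base(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)[0]

    @property
    def length(self) -> float:
        return polyline_length(self.points)

    def validate(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise ValueError("root polyline must be an (N>=2, 2) array")
        if polyline_length(pts) <= 0:
            raise ValueError("root polyline must have positive arc length")
        if self.order == 1:
            if self.parent is not None:
                raise ValueError("order-1 roots cannot have a parent")
        elif self.order == 2:
            if self.parent is None or self.parent.order != 1:
                raise ValueError("order-2 roots require an order-1 parent")
            if self.attachment is None:
                raise ValueError("order-2 roots require an attachment point")
            d = point_to_polyline_distance(self.attachment, self.parent.points)
            if d > 1.0:
                raise ValueError(
                    f"attachment point {d:.2f} px from parent polyline (max 1 px)"
                )
        else:
            raise ValueError(f"unsupported root order {self.order}")


@dataclass(eq=False)
class Plant:
    seed: np.ndarray  # (2,) seed location in pixels
    roots: list[Root] = field(default_factory=list)

    def roots_of_order(self, order: int) -> list[Root]:
        return [r for r in self.roots if r.order == order]

    def validate(self, seed_tolerance: float = 12.0) -> None:
        seed = np.asarray(self.seed, dtype=float)
        if seed.shape != (2,):
            raise ValueError("seed must be an (x, y) point")
        for root in self.roots:
            root.validate()
            if root.order == 1:
                if np.linalg.norm(root.base - seed) > seed_tolerance:
                    raise ValueError("order-1 root does not start at the seed")


@dataclass(eq=False)
class RootSystem:
    plants: list[Plant] = field(default_factory=list)

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    def all_roots(self, order: int | None = None):
        for plant in self.plants:
            for root in plant.roots:
                if order is None or root.order == order:
                    yield plant, root

    def count_roots(self, order: int) -> int:
        return sum(1 for _ in self.all_roots(order))

    def validate(self, seed_tolerance: float = 12.0) -> None:
        for plant in self.plants:
            plant.validate(seed_tolerance=seed_tolerance)

    def scaled(self, factor: float) -> "RootSystem":
        """Return a copy with every coordinate multiplied by ``factor``."""
        out = RootSystem()
        for plant in self.plants:
            new_plant = Plant(seed=np.asarray(plant.seed, float) * factor)
            mapping: dict[int, Root] = {}
            for root in plant.roots:
                if root.order != 1:
                    continue
                nr = Root(order=1, points=np.asarray(root.points, float) * factor)
                if root.spline is not None:
                    nr.spline = np.asarray(root.spline, float) * factor
                mapping[id(root)] = nr
                new_plant.roots.append(nr)
            for root in plant.roots:
                if root.order != 2:
                    continue
                nr = Root(
                    order=2,
                    points=np.asarray(root.points, float) * factor,
                    parent=mapping.get(id(root.parent)),
                    attachment=None
                    if root.attachment is None
                    else np.asarray(root.attachment, float) * factor,
                )
                if root.spline is not None:
                    nr.spline = np.asarray(root.spline, float) * factor
                new_plant.roots.append(nr)
            out.plants.append(new_plant)
        return out


@dataclass
class ArchitectureParams:
    """Parameters of the procedural root-system generator.

    Two assay styles are supported: ``fibrous`` emulates single-plant
    wheat-like systems (several first-order seminal roots from one seed on
    textured germination paper) and ``taproot`` emulates multi-plant
    plate assays (one primary root plus laterals per plant, up to 5 plants,
    dark plate background).
    """

    style: str = "fibrous"
    n_plants: int = 1
    n_first_order: tuple[int, int] = (3, 5)
    laterals_per_root: tuple[int, int] = (0, 3)
    image_size: tuple[int, int] = (512, 512)  # (width, height)
    root_width: float = 8.0
    curvature_noise: float = 0.12  # radians std per growth step
    growth_length: tuple[float, float] = (200.0, 380.0)
    lateral_length: tuple[float, float] | None = None  # None: style default
    rng_seed: int = 0

    def validate(self) -> None:
        if self.style not in ("fibrous", "taproot"):
            raise ValueError(f"unknown style {self.style!r}")
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        if self.style == "fibrous" and self.n_plants != 1:
            raise ValueError("fibrous style implies a single plant")
        ranges = [
            ("n_first_order", self.n_first_order),
            ("laterals_per_root", self.laterals_per_root),
            ("growth_length", self.growth_length),
        ]
        if self.lateral_length is not None:
            ranges.append(("lateral_length", self.lateral_length))
        for name, rng in ranges:
            lo, hi = rng
            if hi < lo:
                raise ValueError(f"{name} range is empty: {rng}")
        if self.style == "taproot" and self.n_first_order != (1, 1):
            # one primary root per plant is the defining property of the style
            raise ValueError("taproot style implies n_first_order == (1, 1)")
        w, h = self.image_size
        if w <= 0 or h <= 0:
            raise ValueError("image_size must be positive")
        if self.root_width <= 0:
            raise ValueError("root_width must be positive")
        if self.curvature_noise < 0:
            raise ValueError("curvature_noise must be >= 0")
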