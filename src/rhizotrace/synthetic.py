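"""Procedural root-system generation and raster rendering.

The generator produces :class:`~rhizotrace.core.RootSystem` scenes by
simulating roots as direction-biased random walks with per-step angular
noise, then renders them as anti-aliased strokes over procedural
backgrounds.  It exists so that every downstream stage (ground-truth
rendering, the network, feature localization, path search, RSML, traits)
is exercisable without any photographic dataset.

Two assay styles are emulated:

* ``fibrous`` — one plant with several first-order roots radiating from a
  single seed (wheat-like), light roots on a blue germination-paper-like
  textured background.
* ``taproot`` — up to five plants side by side, each with a single primary
  root and short laterals (Arabidopsis/Brassica-like), light roots on a
  dark plate-like background.

Ground-truth tips of the same feature class are kept at least 12 px apart
(by rejection sampling) so that discrete tip localization with an 8 px
deduplication radius can recover tip counts exactly.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import (ArchitectureParams, Plant, Root, RootSystem,
                   polyline_length, resample_polyline)

__all__ = [
    "generate_architecture",
    "render_image",
    "MIN_TIP_SEPARATION",
    "fibrous_params",
    "taproot_params",
]

# Minimum separation between ground-truth tips of the same class, in native
# pixels.  Feature localization runs at the network's half-resolution output
# with an 8 px deduplication radius there; 25 native px (12.5 at output
# scale) guarantees distinct true tips can never be merged.
MIN_TIP_SEPARATION = 25.0

# Default lateral root length range, native px, at the reference 512 px
# image width (scaled linearly for other sizes).  Discrete feature
# localization carries ~1 px endpoint quantization and the stroke overlap
# at junctions a comparable amount, so per-root lengths are only
# measurable to a few px; laterals of >= 80 px keep a 5% relative error
# budget at a >= 3-sigma margin of that noise floor.
DEFAULT_LATERAL_LENGTH = (80.0, 150.0)

_STEP = 4.0  # growth step length in px; polylines are stored at this spacing


def fibrous_params(**kw) -> ArchitectureParams:
    """Single-plant wheat-like defaults."""
    kw.setdefault("style", "fibrous")
    kw.setdefault("n_plants", 1)
    return ArchitectureParams(**kw)


def taproot_params(**kw) -> ArchitectureParams:
    """Multi-plant plate-assay defaults (one primary root per plant).

    The plate image defaults to 640 px so that up to 5 plants keep
    non-overlapping slots wide enough for full-length laterals.
    """
    kw.setdefault("style", "taproot")
    kw.setdefault("n_plants", 3)
    kw.setdefault("n_first_order", (1, 1))
    kw.setdefault("laterals_per_root", (2, 4))
    kw.setdefault("image_size", (640, 640))
    kw.setdefault("growth_length", (220.0, 400.0))
    kw.setdefault("lateral_length", (80.0, 120.0))
    return ArchitectureParams(**kw)


def _grow(
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    length: float,
    curvature_noise: float,
    bounds: tuple[float, float],
    max_turn: float = 1.2,
    pull: float = 0.05,
) -> np.ndarray:
    """Simulate a root as a direction-biased random walk.

    ``heading`` is measured from straight down (+y); the walk keeps the
    heading within ``max_turn`` radians of down so growth is predominantly
    downward (y is non-decreasing when |heading| < pi/2; the cap of 1.2 rad
    allows brief near-horizontal excursions only).  ``pull`` is the
    strength of the bias back toward the initial heading; larger values
    give straighter roots.
    """
    w, h = bounds
    pts = [np.asarray(start, dtype=float)]
    theta = float(heading)
    n_steps = max(int(round(length / _STEP)), 2)
    for _ in range(n_steps):
        theta += curvature_noise * rng.normal()
        theta += pull * (heading - theta)
        theta = float(np.clip(theta, -max_turn, max_turn))
        step = _STEP * np.array([np.sin(theta), np.cos(theta)])
        nxt = pts[-1] + step
        if not (2.0 <= nxt[0] <= w - 3.0 and 2.0 <= nxt[1] <= h - 3.0):
            break
        pts.append(nxt)
    return np.asarray(pts)


def _arc_position(points: np.ndarray, frac: float) -> tuple[np.ndarray, float]:
    """Point at fractional arc length plus the local heading (from +y)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = frac * s[-1]
    i = int(np.searchsorted(s, target, side="right") - 1)
    i = min(max(i, 0), len(points) - 2)
    t = (target - s[i]) / max(s[i + 1] - s[i], 1e-9)
    p = points[i] + t * (points[i + 1] - points[i])
    d = points[i + 1] - points[i]
    return p, float(np.arctan2(d[0], d[1]))


def _build_plant(
    rng: np.random.Generator, params: ArchitectureParams, seed_xy: np.ndarray
) -> Plant:
    w, h = params.image_size
    plant = Plant(seed=seed_xy)
    lo, hi = params.n_first_order
    n1 = int(rng.integers(lo, hi + 1))
    if params.style == "fibrous":
        # seminal roots fan out from the seed
        headings = np.linspace(-0.9, 0.9, n1) if n1 > 1 else np.array([0.0])
        headings = headings + 0.12 * rng.normal(size=n1)
        pull, curv = 0.05, params.curvature_noise
    else:
        # taproot primaries grow straight down within their plate slot
        headings = 0.08 * rng.normal(size=n1)
        pull, curv = 0.15, 0.8 * params.curvature_noise
    for k in range(n1):
        length = rng.uniform(*params.growth_length)
        start = seed_xy + rng.uniform(-1.0, 1.0, size=2)
        pts = _grow(rng, start, float(headings[k]), length, curv, (w, h), pull=pull)
        if len(pts) < 2:
            continue
        plant.roots.append(Root(order=1, points=pts))

    llo, lhi = params.laterals_per_root
    lat_len = params.lateral_length
    if lat_len is None:
        f = params.image_size[0] / 512.0
        lat_len = (DEFAULT_LATERAL_LENGTH[0] * f, DEFAULT_LATERAL_LENGTH[1] * f)
    rw = params.root_width
    order1_dense = {
        id(r): resample_polyline(r.points, 2.0) for r in plant.roots_of_order(1)
    }
    accepted: list[np.ndarray] = []
    for parent in list(plant.roots_of_order(1)):
        n2 = int(rng.integers(llo, lhi + 1))
        placed = 0
        # each lateral is drawn with local rejection against the plant's
        # own geometry; scene-level checks remain the final arbiter
        for _try in range(100 * max(n2, 1)):
            if placed >= n2:
                break
            frac = rng.uniform(0.2, 0.8)
            attach, parent_heading = _arc_position(parent.points, float(frac))
            side = 1.0 if rng.random() < 0.5 else -1.0
            rel = rng.uniform(0.85, 1.2)
            # steep departures keep the branch point well defined; flip the
            # side rather than clipping, which would flatten the angle
            if abs(parent_heading + side * rel) > 1.25:
                side = -side
            heading = float(np.clip(parent_heading + side * rel, -1.25, 1.25))
            length = rng.uniform(*lat_len)
            pts = _grow(
                rng, attach, heading, length, params.curvature_noise, (w, h)
            )
            if len(pts) < 3 or polyline_length(pts) < lat_len[0] - 4.0:
                continue  # bound-truncated below the drawn minimum length
            dense, arc = _dense_with_arc(pts)
            ok = True
            for r1 in plant.roots_of_order(1):
                d1 = order1_dense[id(r1)]
                if r1 is parent:
                    if _min_dist(dense[arc > 2.5 * rw], d1) < rw:
                        ok = False
                    # the junction must be resolvable at the stroke width:
                    # the lateral has to leave its parent at an effective
                    # angle of >= ~30 deg throughout the branching zone, or
                    # the overlapping strokes swallow its first segment
                    zone = (arc >= rw) & (arc <= 3.0 * rw)
                    if ok and zone.any():
                        tree = cKDTree(d1)
                        dz = tree.query(dense[zone])[0]
                        if np.any(dz < 0.5 * arc[zone]):
                            ok = False
                elif _min_dist(dense, d1) < rw + 6.0:
                    ok = False
                if not ok:
                    break
            if ok and any(_min_dist(dense, a) < rw + 6.0 for a in accepted):
                ok = False
            if ok and any(
                np.linalg.norm(pts[-1] - a[-1]) < MIN_TIP_SEPARATION
                for a in accepted
            ):
                ok = False
            if not ok:
                continue
            plant.roots.append(
                Root(order=2, points=pts, parent=parent, attachment=attach.copy())
            )
            accepted.append(dense)
            placed += 1
        if placed < n2:
            return None  # could not honor the drawn lateral count; retry scene
    return plant


def _tips_ok(rs: RootSystem) -> bool:
    """True when same-class tips (and seeds) are >= MIN_TIP_SEPARATION apart."""
    groups = {
        "seed": [np.asarray(p.seed, float) for p in rs.plants],
        "tip1": [r.tip for _, r in rs.all_roots(order=1)],
        "tip2": [r.tip for _, r in rs.all_roots(order=2)],
    }
    for pts in groups.values():
        if len(pts) < 2:
            continue
        arr = np.asarray(pts)
        d = np.linalg.norm(arr[:, None, :] - arr[None, :, :], axis=-1)
        iu = np.triu_indices(len(arr), k=1)
        if np.min(d[iu]) < MIN_TIP_SEPARATION:
            return False
    return True


def _dense_with_arc(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = resample_polyline(pts, 2.0)
    seg = np.linalg.norm(np.diff(d, axis=0), axis=1)
    return d, np.concatenate([[0.0], np.cumsum(seg)])


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 or len(b) == 0:
        return np.inf
    return float(cKDTree(b).query(a)[0].min())


def _crossings_ok(rs: RootSystem, root_width: float) -> bool:
    """Reject scenes where distinct roots run close enough to merge strokes.

    Merged or crossing strokes make the shortest-path reconstruction
    ambiguous (a search may switch corridors), so the generator keeps
    centerlines of distinct roots separated: order-1 pairs by at least
    ``root_width + 6`` px (ignoring the shared region near a common seed),
    laterals from foreign order-1 roots and from each other likewise, and
    laterals from their own parent beyond the departure zone.
    """
    margin = root_width + 6.0
    o1 = []
    for pi, plant in enumerate(rs.plants):
        for r in plant.roots_of_order(1):
            d, arc = _dense_with_arc(r.points)
            o1.append((pi, r, d, arc))
    for i in range(len(o1)):
        for j in range(i + 1, len(o1)):
            pi, _, di, arci = o1[i]
            pj, _, dj, arcj = o1[j]
            if pi == pj:  # fan mates share the seed; compare beyond it
                a = di[arci > 5 * root_width]
                b = dj[arcj > 5 * root_width]
                if _min_dist(a, b) < margin * 0.8:
                    return False
            else:
                if _min_dist(di, dj) < 2 * margin:
                    return False
    o2 = []
    for plant in rs.plants:
        for lat in plant.roots_of_order(2):
            d, arc = _dense_with_arc(lat.points)
            o2.append((lat, d, arc))
    for lat, d, arc in o2:
        departed = d[arc > 2.5 * root_width]
        for _, r1, d1, _ in o1:
            if r1 is lat.parent:
                if _min_dist(departed, d1) < root_width:
                    return False
            elif _min_dist(d, d1) < margin:
                return False
    for i in range(len(o2)):
        for j in range(i + 1, len(o2)):
            if _min_dist(o2[i][1], o2[j][1]) < margin:
                return False
    return True


def generate_architecture(params: ArchitectureParams) -> RootSystem:
    """Generate a random root system satisfying the container invariants.

    Deterministic for a fixed ``params.rng_seed``.  Tip-separation and
    root-count constraints are enforced by rejection sampling: systems whose
    same-class tips fall closer than 12 px are regenerated from the next
    substream of the seeded generator.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(params.rng_seed))
    w, h = params.image_size

    for _attempt in range(500):
        rs = RootSystem()
        failed = False
        if params.style == "fibrous":
            seed_xy = np.array(
                [rng.uniform(0.35 * w, 0.65 * w), rng.uniform(0.06 * h, 0.14 * h)]
            )
            plant = _build_plant(rng, params, seed_xy)
            if plant is None:
                continue
            rs.plants.append(plant)
        else:
            # plants occupy evenly spaced horizontal slots on the plate
            slots = np.linspace(0.5 / params.n_plants, 1 - 0.5 / params.n_plants,
                                params.n_plants)
            for sx in slots:
                seed_xy = np.array(
                    [
                        (sx + rng.uniform(-0.25, 0.25) / params.n_plants) * w,
                        rng.uniform(0.06 * h, 0.14 * h),
                    ]
                )
                plant = _build_plant(rng, params, seed_xy)
                if plant is None:
                    failed = True
                    break
                rs.plants.append(plant)
            if failed:
                continue
        lo, _ = params.n_first_order
        counts_ok = all(len(p.roots_of_order(1)) >= max(lo, 1) for p in rs.plants)
        if counts_ok and _tips_ok(rs) and _crossings_ok(rs, params.root_width):
            rs.validate(seed_tolerance=max(params.root_width, 2.0))
            return rs
    raise RuntimeError(
        "could not generate a system honoring tip separation; "
        "parameters may be too dense for the image size"
    )


# ---------------------------------------------------------------------------
# rendering


def _stroke_distance(
    polylines: list[np.ndarray], shape: tuple[int, int]
) -> np.ndarray:
    """Distance from each pixel to the nearest polyline centerline.

    Polylines are rasterized at sub-pixel step length onto the grid and the
    Euclidean distance transform of the complement gives the distance field.
    """
    h, w = shape
    on = np.zeros((h, w), dtype=bool)
    clipped = False
    for pts in polylines:
        dense = resample_polyline(pts, 0.7)
        xi = np.round(dense[:, 0]).astype(int)
        yi = np.round(dense[:, 1]).astype(int)
        inb = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
        if not inb.all():
            clipped = True
        on[yi[inb], xi[inb]] = True
    if clipped:
        warnings.warn("polyline points outside image bounds were clipped")
    if not on.any():
        return np.full((h, w), np.inf)
    return ndimage.distance_transform_edt(~on)


def _background(
    rng: np.random.Generator, shape: tuple[int, int], style: str
) -> np.ndarray:
    h, w = shape
    noise = rng.normal(size=(h, w))
    texture = ndimage.gaussian_filter(noise, 3.0)
    texture /= max(np.abs(texture).max(), 1e-9)
    img = np.empty((h, w, 3), dtype=np.float64)
    if style == "fibrous":
        base = np.array([0.30, 0.42, 0.72])  # blue germination paper
        fibres = ndimage.gaussian_filter(rng.normal(size=(h, w)), (0.5, 6.0))
        fibres /= max(np.abs(fibres).max(), 1e-9)
        for c in range(3):
            img[..., c] = base[c] + 0.05 * texture + 0.03 * fibres
    else:
        base = np.array([0.10, 0.10, 0.13])  # dark plate with growth medium
        for c in range(3):
            img[..., c] = base[c] + 0.03 * texture
    return img


def render_image(rs: RootSystem, params: ArchitectureParams) -> np.ndarray:
    """Render a root system as an (H, W, 3) float image in [0, 1].

    Roots are anti-aliased strokes of ``params.root_width`` (order-2 roots
    at 60% of that width, as laterals are thinner in real assays) over a
    procedural background; deterministic for fixed inputs.
    """
    w, h = params.image_size
    rng = np.random.default_rng(np.random.SeedSequence([params.rng_seed, 0xBEE5]))
    img = _background(rng, (h, w), params.style)

    widths = {1: params.root_width, 2: 0.6 * params.root_width}
    root_color = np.array([0.93, 0.92, 0.88])
    for order in (1, 2):
        lines = [np.asarray(r.points, float) for _, r in rs.all_roots(order=order)]
        if not lines:
            continue
        dist = _stroke_distance(lines, (h, w))
        alpha = np.clip(widths[order] / 2.0 + 0.5 - dist, 0.0, 1.0)
        shade = 1.0 - 0.25 * np.clip(dist / max(widths[order] / 2.0, 1e-9), 0, 1)
        for c in range(3):
            img[..., c] = (1 - alpha) * img[..., c] + alpha * root_color[c] * shade

    img += 0.015 * rng.normal(size=img.shape)
    return np.clip(img, 0.0, 1.0)
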