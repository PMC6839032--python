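"""End-to-end inference: image -> architecture -> RSML + masks + traits.

The full pipeline resizes an input to the network's square input side
(aspect-preserving letterbox), runs the forward pass, optionally refines
the segmentation with the dense CRF, localizes seeds and tips, rebuilds
the architecture with the heuristic graph searches, smooths every root
with a cardinal spline, and emits RSML, binary masks, and a trait table —
all coordinates returned to native image resolution.

An *oracle* mode substitutes ground-truth class maps and heat maps
(rendered from a known architecture) for the network output, exercising
the whole non-learned pipeline deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .core import RootSystem, point_to_polyline_distance, project_to_polyline
from .nn.model import RootNet
from .pathfinding import reconstruct
from .postprocess import (
    DEDUP_RADIUS,
    NMS_THRESHOLD,
    CRFConfig,
    FeatureSet,
    crf_refine,
    localize_features,
)
from .rsml import write_masks, write_rsml
from .spline import DEFAULT_SPACING, DEFAULT_TENSION, fit_spline
from .targets import ClassMaps, HeatMaps, render_class_masks, render_heatmaps
from .train import gray_to_rgb
from .traits import TraitTable, compute_traits

__all__ = ["PipelineConfig", "smooth_roots", "infer_maps", "infer_image",
           "process_images", "save_overlay"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Constants of the non-learned pipeline; defaults are the published values."""

    checkpoint: str | None = None
    input_size: int = 1024  # square network input side, multiple of 128
    crf: CRFConfig = field(default_factory=CRFConfig)
    nms_threshold: float = NMS_THRESHOLD
    dedup_radius: float = DEDUP_RADIUS
    spline_spacing: float = DEFAULT_SPACING
    spline_tension: float = DEFAULT_TENSION
    mm_per_pixel: float | None = None
    mask_threshold: float = 0.5
    oracle: bool = False
    trait_resample_step: float = 1.0


def smooth_roots(
    rs: RootSystem,
    spacing: float = DEFAULT_SPACING,
    tension: float = DEFAULT_TENSION,
    trim_radius: float = 6.0,
) -> RootSystem:
    """Replace each root's polyline with its cardinal-spline resampling.

    Laterals are re-anchored after smoothing: the attachment point is
    re-projected onto the smoothed parent and becomes the lateral's first
    point, preserving the attachment invariant.  Operates in place and
    returns the system.
    """
    for plant in rs.plants:
        for root in plant.roots_of_order(1):
            try:
                curve = fit_spline(
                    _presmooth(root.points), spacing=spacing, tension=tension
                )
            except ValueError:
                continue
            root.points = curve.sample(8)
            root.spline = curve.control_points
        for lat in plant.roots_of_order(2):
            fixed = _reanchor_lateral(
                _presmooth(lat.points), lat.parent.points, trim_radius
            )
            try:
                curve = fit_spline(fixed, spacing=spacing, tension=tension)
            except ValueError:
                continue
            pts = curve.sample(8)
            attach = project_to_polyline(pts[0], lat.parent.points)
            lat.points = np.vstack([attach, pts[1:]])
            lat.attachment = attach.copy()
            lat.spline = curve.control_points
    return rs


def _presmooth(points: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average pre-filter for pixel-quantized paths.

    Graph-search paths are staircases: vertices sit on the pixel grid with
    up to ~0.7 px quantization jitter, which both inflates arc length and
    perturbs spline control points.  A short centered running mean recovers
    the sub-pixel centerline; the endpoints are preserved.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) <= window:
        return pts
    pad = window // 2
    kernel = np.ones(window) / window
    out = np.empty_like(pts)
    for d in range(2):
        col = np.pad(pts[:, d], (pad, pad), mode="edge")
        out[:, d] = np.convolve(col, kernel, mode="valid")
    out[0], out[-1] = pts[0], pts[-1]
    return out


def _reanchor_lateral(
    pts: np.ndarray, parent_pts: np.ndarray, trim_radius: float
) -> np.ndarray:
    """Correct the attachment end of a lateral's (presmoothed) pixel path.

    Where lateral and parent strokes overlap, the minimal-cost path can cut
    the junction corner, meeting the parent's path a few pixels from the
    true branching point.  Path points within ``trim_radius`` of the parent
    centerline are discarded and the lateral's local tangent — estimated
    over a fixed arc just outside the overlap — is extrapolated back onto
    the parent polyline; if the ray misses, or the correction would exceed
    the overlap scale, the original endpoint is simply snapped instead.
    """
    parent_pts = np.asarray(parent_pts, dtype=float)
    snap = project_to_polyline(pts[0], parent_pts)
    keep = np.vstack([snap, pts[1:]])
    dists = [point_to_polyline_distance(p, parent_pts) for p in pts]
    k = next((i for i, d in enumerate(dists) if d > trim_radius), None)
    if k is None or k == 0 or k >= len(pts) - 2:
        return keep
    ref, arc = k, 0.0
    while ref + 1 < len(pts) and arc < 8.0:
        arc += float(np.linalg.norm(pts[ref + 1] - pts[ref]))
        ref += 1
    v = pts[k] - pts[ref]
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        return keep
    attach = _ray_polyline_intersection(
        pts[k], v / norm, parent_pts, max_t=2.2 * trim_radius
    )
    if attach is None or np.linalg.norm(attach - snap) > 2.0 * trim_radius:
        return keep
    return np.vstack([attach, pts[k:]])


def _ray_polyline_intersection(
    origin: np.ndarray, direction: np.ndarray, polyline: np.ndarray, max_t: float
) -> np.ndarray | None:
    """First intersection of origin + t*direction (0 <= t <= max_t) with a
    polyline, or None if the ray misses every segment."""
    best_t, best_point = None, None
    for a, b in zip(polyline[:-1], polyline[1:]):
        e = b - a
        denom = direction[0] * (-e[1]) - direction[1] * (-e[0])
        if abs(denom) < 1e-12:
            continue  # parallel
        rhs = a - origin
        t = (rhs[0] * (-e[1]) - rhs[1] * (-e[0])) / denom
        s = (direction[0] * rhs[1] - direction[1] * rhs[0]) / denom
        if 0.0 <= t <= max_t and -1e-9 <= s <= 1.0 + 1e-9:
            if best_t is None or t < best_t:
                best_t, best_point = t, origin + t * direction
    return best_point


def _letterbox(image: np.ndarray, size: int) -> tuple[np.ndarray, float]:
    """Aspect-preserving resize + pad (top-left anchored) to a square.

    Returns the (size, size, 3) image and the scale factor mapping native
    coordinates into the letterboxed frame.
    """
    h, w = image.shape[:2]
    scale = size / max(h, w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    resized = resize(image, (nh, nw), order=1, anti_aliasing=scale < 1.0)
    out = np.empty((size, size, 3), dtype=np.float64)
    out[...] = resized.reshape(nh * nw, -1).mean(axis=0)
    out[:nh, :nw] = resized
    return out, scale


def infer_maps(
    class_probs: ClassMaps,
    heats: HeatMaps,
    config: PipelineConfig,
    scale: float = 1.0,
) -> tuple[RootSystem, FeatureSet]:
    """Post-processing core: maps -> features -> architecture -> splines.

    ``scale`` converts map coordinates to native pixels (2 x resize factor
    for network output, 2 for half-resolution oracle maps).
    """
    features = localize_features(
        heats, threshold=config.nms_threshold, radius=config.dedup_radius
    )
    rs = reconstruct(
        class_probs, features, scale=scale, mask_threshold=config.mask_threshold
    )
    smooth_roots(
        rs,
        spacing=config.spline_spacing * scale,
        tension=config.spline_tension,
    )
    return rs, features


def infer_image(
    image: np.ndarray,
    model: RootNet | None,
    config: PipelineConfig,
    oracle_system: RootSystem | None = None,
) -> tuple[RootSystem, ClassMaps, FeatureSet, TraitTable]:
    """Analyse one image; returns (architecture, class maps, features, traits).

    ``image`` is (H, W, 3) or (H, W) in [0, 1]; grayscale inputs are
    expanded by channel duplication.  In oracle mode ``oracle_system``
    provides the ground-truth architecture whose rendered maps replace the
    network output.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = gray_to_rgb(img).transpose(1, 2, 0)
    h, w = img.shape[:2]

    if config.oracle:
        if oracle_system is None:
            raise ValueError("oracle mode requires the ground-truth architecture")
        half = (h // 2, w // 2)
        class_maps = render_class_masks(oracle_system, half, stroke_width=4.0, scale=0.5)
        heats = render_heatmaps(oracle_system, half, sigma=1.0, scale=0.5)
        rs, features = infer_maps(class_maps, heats, config, scale=2.0)
    else:
        if model is None:
            raise ValueError("network mode requires a model")
        boxed, box_scale = _letterbox(img, config.input_size)
        x = boxed.transpose(2, 0, 1)[None].astype(np.float32)
        seg, heat = model.predict(x)
        class_maps = ClassMaps(background=seg[0, 0], order1=seg[0, 1], order2=seg[0, 2])
        guide = resize(boxed, (config.input_size // 2, config.input_size // 2), order=1)
        class_maps = crf_refine(class_maps, guide, config.crf)
        heats = HeatMaps(seed=heat[0, 0], tip1=heat[0, 1], tip2=heat[0, 2])
        rs, features = infer_maps(class_maps, heats, config, scale=2.0 / box_scale)

    traits = compute_traits(
        rs, resample_step=config.trait_resample_step, mm_per_pixel=config.mm_per_pixel
    )
    return rs, class_maps, features, traits


def process_images(
    paths: list[Path],
    model: RootNet | None,
    config: PipelineConfig,
    out_dir: Path,
    oracle_systems: dict[str, RootSystem] | None = None,
) -> int:
    """Batch-process images unattended; returns the number of failures.

    Per image: RSML (`<stem>.rsml`), binary masks (`<stem>_mask{1,2}.png`),
    and one trait CSV row appended to ``traits.csv``.  Unreadable images
    are skipped with a logged error and counted in the exit summary.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    failures = 0
    trait_rows = []
    for path in paths:
        stem = Path(path).stem
        try:
            img = np.asarray(Image.open(path), dtype=np.float64) / 255.0
            oracle_rs = (oracle_systems or {}).get(stem)
            rs, class_maps, _, traits = infer_image(
                img, model, config, oracle_system=oracle_rs
            )
        except Exception:
            logger.exception("failed to process %s", path)
            failures += 1
            continue
        h, w = img.shape[:2]
        write_rsml(rs, {"label": stem, "size": (w, h)}, out_dir / f"{stem}.rsml")
        native = render_class_masks(rs, (h, w), stroke_width=8.0, scale=1.0)
        write_masks(
            native,
            {
                "order1": out_dir / f"{stem}_mask1.png",
                "order2": out_dir / f"{stem}_mask2.png",
            },
        )
        traits.image_id = stem
        trait_rows.append(traits)
    if trait_rows:
        lines = [trait_rows[0].to_csv().splitlines()[0]]
        for t in trait_rows:
            lines.extend(t.to_csv().splitlines()[1:])
        (out_dir / "traits.csv").write_text("\n".join(lines) + "\n")
    return failures

def save_overlay(image: np.ndarray, rs: RootSystem, path) -> None:
    """Debug aid: draw extracted root paths over the input image as a PNG.

    Order-1 roots in yellow, order-2 in cyan, seeds as red squares.
    """
    from PIL import Image

    from .core import resample_polyline

    img = np.asarray(image, dtype=np.float64).copy()
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    h, w = img.shape[:2]
    colors = {1: (1.0, 0.9, 0.1), 2: (0.1, 0.9, 0.9)}
    for _, root in rs.all_roots():
        dense = resample_polyline(np.asarray(root.points, float), 0.7)
        xi = np.clip(np.round(dense[:, 0]).astype(int), 0, w - 1)
        yi = np.clip(np.round(dense[:, 1]).astype(int), 0, h - 1)
        img[yi, xi] = colors[root.order]
    for plant in rs.plants:
        x, y = np.round(np.asarray(plant.seed, float)).astype(int)
        img[max(y - 2, 0) : y + 3, max(x - 2, 0) : x + 3] = (1.0, 0.2, 0.2)
    Image.fromarray((np.clip(img, 0, 1) * 255).astype(np.uint8)).save(str(path))
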