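"""Training-target rendering: per-class segmentation masks and feature heat maps.

A root system is converted into the two kinds of dense targets the network
learns: binary class masks (background / first-order / second-order), with
every root drawn as a hard 8-px-wide polyline stroke, and [0, 1] heat maps
in which each seed and root tip is a unit-amplitude Gaussian of standard
deviation 1 px.

Targets are rendered directly at the network's output resolution, which is
half the input side length; callers pass the target ``shape`` and a
coordinate ``scale`` mapping native coordinates onto it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import RootSystem, resample_polyline

__all__ = ["ClassMaps", "HeatMaps", "render_class_masks", "render_heatmaps"]

#: stroke width used for ground-truth masks, px
DEFAULT_STROKE_WIDTH = 8.0
#: Gaussian standard deviation for feature heat maps, px
DEFAULT_SIGMA = 1.0


@dataclass
class ClassMaps:
    """Per-class pixel maps: background, order-1 roots, order-2 roots.

    Ground truth is binary; network predictions are probabilistic.  Where
    order-1 and order-2 strokes cross, the pixel is set in *both* root
    channels (each class mask is used independently downstream) and the
    background channel is 0.
    """

    background: np.ndarray
    order1: np.ndarray
    order2: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.background.shape

    def stack(self) -> np.ndarray:
        return np.stack([self.background, self.order1, self.order2])

    def validate(self, binary: bool = False) -> None:
        if not (self.background.shape == self.order1.shape == self.order2.shape):
            raise ValueError("class map channels must share a shape")
        for ch in (self.background, self.order1, self.order2):
            if ch.min() < 0 or ch.max() > 1:
                raise ValueError("class map values must lie in [0, 1]")
            if binary and not np.isin(ch, (0.0, 1.0)).all():
                raise ValueError("ground-truth class maps must be binary")


@dataclass
class HeatMaps:
    """Feature-likelihood maps: seed, order-1 tips, order-2 tips; values in [0, 1]."""

    seed: np.ndarray
    tip1: np.ndarray
    tip2: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.seed.shape

    def stack(self) -> np.ndarray:
        return np.stack([self.seed, self.tip1, self.tip2])

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)


def _stroke_mask(
    polylines: list[np.ndarray], shape: tuple[int, int], width: float
) -> np.ndarray:
    """Hard binary stroke of the given width around each polyline.

    Rasterizes the centerlines at sub-pixel spacing, then thresholds the
    Euclidean distance transform at width/2 — giving consistent stroke
    thickness and round caps without anti-aliasing.
    """
    h, w = shape
    if not polylines:
        return np.zeros((h, w), dtype=np.float64)
    on = np.zeros((h, w), dtype=bool)
    for pts in polylines:
        dense = resample_polyline(np.asarray(pts, float), 0.7)
        xi = np.round(dense[:, 0]).astype(int)
        yi = np.round(dense[:, 1]).astype(int)
        inb = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
        on[yi[inb], xi[inb]] = True
    if not on.any():
        return np.zeros((h, w), dtype=np.float64)
    dist = ndimage.distance_transform_edt(~on)
    # the rasterized centerline is itself one pixel wide, so thresholding
    # at (w-1)/2 yields a stroke spanning ~w pixels across
    return (dist <= (width - 1.0) / 2.0).astype(np.float64)


def render_class_masks(
    rs: RootSystem,
    shape: tuple[int, int],
    stroke_width: float = DEFAULT_STROKE_WIDTH,
    scale: float = 1.0,
) -> ClassMaps:
    """Render binary class masks at the given (H, W) shape.

    ``scale`` multiplies every root coordinate before rasterization (0.5
    when rendering native ground truth at the half-resolution network
    output).  The stroke width is applied in *target* pixels.
    """
    lines1 = [np.asarray(r.points, float) * scale for _, r in rs.all_roots(order=1)]
    lines2 = [np.asarray(r.points, float) * scale for _, r in rs.all_roots(order=2)]
    order1 = _stroke_mask(lines1, shape, stroke_width)
    order2 = _stroke_mask(lines2, shape, stroke_width)
    background = 1.0 - np.maximum(order1, order2)
    return ClassMaps(background=background, order1=order1, order2=order2)


def _gaussian_splat(
    points: list[np.ndarray], shape: tuple[int, int], sigma: float
) -> np.ndarray:
    """Superpose unit-peak Gaussians at the given points, clamped at 1."""
    h, w = shape
    out = np.zeros((h, w), dtype=np.float64)
    r = int(np.ceil(4 * sigma))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    for p in points:
        x, y = float(p[0]), float(p[1])
        cx, cy = int(round(x)), int(round(y))
        if not (0 <= cx < w and 0 <= cy < h):
            continue
        g = np.exp(-(((xx + cx - x) ** 2) + ((yy + cy - y) ** 2)) / (2 * sigma**2))
        y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
        x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
        out[y0:y1, x0:x1] += g[
            y0 - (cy - r) : g.shape[0] - ((cy + r + 1) - y1),
            x0 - (cx - r) : g.shape[1] - ((cx + r + 1) - x1),
        ]
    return np.clip(out, 0.0, 1.0)


def render_heatmaps(
    rs: RootSystem,
    shape: tuple[int, int],
    sigma: float = DEFAULT_SIGMA,
    scale: float = 1.0,
) -> HeatMaps:
    """Render feature heat maps: one Gaussian per seed / order-1 tip / order-2 tip.

    Each feature contributes a unit-amplitude Gaussian of standard deviation
    ``sigma`` (in target pixels); overlapping Gaussians are clamped at 1.
    The tip of a root is the last point of its polyline.
    """
    seeds = [np.asarray(p.seed, float) * scale for p in rs.plants]
    tips1 = [r.tip * scale for _, r in rs.all_roots(order=1)]
    tips2 = [r.tip * scale for _, r in rs.all_roots(order=2)]
    return HeatMaps(
        seed=_gaussian_splat(seeds, shape, sigma),
        tip1=_gaussian_splat(tips1, shape, sigma),
        tip2=_gaussian_splat(tips2, shape, sigma),
    )
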