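"""Segmentation refinement and discrete feature localization.

Two stages sit between the network and the path search:

* a fully connected CRF with Gaussian pairwise potentials (mean-field
  inference) that smooths the 3-class segmentation — switchable off;
* heat-map peak extraction: thresholded 3x3 scanline non-maximal
  suppression followed by greedy radius deduplication through a spatial
  grid index, yielding one discrete point per seed / root tip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .targets import ClassMaps, HeatMaps

__all__ = [
    "CRFConfig",
    "crf_refine",
    "nms_peaks",
    "dedup_points",
    "FeatureSet",
    "localize_features",
    "NMS_THRESHOLD",
    "DEDUP_RADIUS",
]

#: detection threshold applied before non-maximal suppression
NMS_THRESHOLD = 0.7
#: a feature within this radius of an already-kept feature is a duplicate
DEDUP_RADIUS = 8.0


# ---------------------------------------------------------------------------
# dense CRF


@dataclass
class CRFConfig:
    """Mean-field dense-CRF parameters.

    The appearance kernel couples pixels that are close *and* similar in
    intensity (spatial std ``sxy_app``, intensity std ``s_int`` on a 0-255
    scale); the smoothness kernel couples nearby pixels regardless of
    appearance.  Defaults follow common practice for this family of models;
    the stage's effect is deliberately subtle.
    """

    enabled: bool = True
    iterations: int = 5
    sxy_app: float = 30.0
    s_int: float = 13.0
    w_app: float = 5.0
    sxy_smooth: float = 3.0
    w_smooth: float = 3.0
    intensity_bins: int = 16


def _bilateral_blur(q: np.ndarray, guide: np.ndarray, cfg: CRFConfig) -> np.ndarray:
    """Approximate bilateral filtering of ``q`` guided by image intensity.

    Splats values into a downsampled (y, x, intensity) bilateral grid,
    blurs the grid with a Gaussian, and slices back at each pixel's
    position — the standard grid approximation of the appearance kernel.
    """
    h, w = q.shape
    ss = max(int(round(cfg.sxy_app / 2.0)), 1)
    nb = cfg.intensity_bins
    sb = max(cfg.s_int / (256.0 / nb), 0.5)

    gy = (np.arange(h) / ss).astype(int)
    gx = (np.arange(w) / ss).astype(int)
    gi = np.clip((guide * (nb - 1)).astype(int), 0, nb - 1)
    gh, gw = gy[-1] + 1, gx[-1] + 1

    flat_idx = (gy[:, None] * gw + gx[None, :]) * nb + gi
    grid = np.bincount(flat_idx.ravel(), weights=q.ravel(), minlength=gh * gw * nb)
    norm = np.bincount(flat_idx.ravel(), minlength=gh * gw * nb)
    grid = grid.reshape(gh, gw, nb)
    norm = norm.reshape(gh, gw, nb)

    sigma = (cfg.sxy_app / ss, cfg.sxy_app / ss, sb)
    grid = ndimage.gaussian_filter(grid, sigma, mode="constant")
    norm = ndimage.gaussian_filter(norm, sigma, mode="constant")

    out = grid[gy[:, None], gx[None, :], gi] / np.maximum(
        norm[gy[:, None], gx[None, :], gi], 1e-9
    )
    return out


def crf_refine(
    seg_probs: ClassMaps, image: np.ndarray, config: CRFConfig | None = None
) -> ClassMaps:
    """Mean-field inference on a fully connected CRF over the 3 classes.

    ``seg_probs`` must be normalized across classes per pixel; ``image`` is
    the (H, W[, 3]) input at the same resolution in [0, 1].  When the stage
    is disabled the input is returned unchanged (identity).
    """
    cfg = config or CRFConfig()
    if not cfg.enabled:
        return seg_probs
    probs = seg_probs.stack().astype(np.float64)
    k, h, w = probs.shape
    img = np.asarray(image, dtype=np.float64)
    guide = img.mean(axis=-1) if img.ndim == 3 else img
    guide = np.clip(guide, 0.0, 1.0)

    unary = -np.log(np.clip(probs, 1e-8, 1.0))
    q = probs.copy()
    for _ in range(cfg.iterations):
        msg = np.empty_like(q)
        for c in range(k):
            smooth = ndimage.gaussian_filter(q[c], cfg.sxy_smooth) - q[c]
            app = _bilateral_blur(q[c], guide, cfg) - q[c]
            msg[c] = cfg.w_smooth * smooth + cfg.w_app * app
        # Potts compatibility: each class is penalized by the mass of the
        # *other* classes' filtered beliefs
        total = msg.sum(axis=0, keepdims=True)
        energy = unary + (total - msg)
        energy -= energy.min(axis=0, keepdims=True)
        q = np.exp(-energy)
        q /= q.sum(axis=0, keepdims=True)
    return ClassMaps(background=q[0], order1=q[1], order2=q[2])


# ---------------------------------------------------------------------------
# peak extraction


def nms_peaks(channel: np.ndarray, threshold: float = NMS_THRESHOLD) -> list[tuple]:
    """Thresholded 3x3 scanline non-maximal suppression.

    A pixel is returned iff its value is >= ``threshold``, no 3x3 neighbour
    has a strictly greater value, and no *earlier-scanned* (row-major)
    neighbour has an equal value — so of a tied pair the earlier pixel
    wins, deterministically.  Returns ``(x, y, score)`` tuples in scan
    order.
    """
    v = np.asarray(channel, dtype=np.float64)
    h, w = v.shape
    cand = np.argwhere(v >= threshold)  # row-major order
    out = []
    for y, x in cand:
        val = v[y, x]
        keep = True
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == 0 and dx == 0:
                    continue
                ny, nx = y + dy, x + dx
                if not (0 <= ny < h and 0 <= nx < w):
                    continue
                nv = v[ny, nx]
                if nv > val:
                    keep = False
                elif nv == val and (ny < y or (ny == y and nx < x)):
                    keep = False  # earlier-scanned equal neighbour wins
            if not keep:
                break
        if keep:
            out.append((int(x), int(y), float(val)))
    return out


class _GridIndex:
    """Uniform-grid spatial index supporting greedy radius queries."""

    def __init__(self, radius: float):
        self.radius = float(radius)
        self.cell = max(self.radius, 1e-9)
        self.buckets: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return (int(np.floor(x / self.cell)), int(np.floor(y / self.cell)))

    def has_within(self, x: float, y: float) -> bool:
        kx, ky = self._key(x, y)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for px, py in self.buckets.get((kx + dx, ky + dy), ()):
                    if (px - x) ** 2 + (py - y) ** 2 <= self.radius**2:
                        return True
        return False

    def insert(self, x: float, y: float) -> None:
        self.buckets.setdefault(self._key(x, y), []).append((x, y))


def dedup_points(points: list[tuple], radius: float = DEDUP_RADIUS) -> list[tuple]:
    """Greedy deduplication: keep a point unless one already kept lies within ``radius``.

    Points are processed in the given (scan) order; ties therefore resolve
    to the earlier point.
    """
    index = _GridIndex(radius)
    kept = []
    for p in points:
        x, y = float(p[0]), float(p[1])
        if index.has_within(x, y):
            continue
        index.insert(x, y)
        kept.append(p)
    return kept


@dataclass
class FeatureSet:
    """Discrete localized features, in output-resolution pixel coordinates."""

    seeds: list[tuple] = field(default_factory=list)
    tips1: list[tuple] = field(default_factory=list)
    tips2: list[tuple] = field(default_factory=list)

    def to_csv_rows(self):
        for name in ("seeds", "tips1", "tips2"):
            for x, y, s in getattr(self, name):
                yield (name, x, y, s)

    def to_csv(self, path=None) -> str:
        """Debug export: one (class, x, y, score) row per feature."""
        lines = ["class,x,y,score"]
        lines += [f"{c},{x},{y},{s:.6f}" for c, x, y, s in self.to_csv_rows()]
        text = "\n".join(lines) + "\n"
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text


def localize_features(
    heats: HeatMaps,
    threshold: float = NMS_THRESHOLD,
    radius: float = DEDUP_RADIUS,
) -> FeatureSet:
    """NMS + dedup per heat-map channel.

    An empty seed list is legal (the downstream reconstruction then emits
    an empty architecture with a warning).
    """
    fs = FeatureSet(
        seeds=dedup_points(nms_peaks(heats.seed, threshold), radius),
        tips1=dedup_points(nms_peaks(heats.tip1, threshold), radius),
        tips2=dedup_points(nms_peaks(heats.tip2, threshold), radius),
    )
    return fs
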