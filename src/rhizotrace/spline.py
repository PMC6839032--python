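"""Cardinal-spline smoothing of extracted root paths.

Pixel-accurate paths recovered by the graph search are staircase-like.
Each path is smoothed by sampling control points at equal arc-length
spacing and interpolating them with a cubic cardinal spline.  Cardinal
splines are the standard interpolating family with a tension parameter;
the tension is fixed at 0.5 by default.  Tangent convention: at interior
control point i the tangent is (1 - tension) * (P[i+1] - P[i-1]) / 2, with
one-sided differences at the endpoints, so the spline passes through every
control point exactly and reproduces straight lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import polyline_length, resample_polyline

__all__ = ["SplineCurve", "fit_spline"]

DEFAULT_TENSION = 0.5
DEFAULT_SPACING = 20.0  # px between control points, at output resolution


@dataclass
class SplineCurve:
    control_points: np.ndarray  # (K, 2), K >= 2
    tension: float = DEFAULT_TENSION
    spacing: float = DEFAULT_SPACING
    _tangents: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        cp = np.asarray(self.control_points, dtype=float)
        if cp.ndim != 2 or cp.shape[1] != 2 or len(cp) < 2:
            raise ValueError("spline needs >= 2 control points")
        self.control_points = cp
        t = self.tension
        m = np.empty_like(cp)
        m[1:-1] = (1.0 - t) * (cp[2:] - cp[:-2]) / 2.0
        m[0] = (1.0 - t) * (cp[1] - cp[0])
        m[-1] = (1.0 - t) * (cp[-1] - cp[-2])
        self._tangents = m

    def evaluate(self, u: np.ndarray) -> np.ndarray:
        """Evaluate at global parameters ``u`` in [0, K-1] (integers hit control points)."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        k = len(self.control_points)
        i = np.clip(np.floor(u).astype(int), 0, k - 2)
        s = (u - i)[:, None]
        p0 = self.control_points[i]
        p1 = self.control_points[i + 1]
        m0 = self._tangents[i]
        m1 = self._tangents[i + 1]
        h00 = 2 * s**3 - 3 * s**2 + 1
        h10 = s**3 - 2 * s**2 + s
        h01 = -2 * s**3 + 3 * s**2
        h11 = s**3 - s**2
        return h00 * p0 + h10 * m0 + h01 * p1 + h11 * m1

    def sample(self, points_per_segment: int = 10) -> np.ndarray:
        """Densely sample the whole curve as a polyline (endpoints included)."""
        k = len(self.control_points)
        u = np.linspace(0.0, k - 1, (k - 1) * points_per_segment + 1)
        return self.evaluate(u)

    @property
    def length(self) -> float:
        return polyline_length(self.sample(20))


def fit_spline(
    path: np.ndarray,
    spacing: float = DEFAULT_SPACING,
    tension: float = DEFAULT_TENSION,
) -> SplineCurve:
    """Fit a cardinal spline through control points sampled along ``path``.

    Control points are taken at equal arc-length spacing (both endpoints
    always included).  Degenerate single-point paths are rejected.
    """
    pts = np.asarray(path, dtype=float)
    if pts.ndim != 2 or len(pts) < 2 or polyline_length(pts) <= 0:
        raise ValueError("cannot fit a spline to a degenerate path")
    # every root gets at least 8 control segments so smoothing cannot
    # collapse short roots toward a chord
    eff = min(spacing, polyline_length(pts) / 8.0)
    control = resample_polyline(pts, max(eff, 1e-6))
    return SplineCurve(control_points=control, tension=tension, spacing=spacing)
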