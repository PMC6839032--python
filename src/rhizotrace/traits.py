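"""Phenotypic trait quantification from extracted root architectures.

The measurement layer: given a :class:`RootSystem`, compute per-plant
summary traits commonly used in root phenotyping:

* ``max_depth`` — vertical distance from the seed to the lowest
  first-order root tip (depth grows with image y).
* ``max_width`` — horizontal extent over all root points (all orders).
* ``convex_hull_area`` — area of the convex hull of all root points.
* ``centroid_depth`` — mean y of uniformly resampled points over all
  roots, minus the seed y, so long roots weigh proportionally to length.
* per-order root counts and total arc lengths.

All values default to pixels at native resolution; an optional
mm-per-pixel scale converts lengths and areas.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .core import RootSystem, polyline_length, resample_polyline

__all__ = ["PlantTraits", "TraitTable", "compute_traits"]

DEFAULT_RESAMPLE_STEP = 1.0  # px


@dataclass
class PlantTraits:
    plant_index: int
    max_depth: float
    max_width: float
    convex_hull_area: float
    centroid_depth: float
    n_roots_order1: int
    n_roots_order2: int
    total_length_order1: float
    total_length_order2: float
    empty: bool = False  # plant had no roots; all-zero row


@dataclass
class TraitTable:
    rows: list[PlantTraits] = field(default_factory=list)
    mm_per_pixel: float | None = None
    image_id: str = ""

    COLUMNS = [f.name for f in fields(PlantTraits)]

    def to_csv(self, path: str | Path | None = None) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["image_id"] + self.COLUMNS)
        for row in self.rows:
            writer.writerow(
                [self.image_id] + [getattr(row, c) for c in self.COLUMNS]
            )
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text


def _hull_area(points: np.ndarray) -> float:
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is the area
    except QhullError:  # all points collinear
        return 0.0


def compute_traits(
    rs: RootSystem,
    resample_step: float = DEFAULT_RESAMPLE_STEP,
    mm_per_pixel: float | None = None,
    image_id: str = "",
) -> TraitTable:
    """Compute the per-plant trait table.

    Roots are resampled at ``resample_step`` px before point-based traits
    (width, hull, centroid) are measured; arc lengths are measured on the
    original polylines.  Plants without roots yield flagged all-zero rows.
    """
    s = mm_per_pixel if mm_per_pixel else 1.0
    table = TraitTable(mm_per_pixel=mm_per_pixel, image_id=image_id)
    for pi, plant in enumerate(rs.plants, start=1):
        if not plant.roots:
            table.rows.append(
                PlantTraits(pi, 0, 0, 0, 0, 0, 0, 0.0, 0.0, empty=True)
            )
            continue
        seed = np.asarray(plant.seed, dtype=float)
        order1 = plant.roots_of_order(1)
        order2 = plant.roots_of_order(2)
        sampled = [
            resample_polyline(np.asarray(r.points, float), resample_step)
            for r in plant.roots
        ]
        all_pts = np.concatenate(sampled, axis=0)
        tips1_y = [r.tip[1] for r in order1]
        max_depth = (max(tips1_y) - seed[1]) if tips1_y else 0.0
        table.rows.append(
            PlantTraits(
                plant_index=pi,
                max_depth=max_depth * s,
                max_width=float(all_pts[:, 0].max() - all_pts[:, 0].min()) * s,
                convex_hull_area=_hull_area(all_pts) * s * s,
                centroid_depth=float(all_pts[:, 1].mean() - seed[1]) * s,
                n_roots_order1=len(order1),
                n_roots_order2=len(order2),
                total_length_order1=sum(polyline_length(r.points) for r in order1) * s,
                total_length_order2=sum(polyline_length(r.points) for r in order2) * s,
            )
        )
    return table
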