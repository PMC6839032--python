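"""Independent brute-force geometry oracle used by trait tests.

Deliberately naive: exhaustive gift-wrapping hull, direct segment sums —
sharing no code with the implementation under test.
"""

import numpy as np

from rhizotrace.core import resample_polyline


def brute_force_traits(plant, resample_step=1.0):
    """Independent geometry oracle: exhaustive hull + segment sums."""
    seed = np.asarray(plant.seed, float)
    pts = np.concatenate(
        [resample_polyline(np.asarray(r.points, float), resample_step)
         for r in plant.roots]
    )

    def hull_area(points):
        points = np.unique(points, axis=0)
        if len(points) < 3:
            return 0.0
        # gift wrapping via exhaustive cross-product checks
        hull = []
        start = min(range(len(points)), key=lambda i: (points[i][0], points[i][1]))
        current = start
        while True:
            hull.append(current)
            cand = (current + 1) % len(points)
            for j in range(len(points)):
                if j == current:
                    continue
                u = points[cand] - points[current]
                v = points[j] - points[current]
                cross = u[0] * v[1] - u[1] * v[0]
                if cross < -1e-12 or (
                    abs(cross) < 1e-12
                    and np.linalg.norm(points[j] - points[current])
                    > np.linalg.norm(points[cand] - points[current])
                ):
                    cand = j
            current = cand
            if current == start:
                break
        poly = points[hull]
        x, y = poly[:, 0], poly[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))

    def seg_sum(roots):
        return sum(
            float(np.sum(np.linalg.norm(np.diff(np.asarray(r.points, float), axis=0), axis=1)))
            for r in roots
        )

    order1 = plant.roots_of_order(1)
    tips1_y = [np.asarray(r.points, float)[-1, 1] for r in order1]
    return dict(
        max_depth=max(tips1_y) - seed[1],
        max_width=pts[:, 0].max() - pts[:, 0].min(),
        convex_hull_area=hull_area(pts),
        centroid_depth=pts[:, 1].mean() - seed[1],
        total_length_order1=seg_sum(order1),
        total_length_order2=seg_sum(plant.roots_of_order(2)),
    )
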