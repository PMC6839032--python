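"""Generate a synthetic root scene and render it with its training targets.

Builds a single wheat-like plant (fibrous: several first-order roots from
one seed, plus laterals), renders the photograph-like image, and the
binary class masks / Gaussian tip heat maps the network would train on.
"""

import numpy as np

from rhizotrace import generate_architecture, render_image
from rhizotrace.synthetic import fibrous_params
from rhizotrace.targets import render_class_masks, render_heatmaps

params = fibrous_params(n_first_order=(4, 4), laterals_per_root=(1, 2), rng_seed=42)
rs = generate_architecture(params)
img = render_image(rs, params)

w, h = params.image_size
masks = render_class_masks(rs, (h // 2, w // 2), stroke_width=4.0, scale=0.5)
heats = render_heatmaps(rs, (h // 2, w // 2), sigma=1.0, scale=0.5)

print(f"plants: {rs.n_plants}")
print(f"first-order roots: {rs.count_roots(1)}   laterals: {rs.count_roots(2)}")
print(f"image: {img.shape}, values in [{img.min():.2f}, {img.max():.2f}]")
print(f"order-1 mask pixels: {int(masks.order1.sum())} "
      f"({100 * masks.order1.mean():.1f}% of the half-resolution frame)")
print(f"heat-map peaks (seed/tip1/tip2): "
      f"{heats.seed.max():.1f}/{heats.tip1.max():.1f}/{heats.tip2.max():.1f}")
# The mask fraction shows how heavily background dominates -- the reason the
# training loss uses median-frequency class balancing; unit heat-map peaks
# are what the 0.7 detection threshold is calibrated against.
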