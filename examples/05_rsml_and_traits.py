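"""Write a root system to RSML, read it back, and quantify traits.

RSML is the community XML standard for root architectures: scene ->
plant -> nested root elements with polyline geometry.  The writer also
stores each root's smoothed spline as an annotation.
"""

import tempfile
from pathlib import Path

from rhizotrace import compute_traits, generate_architecture, read_rsml, write_rsml
from rhizotrace.synthetic import fibrous_params

params = fibrous_params(n_first_order=(4, 5), laterals_per_root=(1, 2), rng_seed=3)
rs = generate_architecture(params)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "plant.rsml"
    write_rsml(rs, {"label": "example", "size": params.image_size}, path)
    print(f"wrote {path.stat().st_size} bytes of RSML")
    back = read_rsml(path)

print(f"round trip: {back.n_plants} plant, "
      f"{back.count_roots(1)} first-order, {back.count_roots(2)} lateral roots")

table = compute_traits(back, image_id="example")
print(table.to_csv(), end="")
# max_depth is seed-to-deepest-tip, max_width the horizontal extent,
# convex_hull_area the hull of all root points (px^2); lengths are summed
# per order.  Pass mm_per_pixel to convert to physical units.
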