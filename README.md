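# rhizotrace

Automatic extraction of plant **root system architectures** from 2-D
seedling images — for root phenotyping at the scale genetic studies need,
where semi-automatic annotation (minutes of expert time per image) is the
bottleneck.

A single multi-task convolutional network segments root material into
*background / first-order / second-order* classes and simultaneously
regresses heat maps whose Gaussian peaks mark **seeds and root tips**.
Discrete features drive a heuristic search that reconstructs every root:
each class mask becomes an 8-connected pixel lattice where stepping onto a
pixel costs between 0.1 (root edge) and 0.01 (root centerline), or 10.0
off-class, so minimal-cost paths `f(p) = g(p) + h(p)` traced from tips to
seeds (A*, or Dijkstra with multiple seeds) follow root centerlines.
Lateral roots are traced to their parent the same way.  Paths are smoothed
with cardinal splines (tension 0.5) and exported as
[RSML](http://rootsystemml.github.io/), alongside binary masks and a
per-plant trait table (max depth/width, convex hull area, centroid depth,
counts, lengths).

The training objective is a class-balanced sum `L = L1 + L2`: binary
cross-entropy over the class maps with **median-frequency balancing**
(`α_c = median_freq / freq(c)`, countering background dominance) plus
squared error over the heat maps.

Everything — including the network, which runs on a compact numpy
autodiff engine — is exercisable on one CPU via a procedural generator of
synthetic root scenes (wheat-like fibrous plants on blue germination
paper; multi-plant taproot plate assays).  See `docs/methods.md` for the
model details and exactly what the synthetic scenes do and do not emulate.

## Worked example

```bash
python examples/02_oracle_pipeline.py
```

builds a 4-plant synthetic plate scene, feeds its ground-truth maps
through the whole non-learned pipeline (feature localization → path
search → splines → traits) and prints:

```
true:      4 plants, 4 primaries, 13 laterals
recovered: 4 plants, 4 primaries, 13 laterals
per-root arc-length error: mean 0.7%, max 2.1%

per-plant traits (px):
image_id,plant_index,max_depth,max_width,convex_hull_area,centroid_depth,...
,1,290.0,162.0,27763.99...,146.37...,1,4,291.14...,381.16...
```

— plant and per-order root counts are recovered exactly, each root's arc
length to within a few percent, and the trait rows are the CSV the tool
emits per image.  The other `examples/` scripts cover scene generation,
the network and losses, desk-scale training, and RSML round trips.

There is also a thin CLI for batch work:

```bash
rhizotrace synth --out ds -n 5 --style taproot --plants 3 --seed 1
rhizotrace infer ds/images --out results --oracle-rsml ds/rsml
rhizotrace traits results/*.rsml
```

(`infer` takes `--checkpoint model.npz` to use a trained network instead
of oracle maps; `train` / `transfer` produce checkpoints.)

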