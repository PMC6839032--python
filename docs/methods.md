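# Methods

`rhizotrace` extracts full root system architectures (RSA) from 2-D
seedling images: a multi-task convolutional network segments root material
by order and localizes seeds and root tips; heuristic shortest-path
searches on class-aware weighted pixel lattices reconstruct each root;
splines smooth the paths; and the result is exported as RSML and
quantified as per-plant traits.  Everything is testable at desk scale
through a procedural generator of synthetic root scenes.

## The network

An extended encoder–decoder with a single hourglass core, operating on
`(3, S, S)` inputs and emitting two `(3, S/2, S/2)` heads.  `S` must be a
multiple of 128 (the hourglass pools four times below the 1/8-resolution
trunk); the published operating point is `S = 1024`.

| stage | operation | output channels (width 1) |
|---|---|---|
| stem | 7×7 conv, stride 2, BN, ReLU | 64 |
| encoder | residual block → maxpool → residual block → maxpool → residual block | 128 → 256 → 256 |
| core | hourglass, depth 4 (maxpool down, bilinear up, one residual per slot) | 256 |
| decoder | 2×2/2 transposed conv → residual → 2×2/2 transposed conv → residual | 256 → 256 → 128 → 64 |
| neck | 1×1 conv, BN, ReLU | 64 |
| heads | two 1×1 convs (bias) | 3 + 3 |

Residual blocks are pre-activation bottlenecks (BN–ReLU–1×1 reduce to
out/4, BN–ReLU–3×3, BN–ReLU–1×1 expand), with a 1×1 projection on the
skip only when the channel count changes; convolutions inside normalized
blocks carry no bias.  With width multiplier 1 this comes to exactly
**1,595,782** trainable parameters (including all batch-norm affine
terms), the count the test suite pins.  Published descriptions of this
family of networks leave several internals open (bottleneck ratio, bias
conventions, transposed-convolution kernels, tail channel widths); the
configuration above is the one within that design space whose parameter
count matches the published total exactly, which we treat as the arbiter.
All feature counts scale with `width_multiplier` for reduced variants
(0.25 is used throughout the desk-scale tests: 103,990 parameters).

The segmentation head is deliberately dual-natured: per-channel sigmoids
feed the binary cross-entropy loss during training, while a softmax
across the three channels yields normalized class maps at inference.
The heat-map head is linear; values are clipped to [0, 1] at inference.

The network, its layers, and reverse-mode differentiation are implemented
directly over numpy (im2col convolutions through BLAS, hand-written
adjoints, float32 throughout, with a fused fast path for 1×1
convolutions).  Gradient correctness is established against finite
differences in the test suite.

## Losses

With `g`/`ĝ` the binary/predicted class maps and `p`/`p̂` the heat maps,
per output channel `n` of `N = 3`:

- `L1 = −(1/N) Σₙ αₙ Σₓᵧ [g log ĝ + (1−g) log(1−ĝ)]` — class-balanced
  binary cross-entropy (the sign makes the minimized loss non-negative);
- `L2 = (1/N) Σₙ Σₓᵧ (p − p̂)²` — summed squared error (per-channel
  weights default to 1 for this head, switchable to the class weights);
- `L = L1 + L2`, with no extra scaling; batches average over samples.

Class weights follow median frequency balancing: `freq(c)` is the pixel
count of class `c` divided by the total pixels of *images containing*
`c`, and `α_c = median_freq / freq(c)`.  A class absent from every image
has no defined weight and raises an error.

## Training

rmsprop (smoothing 0.99, ε 1e-8), initial learning rate 1e-4 dropped
tenfold after 50,000 iterations, batch size 6, up to 500,000 iterations
from scratch and 120,000 when transfer-learning from an existing
checkpoint.  Augmentation applies one identical transform to image,
masks, and heat maps: horizontal flip with probability 0.5 and rotation
uniform in [−30°, 30°] (no random cropping).  Rotated-in corners are
filled with the image's per-channel mean; mask/heat channels with zero,
after which the background channel is rebuilt as the complement of the
root channels.  Minibatches are drawn with per-epoch shuffling; the
checkpoint with the best validation class-average pixel accuracy is
returned.  At the start of training the segmentation head's bias is set
to each class's prior log-odds (computed from the training masks), the
standard initialization for rare-class pixel classification — without it
the first ~1,000 iterations are spent learning class marginals.
Grayscale inputs are expanded by duplicating the channel, so one
architecture serves RGB and near-infrared data interchangeably.

Full-scale training is GPU-cluster work.  The desk-scale protocol
(`rhizotrace.benchmark`) trains the width-0.25 network on 64 synthetic
128 px scenes (16 held out) for 2,000 iterations at the published batch
size of 6; scaled scenes draw 2-3 laterals per root so all three classes
appear in every scene.  Two scale-aware choices matter: the hourglass
keeps its 8×8 bottleneck (one pooling level for 128 px inputs, where the
trunk is 16 px — pooling to 1×1 would leave batch normalization
estimating statistics from a handful of values), and each residual
block's expansion convolution is initialized at a quarter of the He scale
so blocks start near the identity.  Both choices also apply unchanged at
full scale; neither alters the reference parameter count, which is
defined by the depth-4 configuration.

## Post-processing

*Dense CRF.*  Mean-field inference on a fully connected CRF over the
three classes, with a Gaussian smoothness kernel (spatial σ 3 px, weight
3) and an appearance kernel (spatial σ 30 px, intensity σ 13/256, weight
5), 5 iterations; compatibilities are Potts.  The appearance kernel is
computed with a downsampled bilateral grid guided by image intensity —
the standard grid approximation of high-dimensional Gaussian filtering.
Kernel parameters are exposed in `CRFConfig`; the whole stage is
switchable off (identity), and its effect is intentionally subtle.

*Feature localization.*  Per heat-map channel: thresholded (0.7) 3×3
scanline non-maximal suppression — a pixel survives only if no neighbour
is strictly greater and no earlier-scanned neighbour is equal (row-major
order, so ties resolve deterministically to the earlier pixel) — followed
by greedy deduplication through a uniform-grid spatial index: a candidate
within 8 px of an already-kept point is discarded.

## Architecture reconstruction

Each class mask becomes an 8-connected lattice of traversal costs.  The
Euclidean distance transform of the mask is normalized to [0, 1] *per
connected component* (so thin and thick roots both keep a full-range
centering signal), then mapped linearly: root-edge pixels cost 0.1 per
step, centerline pixels 0.01, off-class pixels 10.0; diagonal steps pay
an extra √2.

First-order roots are traced from each detected tip to the seed set — A*
(`f = g + h`) when a single seed is present, uniform-cost search to the
nearest seed when there are several; second-order tips are traced on the
second-order graph with Dijkstra, ending on any pixel of an extracted
first-order path, and attach to that root.  Plants whose seed attracts no
first-order root are removed.  Paths are found tip → seed and reversed so
polylines run base → tip, then scaled back to native resolution.

The Manhattan heuristic is scaled by `(minimum step weight)/√2` — i.e.
0.01/√2.  A raw Manhattan distance over-estimates on an 8-connected
lattice (a diagonal step shrinks it by 2 while costing √2 × 0.01), and
even a 0.01 scaling remains inadmissible for the same reason; dividing by
√2 restores admissibility and consistency, so A* costs are exactly
optimal (verified against independent Dijkstra implementations).  Ties on
`f` break FIFO for determinism.  A path whose cost is >30% off-class
pixels is logged as suspect, never filtered — the pipeline stays fully
automatic.

Numerical choices in path measurement: search paths are pixel staircases,
so before spline fitting each path is filtered with a short (window 3–5)
moving average that recovers the sub-pixel centerline without erasing real
curvature; a lateral's first point is then re-projected onto its
(smoothed) parent so the attachment invariant holds exactly.

## Splines and RSML

Control points are sampled at equal arc-length spacing (default 20 px at
output resolution, never fewer than 8 segments per root so short roots
are not collapsed toward chords) and interpolated with cubic cardinal
splines, tension fixed at 0.5: the tangent at interior control point *i*
is `(1 − tension) · (P[i+1] − P[i−1]) / 2`, one-sided at the endpoints.
Cardinal splines are the standard interpolating family with a tension
parameter; they reproduce straight lines exactly and pass through every
control point.

RSML output follows the published schema: scene → plant → root elements
with laterals nested under their parent, polyline geometry per root, the
smoothed spline stored as an `annotation` so strict readers still parse
the polyline, and a metadata block (units, resolution, software).  The
seed location is written as a plant property; readers missing it fall
back to the first order-1 root's base.  Nesting deeper than two levels is
rejected — the tool models first- and second-order roots only.

## Traits

Per plant: `max_depth` (seed to lowest first-order tip, y-down),
`max_width` (horizontal extent of all root points), `convex_hull_area`
(hull of all root points), `centroid_depth` (mean y of uniformly
resampled points over all roots minus seed y — so long roots weigh
proportionally to length; resampling at ≤2 px makes the choice of step
immaterial to <0.5%), per-order counts and total arc lengths.  Pixels by
default; a mm-per-pixel factor converts lengths and areas.  The
implementation uses library hull/geometry routines and is tested against
an exhaustive brute-force oracle.

## The synthetic generator — what it does and does not emulate

Roots are direction-biased random walks (heading measured from image-down,
per-step Gaussian curvature noise, a weak pull toward the initial
heading), resampled to polylines.  Two assay styles: *fibrous* — one
plant, several first-order roots fanning from a seed over a blue
germination-paper-like texture; *taproot* — up to five plants in
horizontal slots on a dark plate (640 px default), one near-vertical
primary each plus laterals departing at 0.85–1.2 rad.  Rendering draws
anti-aliased strokes (laterals at 60% width) with additive noise;
everything is deterministic per seed.

The generator's constraints are resolvability conditions chosen so that
discrete recovery is an exact, testable property:

- tips of the same feature class are ≥25 native px apart (12.5 px at the
  half-resolution output, above the 8 px deduplication radius), enforced
  by rejection — so tip counts are exactly recoverable;
- centerlines of distinct roots never approach within a stroke width
  (+ margin), so the shortest-path reconstruction cannot switch
  corridors — crossing and overlapping roots, which the method is known
  not to disambiguate, are excluded from the study conditions;
- laterals leave their parent at ≥~30° effective angle throughout the
  branching zone and are at least ~80 px long: integer peak localization
  carries ±1 px of endpoint noise per end and the stroke-overlap blob at
  a junction a comparable amount, so a 5% per-root length check needs
  roots several times that noise floor.

Consequently, passing the end-to-end tests demonstrates the correctness
of the machinery under clean, crossing-free conditions; it does not show
robustness to occlusion, root overlap, soil clutter, illumination
variation, or root hairs, none of which the generator emulates.

## Known limitations

- Crossing/parallel roots are not disambiguated (inherited from the
  method); the generator excludes them by design.
- The dense CRF's appearance kernel uses intensity, not full color, in
  its bilateral grid.
- Sub-pixel peak localization is deliberately out of scope; tip
  coordinates are integral at the output resolution.
- The numpy network trains ~2 orders of magnitude slower than a GPU
  framework; desk-scale protocols keep widths, image sizes, and iteration
  counts small, and full-scale replication is out of scope.
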