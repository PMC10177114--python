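# Methods

## Problem and model

`oriface` detects animal faces of arbitrary in-plane orientation in RGB or
single-channel (e.g. infrared) images and predicts, per face, an
axis-aligned bounding box together with a rotation angle, so the face can be
normalized — rotated upright about the box center, cropped and scaled to a
square chip — for a downstream identification model.

The angle is the direction of the line from the left to the right eye
keypoint, in half-turns θ ∈ (−1, 1] (θ×180 = degrees, positive =
counterclockwise, image coordinates with y downward).  Computed from
keypoints it is exactly `atan2(yl − yr, xr − xl)/π`; the implementation uses
atan2 rather than a slope so the vertical case never forms an infinite
quotient.  Because θ jumps between +1 and −1 for nearly upside-down faces —
which would make a regression target discontinuous exactly where faces are
merely a degree apart — the detector predicts the *absolute* value |θ|
(sigmoid output) and the rotation *direction* (two-way softmax) separately
and reassembles the signed angle at inference.

The detector is a one-stage anchor-based network:

* **Backbone** — 14 convolution→batch-norm→ReLU (CBA) units in five blocks:
  block 1 has two CBA (the first 7×7, stride 2), blocks 2–5 have three CBA
  each (3×3; first at stride 2; the third with 4× the channels of the first
  two).  The last CBA of blocks 3–5 emits tensors at strides 8/16/32.
  Channel widths follow `base_width` (default 16) doubling per block; only the
  width ratios are fixed by the design; absolute widths are configuration.
* **Neck** — 1×1 lateral convolutions to a common width (default 64),
  top-down nearest-neighbour 2× up-sampling with element-wise addition
  (cropping one row/column when ceil-divided sizes disagree), plus a fourth
  stride-64 map produced by a stride-2 3×3 convolution from the merged
  stride-32 map.  No post-merge smoothing convolution is applied.
* **Head** — a single 3×3 convolution shared across all four maps with
  `k×9 = 54` output channels for the default `k = 6` anchors per cell:
  2 objectness logits, 4 box encodings, 2 direction logits, 1 angle-value
  logit per anchor.  Per-level outputs are flattened row-major with
  templates innermost and concatenated shallow→deep, which makes head row
  *i* describe anchor *i* of the flat anchor list by construction.

Anchors sit at cell centers of `ceil(dim/stride)` grids at strides
(8, 16, 32, 64) with per-level base sizes (32, 64, 128, 256) px, two scales
(1, 2) and three aspect ratios (1, 2, ½) at constant area — 20,058 anchors
for a 400×400 input.  Boxes are coded anchor-relative:
tx = 10(x−xa)/wa, ty = 10(y−ya)/ha, tw = 5·log(w/wa), th = 5·log(h/ha).

## Training

Each step draws T1 images from the angle-labeled dataset (ds1) and T2 from a
box-only dataset (ds2; it may alias ds1 with labels ignored), applies the
three affine augmentations independently per image with configured
probabilities, optionally tiles 4 (2×2) or 9 (3×3) scenes into one, and
letterboxes to the input size.  Angle ground truth transforms in closed
form: rot90ccw ↦ wrap(θ+0.5), hflip ↦ −θ, vflip ↦ wrap(1−θ).  The vflip
map deserves a note: extending the non-negative branch 1−θ to all θ (and
wrapping) is the only choice that is an involution, composes with hflip to
an exact 180° rotation, and agrees with angles recomputed from mirrored
keypoints under the convention that a mirror swaps the left/right eye
labels; the clockwise branch is sometimes quoted as θ−1, which fails all
three checks once wrapped.

Anchors match to ground truth at IoU ≥ 0.5 (plus a best-anchor-per-object
rule so every object trains at least one anchor); a class-balanced sample of
≤ 256 anchors per image (≤ 25% positives) forms the loss mini-batch.  The
objective is the weighted sum

L = λloc·Lloc + λobj·Lobj + λav·Lav + λad·Lad,  (λ = 1, 5, 1, 10)

* Lloc — Huber (δ=1) on box-encoding residuals, mean over the N_loc sampled
  positives;
* Lobj — focal loss FL(pt) = −(1−pt)^γ log pt with γ=2 and pt = 1−|p−p*|,
  mean over all sampled anchors;
* Lav — squared error on |θ|: ds1 positives pull toward the true value with
  weight λds1 = 10, ds2 positives pull toward 0 with weight λds2 = 0
  (disabled by default but implemented in full), normalized by N_loc;
* Lad — focal loss on the direction probability over the gated set
  {i : |θ*_i| > ε}, ε = 0.025; box-only positives carry no angle and never
  enter the gate.

Empty reductions (no positives, empty gate) contribute 0 rather than NaN.
The optimizer is momentum SGD (0.9) with linear warmup (50 steps) and
cosine decay to 1% of the peak rate, plus global-norm gradient clipping at
10 — the warmup and clipping are stability measures for the float32
training arithmetic and small batches.  Probabilities inside logs are
floored at 1e−7.  Training is deterministic given the config seed.

The numerical engine is a compact reverse-mode autodiff over numpy float32
arrays written for this package (`oriface.nn`): strided SAME-ceil
convolution via im2col + GEMM, fused batch normalization, and the
elementwise/indexing operations the losses need.  Every operation is
validated against central finite differences in the test suite.

## Inference and normalization

Anchors with objectness ≥ 0.5 are decoded, the signed angle is assembled as
+value if p(ccw) > 0.5 else −value, and greedy NMS at IoU 0.5 keeps at most
100 detections (score order, index tie-break).  Normalization rotates the
whole image by −θ×180° about the box center (bilinear, zero fill), crops the
box dimensions, and scales to the output side (default 224); rotating before
cropping avoids clipping rotated content at the corners.

## Evaluation

Detections match ground truth greedily in descending score order at IoU 0.5,
each ground-truth box claimed at most once.  Precision/recall/F1 describe
the operating point at the detector's score threshold; AP integrates
precision over recall increments across the full score sweep (all-points
rule, no 11-point interpolation).  AAD is the mean wraparound angle distance
D = min(|Δθ|, 2−|Δθ|) × 180° over true-positive matches — only matched
detections have a ground-truth angle to compare against.

## Synthetic scenes

The generator renders elliptical face glyphs (semi-axes a and 1.3a, a
uniform in [14, 26] px on a 128 px canvas) with two darker eye dots placed
symmetrically about the face axis at ±0.45a along the eye line and 0.35b
above center, rigidly rotated by θ drawn uniformly from (−1, 1]; one or two
faces per scene, non-overlapping, with Gaussian pixel noise (σ = 0.02 on a
[0,1] scale).  Exact box, angle and keypoints are recorded per glyph, so the
generator doubles as its own oracle: recomputing the angle from rendered
keypoints reproduces the sampled θ to 1e−6.  The glyphs capture what the
method needs from real data — a compact blob whose eye pair defines
orientation — but none of the photographic nuisance (occlusion, clutter,
lighting, out-of-plane pose), so passing the synthetic benchmark shows the
pipeline learns and decodes orientation correctly, not that it would reach
the same accuracy on field imagery.

## Scaled benchmark

`oriface.benchmark.run_scaled_benchmark` trains the small configuration
(base_width 8, 128×128 single-channel input, ~1.5 M parameters) from
scratch on 300 generated scenes for 2,000 steps (batch 3 ds1 + 1 ds2, the
ds2 stream aliasing the same scenes box-only) and evaluates AP and AAD on
100 held-out scenes.  The problem sizes are chosen so the run completes in
a few minutes on one CPU core.  Learning rate is 0.012: rates near 0.02
sit on the edge of float32 training stability and can leave the angle heads
stuck for some seeds, while 0.012 converges for every seed tested.  Flip
and 90°-rotation augmentation stay at probability 0.5; tiling is disabled
at this scale because halving 128 px scenes pushes the eye dots (radius
≈ 0.16a ≈ 2–4 px) below the resolution the angle head needs — at the
full 400 px working resolution that constraint does not bind.

## Degenerate inputs and numerical choices

Coincident keypoints raise (angle undefined); boxes must have positive
extent; matching with no ground truth labels every anchor negative;
`wrap_angle` keeps exact +1.0 (never −1.0); θ = 0 splits to direction
"clockwise" by convention (the combined angle is unaffected).  Nearest
up-sampling crops (never pads) to the lateral size; letterboxing anchors
content at the top-left and scales isotropically so angles are unchanged.
PNG round-trips quantize pixels to 8 bits; annotations themselves
round-trip losslessly through JSONL.

## Known limitations

Single class; axis-aligned boxes only (the angle rides on a separate head —
rotated-box IoU is out of scope); no alternative backbones bundled (any
extractor emitting stride-8/16/32 maps can replace the default); CPU-bound
numpy training is practical at benchmark scale but not at the full
50,000-step production scale; absolute channel widths are free parameters
of the design, so parameter counts depend on the chosen base width.
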