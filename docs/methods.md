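# Methods

`rowline` detects crop rows in RGB field images as whole geometric entities.
This note records the model, the choices behind its parameters, what the
synthetic scenes do and do not emulate, and the numerical conventions that a
user extending the package should know.

## Row representation

A row annotation is an ordered polyline with strictly increasing `y`
(top-left origin, pixel units, sub-pixel precision).  For learning and for
the Row-IoU loss a row is discretized at `N` uniform vertical positions
`y_i = H/(N-1) * i`, `i = 0..N-1`, storing the interpolated abscissa `x_i`
and a validity flag per position (positions outside the polyline's vertical
span are invalid).  `N` defaults to 40 at the full profile and 36 at the
tiny profile; the representation is exact for any polyline that is piecewise
linear between sampling rows, and the representational-completeness test
checks that sampling followed by anchor-relative reconstruction is the
identity on valid rows.

Predictions are expressed relative to an *anchor line* — a straight prior
parameterized by its bottom end point `(x, y)`, its angle `theta` to the
positive x axis (in `(0, pi)`, so never parallel to a sampling row), and a
real-valued length counted in sample rows — plus one horizontal offset per
sampling row.  Angles are measured so that moving up the image by `dy`
moves the reference line by `dy / tan(theta)` in `x`.  Internally all four
anchor parameters are stored in image-relative units (`x/W`, `y/H`,
`theta/pi`, `length/N`) so one optimizer step size is commensurate across
components; pixels are materialized only when geometry is realized.

## Network

A width-scalable 18-layer residual backbone feeds a top-down feature
pyramid; three cascade stages refine a fixed set of learnable anchor lines
(`p0 -> p1 -> p2`), pooling features along the current anchors from
progressively finer fused maps (strides 32, 16, 8).  Each stage samples the
map bilinearly at the anchor's `N` sampling positions, applies a kernel-3
convolution along the line, enriches the features with the attention block
below, and feeds a per-anchor head: two shared fully connected layers with
linear branches for the score and the four parameter deltas, plus a small
per-point convolution over the line sequence producing the per-row offsets
(offsets are a local quantity; regressing them from the flattened trunk
trains far worse).  Delta and offset branches are zero-initialized, so an
untrained cascade is the identity refinement (`p2 == p0`); the score bias
starts at -2 as usual for focal classifiers.

Anchor priors tile position-angle space: 75% of anchors start on the bottom
border, each bottom position carrying a small fan of angles spanning 55-125
degrees (rows seen from a camera pitched down the row direction are
near-vertical in the image), with seeded jitter; the remainder start on the
lower halves of the side borders leaning toward the frame interior.  All
priors are trainable, but at a 10x reduced learning rate
(`train.anchor_lr_scale`), since the priors also define the assignment
geometry and fast drift collapses the angle fan.  Sampling positions are
treated as constants during backpropagation: anchor geometry is trained
through the regression losses, not through the pooling grid, which is the
usual choice for line-anchor detectors and keeps the pooling operation
cheap.

The per-anchor head also emits *extent logits* — one on-row/off-row logit
per sampling position, from the same per-point convolution that produces
the offsets — supervised against the ground-truth validity mask of the
assigned row.  At decode time the anchor's start row and length are taken
from the longest above-0.5 run of the extent, which localizes rows clipped
by the frame edge far better than the regressed scalar length (the scalar
start/length remain supervised and act as the fallback).

### Dual-axis squeeze attention

Features pooled along a line lack global context.  The attention block
scatters the per-point line features onto a zero spatial map (bilinear,
mass-conserving) to form the query; keys and values are 1x1 projections of
the feature map.  Attention is computed separately along the two axes after
averaging over the other axis, so the interaction matrices are `H x H` and
`W x W` rather than `(HW) x (HW)`; the per-position output is the sum of the
row-attention and column-attention results.  A convolutional
detail-enhancement branch (broadcast line query, dense key/value, 3x3
convolution, group-norm + ReLU, 1x1 projection, logistic squashing)
produces a gate `g` in `(0,1)`, fused as `g * y + y`, and the fused map is
sampled back at the anchor points.  A dense `(HW) x (HW)` reference
implementation is available via `attention.mode = "full"` for ablations; on
1x1 maps the two agree exactly (the dense form is doubled there because the
dual-axis form counts the single cell once per axis).  `mode = "off"`
bypasses the block.

## Row-IoU loss

At every valid sampling row of the ground truth, predicted and true
abscissae are extended horizontally by `e` (default 15 px at network
resolution); the signed segment IoU is `(2e - d)/(2e + d)` with
`d = |x_p - x_g|`, negative when disjoint.  The row-level RIoU is the ratio
of summed overlaps to summed unions over the gt-valid positions — a ratio of
sums, *not* a mean of per-position IoUs — and the loss is `1 - RIoU` in
`[0, 2]`.  Validity is taken from the ground truth alone: predictions are
dense along their anchor, and the ground-truth row defines which sampling
positions carry meaning.  The denominator guard `max(den, eps)` keeps the
loss *exactly* zero at the ground truth (an additive stabilizer would not).

The total objective is

    L = w_cls * L_cls + w_xytl * L_xytl + w_riou * L_riou

summed over the three cascade stages with equal weight.  `L_cls` is a focal
loss computed from logits (the clipped-probability form has exactly zero
gradient where a score saturates on the wrong side; the logit form never
does), normalized by the number of positives.  `L_xytl` is smooth-l1 on the
four anchor parameters in image-relative units; `L_riou` is the Row-IoU
loss on the realized abscissae, both averaged over positives.  Defaults
`w_cls = 2`, `w_xytl = 3`, `w_riou = 20`: the Row-IoU loss is
self-normalizing (its per-point gradient scales like `4eN/den^2`, i.e.
*shrinks* as predictions get worse), so it needs a large weight to compete
with the classification gradient in the shared head trunk; the values were
chosen by monitoring loss-term gradient balance on synthetic training runs.
The focal alpha default is 0.5 — at these training scales the positives are
the scarce signal and the usual 0.25 starves recall.  The extent logits
add a binary cross-entropy term (weight 6 inside the xytl bucket) against
the gt validity mask of each positive.
A smooth-l1-on-abscissae alternative is available via
`loss.regression = "smooth_l1"` for the ablation grid.

### Numerical conditioning of the geometry losses

Two properties of the anchor-line parameterization demanded care.  First,
the abscissa model `x + (y - y_i)/tan(theta)` is *gauge-invariant*: sliding
the start point along the line leaves every abscissa unchanged.  The
Row-IoU gradient reaching `y` is roughly `N/tan(theta)` times stronger than
the smooth-l1 term that anchors the gauge (all sampling rows move
coherently), and in early training it drags start points far outside the
frame, where the length gate empties the prediction.  The start point is
therefore *detached* in the Row-IoU abscissa path — `y` is trained only by
its direct smooth-l1 target — and all four normalized parameters are
bounded per stage by a straight-through projection (`x/W` in [-0.5, 1.5],
`y/H` in [0, 1], `theta/pi` in [0.02, 0.98], `len/N` in [0, 1]).  Second,
normalization is *group* norm, not batch norm: with batch 8, batch-norm
running statistics diverged from batch statistics enough that eval-mode
geometry differed from train-mode geometry by hundreds of pixels,
producing wildly oscillating validation scores; group norm computes
identical statistics in both modes.

## Dynamic assignment

Each ground-truth row dynamically claims `k` predictions as positives,
`k = clamp(round(sum of top-4 positive row-IoU values), 1, 4)`, choosing the
`k` with the lowest cost `C = w_sim * (C_dis * C_xy * C_theta)^2 +
w_cls * C_cls` (mean point distance over image width, start-point distance
over the diagonal, angle difference over pi, each clamped to `[0, 1]`; the
classification cost is the focal cost of the score against a positive
label).  Conflicts go to the cheaper ground truth; a ground truth left
empty claims its cheapest unassigned prediction, so every gt with a
candidate receives at least one positive.

Two numerical points matter here.  First, the squared triple product of
`[0,1]`-scaled factors is *tiny* (a thoroughly mediocre candidate with all
factors at 0.5 scores 0.0156), so `w_sim` must be very large for geometry
to dominate candidate selection; the default is `1e6`, which places the
interesting range of `C_sim` on the same scale as the focal cost.  Second,
inside the assignment the factors are floored at 0.01: without the floor a
prediction 200 px away but with an exactly matching angle has zero cost and
outranks a uniformly close candidate.  The public `similarity_cost`
operation reports the unfloored values.

One assignment per image is shared by all supervised stages.  Which
geometry feeds the cost matters enormously at small training scale:
re-assigning per stage from refined predictions churned completely (a
different anchor serving each row at every step), and even a single
shared assignment from the final stage kept churning as predictions
evolved, so no anchor could specialize.  The default therefore computes
the assignment cost from the *fixed anchor priors* for the first
`assign.static_epochs` epochs (the whole schedule at the tiny profile; a
10-epoch warmup at the full profile), after which the prediction-based
dynamic rule takes over.  The cost formula is identical in both modes.

## Inference

Scores come from the final stage.  Predictions below `infer.score_threshold`
(0.25) are dropped; greedy line NMS keeps the highest-scoring prediction
and suppresses others whose row-IoU with it exceeds `infer.nms_iou`.  The
NMS overlap uses a segment extension of 25 px — half the evaluation stroke
width — so suppression mirrors the thickened-mask protocol rather than the
training extension.  The suppression threshold default is deliberately low
(0.1): adjacent crop rows are separated by far more than the suppression
radius (their row-IoU is negative), so aggressive suppression cannot merge
two real rows; it only removes near-duplicate hypotheses from neighboring
anchors.  At most `infer.max_detections` (8) rows are kept per image, and
samples whose abscissa leaves the frame are trimmed from the realized
polyline rather than clamped to the border.

## Evaluation protocol

Predicted and ground-truth centerlines are stroked to 50 px wide binary
masks at annotation resolution (square caps, joins filled, no
anti-aliasing; a pixel at row `r`, column `c` samples the point
`(x=c, y=r)`, and the stroke covers the half-open band `[-w/2, w/2)` across
the line, so a width-50 vertical line at `x = 50` covers exactly columns
25..74).  Per image, predictions and ground truth are matched one-to-one by
optimal bipartite matching on the mask-IoU matrix (scipy's Hungarian
solver), the same matching at every threshold.  A matched pair with IoU
strictly above `tau` is a true positive; F1 is reported at
`tau = 0.50, 0.55, ..., 0.95` and mF1 is 100 times their mean.  F1 at a
fixed matching is non-increasing in `tau` by construction.  Note that
maximizing total matched IoU does not provably maximize the TP count at
every threshold — counterexamples exist for adversarial IoU matrices — but
on row-geometry instances the two never disagreed in testing, and the fixed
matching keeps the threshold sweep internally consistent.

## Synthetic scenes

The generator renders a flat field seen through a pinhole camera pitched
down toward the ground (default 45 degrees, emulating rig angles between 30
and 60): world-parallel row lines project to straight, converging image
lines, which are the exact ground-truth polylines.  Green plants (clusters
of 3-5 elongated leaf ellipses, perspective-scaled) are placed along each
row at fixed world spacing with jitter, dropped with probability 0.1
(seedling gaps); weeds are isotropic green blobs scattered uniformly at 0.3
blobs per kilopixel, so plants and weeds differ in shape statistics and
spatial organization, not only color; the soil is low-frequency blotched
noise.  Illumination gain in [0.6, 1.4], Gaussian blur (sigma 0.6 px), and
a lateral wind/lodging displacement of the plant blobs (sigma 2 px) perturb
the rendering but never the annotations.  Per-image seeds derive from the
master seed via SHA-256, so datasets are byte-reproducible and splits with
different master seeds share no image.

What the generator does *not* emulate: real leaf morphology and occlusion,
inter-row shadows, terrain relief (rows here are exactly straight in image
space), camera distortion, and the label noise of human annotators.
Passing the end-to-end tests therefore shows that the architecture, losses,
assignment and evaluation pipeline can jointly recover row geometry from
images under controlled clutter — not that the system is field-ready.

## Profiles and problem sizes

The `full` profile mirrors the published training setup (3x800x320 input,
AdamW at 1e-4, polynomial learning-rate decay with power 0.9 — the
described schedule names a cosine decay *with a power factor*, which is
internally inconsistent; polynomial decay uses the stated power, and cosine
remains available via `train.schedule` — 70 epochs, batch 40).  The `tiny`
profile is the CPU-scale configuration used by the test suite and the
acceptance script: 3x320x160 input, 64 anchors, 36 sample rows, a 0.125
backbone width multiplier, 32 pyramid channels, a 100-step learning-rate
warmup, AdamW at 1e-3 with a weight EMA (decay 0.99) for evaluation,
30 epochs, batch 8, 200/50/50 train/val/test scenes generated at 320x160
(annotation resolution equals generation resolution, and the 50 px
evaluation thickness is kept as the protocol constant).

Problem sizes in the shipped checks: the full 200-scene train/evaluate
cycle runs in `scripts/acceptance.py`; the test suite runs the same
30-epoch schedule on three seeds with 128 training scenes, and the ablation
grid uses 64-scene, 4-epoch arms (2 epochs for the pure configuration
toggles), so that the complete suite remains a single-CPU desk-scale run.
Scores grow markedly with training data at this scale (runs at 96, 128,
140 and 200 scenes landed near 34, 42-58, 64 and 66-79 F1@50 in
development), which is the package's main known gap against its own
synthetic-recovery bar: the in-suite three-seed median at 128 scenes was
57 against the 80-point target, and the full-size 200-scene cycle in the
acceptance script reached 67.

## Known limitations

- The autodiff core (`rowline.nn`) implements exactly the operations this
  network needs; it is tape-based, eager, and single-threaded apart from
  BLAS.
- Anchors are straight lines; strongly curved rows would need per-row
  offsets to carry all curvature, and rows more horizontal than 15 degrees
  are outside the prior fan.
- Scores from short, small-data training runs are poorly calibrated in the
  absolute sense; the default score threshold trades recall against the
  false-positive rate under the NMS and detection-cap settings above.
- `length` gating uses ceil, so a length between k-1 and k always activates
  k sampling rows; sub-row partial validity is not modeled.
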