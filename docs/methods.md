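# Methods

## Problem and model

The detection target is the plant stem emerging point (PSEP): the pixel
where a cereal plant's stem exits the soil in a top-view field image.
Because seed drills sow in narrow, jittered rows, plants overlap and the
usable signal is local: the convergence of leaves onto a basal point.  The
package frames detection as two-class semantic segmentation.  Point
annotations are rasterized as filled disks (membership by pixel-center
Euclidean distance, boundary inclusive; overlapping disks merge), the
network predicts per-pixel softmax probabilities over (background, PSEP),
and detections are the centroids of 8-connected components of the
thresholded PSEP channel.  Centroids rather than probability peaks are used
because the annotation marks are filled disks whose center is the intended
location; no minimum component area is imposed by default (a `min_area`
knob exists).

## The objective

Training minimizes the penalty-weighted cross-entropy

    E = -(1/K) Σ_n Σ_k p_n t_nk ln(y_nk),

with per-pixel weights p_n ∈ {0, 1, w}:

* **Halo (p = 0).**  A zero-weight ring around each mark absorbs annotation
  jitter.  Its radius is not dictated by the annotation geometry itself; the
  default equals the mark radius (so the ring spans radii (r, 2r] around a
  point), the smallest scale at which hand-marking error is plausible.
* **Penalty regions (p = w).**  Pixels where the penalty-free primary model
  responded confidently (PSEP probability ≥ 0.5) at least `exclusion_radius`
  away from every annotated disk.  The exclusion default is mark radius +
  halo radius for field-scale marks; the desk-scale benchmark widens it to
  two mark diameters (12 px) so that penalties never sit on the leaves of
  real plants — penalties adjacent to true points are known to prevent
  convergence.  Regions are derived once from the primary model, not
  re-derived per epoch.
* **Everything else (p = 1)**, including the interior of the mark disks.

Two normalizations are exposed.  `literal_scaling=True` reproduces the 1/K
constant exactly (useful for verifying the formula); the training default
divides additionally by Σ p_n, which makes the objective a weighted mean
independent of crop size.  The constant only rescales the effective
learning rate, so both define the same optimum.  Probabilities are clipped
to [1e-7, 1] before the logarithm.

## Network and training

Both backbones share the skip-fusion topology: class scores predicted from
the coarsest features are upsampled ×2 and summed with scores from the next
finer stride, twice, then upsampled to input resolution.  `vgg16-fcn8s` is
the full five-stage VGG16-derived stack (fusion at strides 32/16/8, the
fully-connected layers as 7×7 and 1×1 convolutions); `mini` has three
stages (fusion at strides 8/4/2) with channels (12, 24, 48) by default.
Inputs below 32×32 are rejected; any larger size works (ceil-mode pooling,
nearest-neighbour upsampling cropped to the skip size).

The implementation is plain NumPy: convolutions are evaluated as k² shifted
matrix products (BLAS), with hand-derived backward passes verified against
finite differences in the test suite.  Design choices specific to training
small models from scratch:

* **Leaky rectifiers (slope 0.1) in the mini backbone.**  With Adagrad at
  the desk-scale learning rate, an aggressive early update can push every
  unit's pre-activation negative; with classic ReLUs the gradient then
  vanishes permanently and the model is stuck predicting pure background
  (observed as a loss plateau at the class-prior entropy).  A small
  negative slope keeps units recoverable.  The vgg16-fcn8s stack keeps
  classic ReLUs, matching its standard layer definitions.
* **Prior-biased score initialization.**  PSEP pixels are ~1–2% of a scene,
  so the fused class scores are initialized with a PSEP-vs-background logit
  offset of −4 (initial PSEP probability ≈ 1.8%).  Starting at the class
  prior removes the large, uninformative background gradients of the first
  updates.
* **Optimizer.**  Adagrad with a stepped schedule; the field-scale default
  is 40 epochs at lr 1e-3 with halvings after epochs 32 and 36, random
  1500×1500 crops, one update per image.  Desk-scale runs use the same
  schedule object at 8–10 epochs, lr 0.05, 96-px crops.
* **Determinism.**  All randomness (initialization, shuffling, crop
  positions, scene content) derives from explicit seeds; a fixed seed and
  fixed threading reproduce a run bit-for-bit.

## Two-pass penalty protocol

`PenaltyPipeline` trains the primary model penalty-free (weights 1, halo 0),
derives penalty regions from it, and for any positive weight retrains a
*copy of the primary model* under the penalty-weighted loss (a gentler
schedule, lr 0.01 for 8 epochs in the benchmark).  Warm-starting mirrors
the retraining step of the protocol and matters in practice: training from
scratch under ×50 pixel weights lets early penalty spikes flood the Adagrad
accumulators of features shared with true plants, which permanently slows
their learning and produces a globally timid model.  Weight 0 in the model
grid denotes the primary network itself.

## Evaluation

Detections and annotations are matched one-to-one by minimum-cost
assignment (Hungarian algorithm on the distance matrix, infeasible pairs
given a cost larger than any full assignment of feasible ones), which
maximizes the number of pairs within tolerance and, among such assignments,
minimizes total distance.  The default tolerance equals the mark diameter —
two points whose annotation disks could touch.  Empty denominators use the
perfect-by-convention rule (P = 1 with no detections, R = 1 with no
annotations) so empty scenes predicted empty score 1.  Grid cells report
P/R/F micro-averaged (TP/FP/FN summed over evaluation images before the
ratios); the best cell is the maximum F with ties to the lower threshold.
Count agreement is the coefficient of determination R² = 1 − SS_res/SS_tot
with annotated counts as reference.  Pixel accuracy is deliberately not
reported: with PSEP pixels this rare, all-background scores ≈ 99%.

## Synthetic scenes

The generator emulates what the method needs from field imagery and no
more: a soil background (low-frequency blotches, grain noise, speckle
clutter), plants as 2–4 curved leaf strokes radiating from a base point
darkened into a small blob (the base pixel is the ground truth), and
distractors with no truth point — lone leaf strokes, pale residue straws
and, most importantly, pairs of leaf tips converging on a point with a
sub-pixel gap and no basal blob.  The tip-pair is the deliberate lookalike:
a penalty-free model reliably fires on it, and rejecting it requires
attending to fine structure (the gap, the missing blob) that ordinary
weight-1 training does not prioritize.  The `hard` preset (seed-drill rows
with jitter and overlap, 2.5 distractors per plant, 128×128) provokes this
failure mode; the `easy` preset (well-separated, high-contrast, no
distractors, 256×256 for evaluation) isolates counting ability.

What the synthetic world does *not* model: real soil texture and residue
statistics, illumination and shadow, weed species, camera optics, and
annotation error (truth is exact).  Passing tests therefore demonstrate the
mechanics of the method — the loss, the two-pass protocol, matching and
survey logic — not field-level accuracy.

## Benchmark problem sizes

`penalty_benchmark`: 100 hard training scenes and 50 evaluation scenes of
128×128 px with 6–15 plants each, mark diameter 6 px, tolerance 6 px, mini
backbone, penalty weight 50.  `count_recovery_benchmark`: 40 easy 128×128
training scenes, 30 easy 256×256 evaluation scenes with counts evenly
spanning 0–110 (covering all eleven ranges of the average-60 scheme),
operating threshold 0.4.  Each runs in minutes on a single CPU core.  These sizes are the package's desk-scale study conditions; the
field-scale defaults (20-px marks, 1500-px crops, 40 epochs) remain the
configuration defaults throughout.

## Known limitations

* The NumPy implementation processes one image per update; there is no
  batching or GPU path, so field-scale training with the vgg16-fcn8s
  backbone, while implemented, is impractical here and pretrained weights
  are not shipped.
* The penalty mechanism's benefit depends on the primary model actually
  committing distractor errors; on data where weight-1 training already
  separates distractors, retraining with penalties changes little.
* Micro-averaged grid metrics weight dense images more than sparse ones;
  per-image averaging is not currently exposed.
* Range bandwidths from non-integer averages are kept fractional;
  classification of integer counts remains well defined.
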