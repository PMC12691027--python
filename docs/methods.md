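# Methods

## Problem and model

`snoutnet` detects pig faces in RGB images and classifies each face into
one of four health states — Normal, Cold, Cough, Fever — whose clinical
facial cues (eye brightness and discharge, snout moisture/gloss, mouth
aperture) are visually distinguishable.  The detector is a compact
anchor-free single-stage network:

* **Backbone**: strided stem plus four stages of stride-2 convolution and
  CSP split/merge blocks (C2f), ending in an SPPF pooling block; feature
  maps at strides 4/8/16/32.
* **Neck**: PAFPN — top-down then bottom-up multi-scale aggregation,
  emitting the pyramid P3/P4/P5 (strides 8/16/32).
* **Head**: decoupled per-level branches.  Regression predicts, for each
  of the four box-edge distances, a categorical distribution over
  `reg_max = 16` bins in stride units, decoded by expectation
  (distribution-focal formulation).  Classification predicts one sigmoid
  score per class.  With 4 classes the combined per-level output is
  4 + 4·16 = 68 channels.

Scaling follows the "s"-scale convention: base channels
(64, 128, 256, 512, 512) and stage depths (3, 6, 6, 3) multiplied by
`width_mult = 0.50` / `depth_mult = 0.33`.  Tests and the end-to-end
checks use a reduced instantiation (`width_mult = 0.125`,
`depth_mult = 0.17`, inputs 96–128 px); these sizes are the package's
own desk-scale choice and all structural guarantees (cost algebra,
shape contracts, orderings) are scale-independent.

## The three refined components

**FASFF (adaptive spatial feature fusion).**  Between neck and heads,
each output level fuses all pyramid levels aligned to its own grid:
coarser maps are bilinearly upsampled, finer maps downsampled by strided
3×3 convolutions, channels matched by pointwise projection.  A pointwise
sub-network (concat → 1×1 to 3r channels, r = 8 → SiLU → 1×1 to 3
logits) produces per-location level logits, normalized by a softmax
across levels, so the weights are nonnegative and sum to one at every
location; the fused map is the per-location convex combination.
Per-output-level fusion is the established convention and keeps head
geometry exact; the literal single-common-grid reading (fuse once at the
finest grid, redistribute by block averaging) is available via
`common_grid=True`.  The four-head variant (`fasff4`) adds one extra
top-down stage to a stride-4 P2 level and fuses/detects over four levels,
for very small faces.

**CSPPC (partial-convolution blocks).**  Partial convolution partitions
the C input channels into two groups via a binary selection vector
(contiguous halves by default) and convolves each group with its own
sub-kernel over only its own channels — a block-diagonal kernel.  For the
equal split, parameters and MACs are exactly half of the dense C×C
convolution (C²k²/2), which is the module's core invariant, verified
against a masked dense kernel to 1e-5.  CSPPC keeps the C2f topology but
replaces each dense 3×3 bottleneck pair with a PConv plus a pointwise
convolution restoring cross-group mixing; output shapes are unchanged, so
the swap is drop-in everywhere.

**iEMA (attention ahead of each head).**  EMA splits channels into groups
(8 by default, reduced to a divisor when channels are narrow) and runs
two parallel branches: a 1×1 branch driven by directional (H/W) average
pooling and a replicate-padded 3×3 branch.  Each branch's globally pooled
descriptor is dotted against the other branch's per-position features;
the two similarity maps are summed, sigmoid-gated, and applied
multiplicatively.  The published description leaves the dot-product
operands open; this bidirectional pooled-descriptor reading is a
reconstruction and is documented as such.  The iRMB that follows is
expand (1×1) → depthwise 3×3 → project (1×1) with an identity skip and a
zero-initialized projection (identity at start).  All its convolutions
are bias-free and unnormalized, so the parameter count is exactly
C·E + E·k² + E·C.  The expansion ratio is 1.5: it keeps the whole
module's overhead near 8% of the host detector (the design brief for
this component was a small-single-digit-percent overhead; a ratio of 2.0
pushes past 10%).  Ablation flags build EMA-only, iRMB-only, or the full
EMA→iRMB composition.

## Losses and assignment

Total loss: `7.5·L_box + 0.5·L_cls + 1.5·L_dfl` (canonical weights for
this detector family; the decomposition itself is fixed, the weights are
a package choice).

* `L_box = 1 − CIoU` over matched pairs.  CIoU = IoU − ρ²/c² − αv with ρ
  the center distance, c the enclosing diagonal, v the squared arctan
  aspect difference scaled by 4/π², α = v/(1−IoU+v) with gradient stopped
  through α (standard practice).  CIoU ≤ IoU always; equality iff centers
  and aspect ratios coincide.
* `L_dfl`: cross-entropy of each edge's bin distribution against the two
  integers bracketing the continuous target, linearly weighted.  Targets
  are clipped to [0, reg_max−1−10⁻³] so both bracketing bins exist.
* `L_cls`: binary cross-entropy with label smoothing ε = 0.05 (targets
  1 → 1−ε, 0 → ε), normalized by the number of assigned locations.

Assignment is a deliberately simple, exhaustively testable center-prior
rule: a grid cell is a candidate for a ground truth when its center lies
inside the box and the box's maximum edge distance falls in the cell's
level range ((previous upper, 8·stride], open at the coarsest level); the
k = 10 candidates nearest the box center are matched; a cell claimed by
several boxes goes to the smaller-area one (ties to the lower index).
Prediction-aware assigners were rejected because their behavior cannot be
enumerated in a test.

## Training protocol

AdamW with decoupled weight decay 0.05 (skipped for 1-D parameters),
linear warm-up from lr_init/100 over the first 3 epochs, cosine decay
from 1e-3 to 1e-5 across epochs 3→100, gradient clipping at global norm
1.0, batch size 16, early stopping after 15 non-improving validation
epochs, best-validation-mAP50 checkpoint returned.  mAP50 (not mAP50–95)
drives model selection because it is the headline metric.  Repeated runs
use seeds (42, 3407, 2025); aggregates are mean ± sd with a
t-distribution interval at n−1 degrees of freedom.

The numerics core is a small reverse-mode autodiff engine over numpy
(`snoutnet.autodiff`): convolution via strided window views and einsum
contractions, fused batch-norm and softmax backward rules, float32
throughout.  Every layer's gradient is validated against central
differences in the test suite.

## Synthetic scenes

The generator renders parametric blob composites, not photorealistic
pigs.  Its contract: four appearance classes separated by ≥ 0.25 in at
least one archetype coordinate (eye brightness, snout gloss, mouth
aperture — e.g. Normal 0.85/0.85/0.10 vs Fever 0.35/0.15/0.30, Fever
additionally hue-shifted toward red, Cold with discharge streaks);
identity-linked base hue and speckle texture so ID-aware splitting is
testable; log-uniform face scale over (0.25, 0.45) of the canvas so
both small- and large-target paths are exercised; class-independent
background clutter.  Default canvas 96 px, two faces per scene, 40
identities.  A linear probe on crude per-region color statistics reaches
>90% accuracy on 400 faces, which is what makes the end-to-end training
check winnable.

What the generator does *not* emulate: occlusion beyond 50% box overlap,
motion blur, illumination fields, viewpoint/pose variation, fur texture,
inter-individual morphology.  Passing tests therefore demonstrate that
the pipeline's machinery is correct and trainable, not that the detector
reaches any particular accuracy on real farm imagery.

## Data engineering

Preprocessing: resize to a common square resolution (640 default) →
single-level db2 wavelet shrinkage (soft universal threshold
σ√(2 log N), σ from the MAD of the diagonal detail band / 0.6745) →
per-channel Z-score with statistics fitted on the training split only.
A zero-variance channel standardizes to all zeros with a logged warning.
Augmentation: rotation ±15° (boxes become the clipped axis-aligned hull
of the rotated corners; boxes keeping < 10% of their area are dropped
with a logged count), horizontal flip p = 0.5 (xc → 1−xc), photometric
saturation/brightness/contrast factors in [0.8, 1.2].

Splitting is animal-ID-exclusive: whole identity groups are assigned, in
seeded shuffle order, to the split with the largest remaining relative
per-class quota deficit.  This greedy rule fills integral quotas exactly
(the balanced 5600-image case lands at 950/275/175 per class) and
otherwise deviates by at most one group.  A degenerate single-identity
dataset collapses to one split with a warning; a multi-identity dataset
in which some class has fewer identities than active splits is rejected,
naming the class.

## Numerical choices and edge cases

* Softmax uses max-subtraction; fusion weights stay normalized for
  logits up to ±10⁴.
* NMS: class-wise greedy, IoU 0.7, confidence floor 0.25 for deployment
  `predict`; evaluation calls use a lower floor (0.05–0.10) so the PR
  curve is sampled deeply.
* Complexity audit counts parameters by exact enumeration and FLOPs as
  2 × MACs over conv layers at the stated input size (norm/activation
  cost not modeled); printed third-party FLOPs figures are not
  comparable across measurement conventions, so the audit targets exact
  internal accounting and cross-variant orderings.
* Degenerate CIoU operands are guarded by ε = 10⁻⁷ floors on widths.
* Box decode clips to the frame; zero-width boxes are discarded.

## End-to-end check sizes

The heavyweight end-to-end test trains each of the four variants
(baseline, fasff3, cspc, iema) at `width_mult 0.125` on 64 scenes
(96 px canvas, resized to 128 for training) for 200 iterations at batch
16 (≈ 50 epochs), lr 6e-3 → 6e-4, and evaluates 16 held-out scenes.
These sizes were chosen so the whole four-variant check completes in a
few minutes on one CPU core while still exercising every architectural
path; they are deliberately small and say nothing about full-scale
accuracy.

## Known limitations

* The dual small-goal/big-goal reporting convention seen in some
  published comparisons has no structural definition here; both a
  three-head and a four-head fusion variant are provided instead.
* The EMA dot-product fusion is a reconstruction (see above).
* Training is CPU-bound numpy; it is meant for verification-scale
  experiments, not production training runs.
* `mAP50-95 ≥ mAP50` can never occur, but AP at a single higher IoU
  threshold is not formally monotone under greedy matching; the
  monotonicity test is over random fixtures, not a theorem.
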