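# Methods

## The pipeline

A whole-slide image is partitioned into non-overlapping 299×299 RGB tiles
(0-based, half-open, row-major; partial edge tiles are dropped rather than
padded, so a fixed-input classifier never sees fabricated pixels).  Tiles
pass a two-stage cascade:

1. **Tumor gate.** A binary classifier scores each tile healthy vs
   cancerous.  The test-time decision is the argmax; a separate, stricter
   gate (P(cancerous) ≥ 0.95, inclusive) is used only when constructing
   the stage-2 *training* set.
2. **Mutation classifier.** Tiles called cancerous are scored WT vs EGFR.
   Because single tiles cannot be genotyped, stage-2 training tiles carry
   their slide's mutational status as a weak label; this noise is
   intrinsic to the design and bounds the tile-level performance, which is
   why the slide-level vote exists.

**Confidence and abstention.** A vote whose top-class probability does not
exceed 0.90 (strict) abstains from tile-level *metrics* — performance is
reported "considering votes with a confidence over 90 %", with abstention
counts reported separately and never imputed.  The slide-level AI-mutation
Ratio, by contrast, is a plain voting process over argmax decisions: every
tumor tile votes.  This split matters and is deliberate.  A
capacity-limited classifier trained with cross-entropy converges toward
*calibrated* probabilities, and under weak labels the achievable
confidence is capped by the label purity — with mutant-tile fractions
drawn from Beta(8,2) (mutated slides) and Beta(1,9) (WT slides) the purity
of the mutant texture class is ≈ 0.89 < 0.90, so a calibrated stage-2
model abstains on essentially *every* tile and, were abstentions removed
from the ratio too, every slide would be undetermined.  The
`CascadeConfig.abstain_excluded_from_ratio` flag exposes the stricter
behavior for experimentation.

**Slide call.** ratio = n_EGFR / (n_EGFR + n_WT), undefined when no tumor
vote exists (slide UNDETERMINED).  The slide is called EGFR when ratio ≥
0.25 (inclusive); the threshold favors mutation detection, consistent with
a sensitivity-first reading of the task.  The ratio is a proportion of
tumor tissue, not an odds n_EGFR/n_WT: reported per-slide values like 98 %
only make sense on the proportion scale.

**Group comparison.** EGFR-slide vs WT-slide ratio distributions are
compared with a two-sided Wilcoxon rank-sum test (scipy's Mann–Whitney U:
exact null when both groups have ≤ 8 observations and no cross-group ties,
normal approximation with tie correction otherwise; two identical constant
groups return p = 1 with a degenerate flag).

## Heatmaps

Cascade labels are reassembled onto the slide grid and smoothed with a 3×3
**modal** filter — the categorical analog of a median filter, and equal to
it for the binary EGFR/WT case under a 0/1 encoding (a median of unordered
categories is otherwise undefined).  Only HEALTHY/EGFR/WT cells vote or
change; ABSTAIN, BACKGROUND and EMPTY cells are inert; ties keep the
original label; borders use the truncated neighborhood.  Consequences:
smoothing never introduces a label absent from the input, and a second
pass changes no more cells than the first.  Smoothing affects rendering
only, not the ratio, by default; the order "aggregate, then visualize"
keeps the reported numbers independent of a display filter.

## Metrics

Standard binary forms: accuracy (tp+tn)/n, sensitivity tp/(tp+fn),
specificity tn/(tn+fp), F1 2tp/(2tp+fp+fn), Cohen's κ = (p_o−p_e)/(1−p_e)
with p_e from the marginals, AUC as Mann–Whitney concordance with 0.5
credit for ties (provably equal to the trapezoid area under the ROC sweep,
asserted to 1e-9 in tests).  Zero-denominator metrics are NaN with an
explicit `undefined` flag, never a silent zero.

A reconstruction note: on a 60-slide test set with per-class rates 25/34
(73.53 %) and 21/26 (80.77 %) there are exactly two integer confusion
matrices, (tp=25, fn=9, fp=5, tn=21) and its transpose-mate (tp=25, fn=5,
fp=9, tn=21).  Both yield accuracy 46/60 = 0.7667 and F1 50/64 = 0.7812,
and both yield κ = 0.5333.  A published κ of 0.5583 alongside those rates
is therefore not reproducible from any consistent matrix; the suite pins
0.5333 and treats the other figure as a reporting inconsistency.

## The surrogate backbone

No deep-learning framework is required: `SmallConvNet` is a compact CNN
written on numpy with im2col 3×3 same-padding convolutions and manual
backpropagation (the analytic gradients are checked against central finite
differences in the test suite).

- input 299×299×3 uint8 → [0,1]; fixed average pool to a ~23×23 working
  grid (the pooling factor is the divisor of the input size whose grid is
  closest to 23);
- n conv+ReLU blocks (default channels (8, 16)) at constant resolution,
  exposed as `relu_1 … relu_n` for Grad-CAM;
- global average pooling → dense → softmax pair.

Training is SGD with momentum 0.9 on binary cross-entropy, shuffled
mini-batches, optional early stopping on validation loss (patience 5,
max 50 epochs by default; the pipeline's surrogate default is lr 0.05,
batch 32, 30 epochs — sized to the synthetic textures), and layer
freezing: the first `frozen_layers` conv blocks receive no updates, the
head always trains, and freezing more layers strictly shrinks the updated
parameter set.  Runs are bit-reproducible from the seed in single-threaded
mode.  The published reference backbone (InceptionResNet-V2; 471 frozen
layers / batch 128 for the tumor stage, 1 / 64 for the mutation stage,
lr 0.001) is recorded in `REFERENCE_CONFIGS` as metadata; its weights and
multi-hour GPU trainings are out of scope, and `frozen_layers` counts in
each backbone's own enumeration order.

## Stain normalization and augmentation

Stain normalization is Reinhard mean/SD transfer in CIELAB against a
fitted reference profile (channel means/SDs of a tile population; SDs are
floored at 1e-6 for constant-color degenerates; L is clipped to [0,100]
before inversion).  It is deterministic and idempotent to within a unit of
intensity, which is what the tests assert.

The augmentation sampler draws uniformly per tile: translation ±10 px,
scale [0.5, 1.5], rotation ±90°, and — for the mutation stage only — hue
offset [0.03, 0.04], saturation offset ±0.05, brightness offset ±0.1, and
Gaussian blur with σ = 1 + U[0, 1).  The hue range is kept asymmetric as
specified even though it looks like a typo for a symmetric interval; the
"pixel range" entry is interpreted as x/y translation (it sits among the
geometric parameters).  Application order is fixed: geometric (scale and
rotate about the center, then translate; bilinear, reflective borders) →
color → blur, so outputs are reproducible from the drawn sample.

## HD-CAM explainability

Grad-CAM at a named ReLU layer: channel weights are the spatially averaged
gradients of the **pre-softmax** class logit with respect to the layer's
activations; the map is the rectified weighted activation sum, min–max
normalized (all-constant maps stay zero rather than dividing by zero) and
bilinearly upsampled to tile resolution.  HD-CAM fuses the last ten such
layers with weights w_i ∝ i (i = 1 shallowest … n deepest), normalized to
sum 1 — the simplest monotone "linear distribution" giving deeper layers
more weight; w₁₀/w₁ = 10.  The fused map is min–max normalized again;
because the fusion is convex, it is invariant to rescaling all weights.
Models with fewer than ten eligible layers use all of them with a warning.
Explanations are computed on the most confident correctly classified tiles
of each class (ties broken by grid position), i.e. under maximal model
certainty.

## Synthetic cohorts: what they emulate, and what they do not

Each synthetic slide is a grid of textured tiles with planted truth.
Textures are parametric blob/noise fields: a class base color with
Gaussian pixel noise (SD 6) plus Poisson-many darker chromatin-like blobs;
healthy tissue is pale eosin-pink with sparse blobs, the two tumor classes
are purple morphologies separated in hue and blob density.  Three centers
add fixed RGB offsets (≤ 8 units) to every tile, emulating
inter-laboratory staining heterogeneity at a magnitude well below the
class separation.  Per slide, 60 % of tiles are tumor; the mutant-tile
fraction is drawn from Beta(8,2) for EGFR slides and Beta(1,9) for WT
slides and converted to a count by round-half-up; mutant tiles are placed
uniformly at random among tumor tiles (the simplest intratumoral
heterogeneity model that exercises the 25 % threshold).  Everything is
bit-exact from the cohort seed via per-slide/per-tile seed sequences.

Oracle classifiers read the planted texture statistics —
nearest-class-centroid on mean tile color, centroids estimated from
reference renders across centers — and emit a configurable confidence, so
tests can exercise gates and abstention exactly.  With confidence 1.0 the
oracles are error-free: the end-to-end identity (per-slide ratio equals
the planted fraction exactly; slide calls equal the threshold
classification of the planted fractions) holds for 100 % of slides.

What passing on this generator shows: the *decision logic* — tiling,
gating, weak-label construction, voting, thresholds, smoothing, metrics,
explanations — is correct and reproducible.  What it does not show:
performance on real H&E, where class textures are not linearly separable,
stain variation is structured rather than additive, tissue boundaries
cross tiles, and mutant morphology is far subtler.  The default study
size (60 evaluation slides of 5×5 tiles, 16 disjoint training slides, 200
ROI-style stage-1 training tiles) is chosen so a full end-to-end run takes
about a minute on one CPU while keeping ≥ 1 500 evaluated tiles.

A note on expected slide accuracy: with a fixed 25 % threshold, WT slides
whose drawn fraction lands at or above 0.25 (probability ≈ 0.09 under
Beta(1,9) at 15 tumor tiles/slide) are *inherently* misclassified even by
a perfect tile classifier.  Across seeds, the trained surrogate's
slide-level accuracy on the default cohort is ≈ 0.88–0.97 and, in every
seed inspected, every error was of this inherent kind — the measured ratio
equaled the planted fraction.  The same sensitivity-first trade-off is why
a real deployment of this design reports specificity below sensitivity at
slide level.

## Numerical and degenerate-case choices

- Gates: stage-2 inclusion ≥ 0.95 inclusive ("at least"), vote confidence
  > 0.90 strict ("over"); both live in `PipelineConfig`/`CascadeConfig`
  defaults, never in stage logic.
- Ratio threshold comparison is inclusive (≥ 0.25 → EGFR).
- Slides with no tumor votes are UNDETERMINED and excluded from slide
  metrics (counted separately).
- All stage seeds derive from one global seed through salted
  `SeedSequence`s; no unseeded randomness anywhere.
- Background masking (HSV saturation < 0.08 on > 90 % of pixels) is off
  when ROIs are supplied and only used for whole-slide runs.
- Tile-manifest, vote-table and slide-summary artifacts are TSV; profiles
  and reports are JSON; heatmaps are PNG with a JSON palette sidecar.

## Known limitations

- The surrogate CNN's global-average-pool bottleneck cannot memorize
  conflicting weak labels, so its probabilities stay near-calibrated;
  overparameterized backbones in production behave differently
  (overconfidently), which is partly why the >90 % filter is viable there.
- Single-resolution tiling only; no pyramid levels, no magnification
  conversion, no scanner metadata.
- Binary mutation calls only (EGFR vs WT); no mutation subtypes.
- Reinhard normalization is global per tile; structured stain variation
  (e.g. per-structure dye uptake) is not modeled — a Macenko-style
  deconvolution can be plugged in behind the same profile interface.
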