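# Methods

This package implements a lightweight DeepLabv3+-family encoder–decoder for
semantic food segmentation (the ILW-DeepLabv3+ design: EfficientNet-B1
backbone, cascaded-waterfall atrous pooling, squeeze-and-excitation head),
together with its training recipe, per-image mIoU evaluation, an exact
parameter/MAC profiler, conformal-prediction uncertainty maps, and mask-based
nutrient estimation. Everything runs in NumPy: the layer library under
`ilwdeeplab.nn` provides forward and backward passes for the convolution,
normalisation, activation, pooling and resizing primitives the architecture
uses, plus SGD with momentum. No GPU or deep-learning framework is required.

## Architecture

**Backbone.** EfficientNet-B1: the B0 stage table compound-scaled by depth
1.1 (stage repeats [2,3,3,4,4,5,2]; widths 16/24/40/80/112/192/320), SiLU
activations, and mobile inverted bottleneck blocks — pointwise expansion
(ratio 6), depthwise 3×3/5×5, a squeeze-and-excitation gate whose squeeze
width is a quarter of the *block input* channels, pointwise projection, and a
residual connection where shapes allow. Two taps feed the decoder: the
24-channel stage-2 output at stride 4 and the 320-channel final stage at
stride 16 (the stage that would reach stride 32 runs with unit stride and
dilation 2 — the standard dense-prediction adaptation). Batch normalisation
uses the EfficientNet epsilon (1e-3) but running-statistics momentum 0.1
rather than the reference 0.01: at the training lengths this package targets
(tens of iterations) 0.01 leaves inference statistics close to their
initialisation and evaluation-mode predictions collapse to the background
class, while 0.1 tracks the batch statistics almost completely. Neither
choice affects any complexity figure.

The classification variant of EfficientNet-B1 ends in a 1280-channel
pointwise projection that a segmentation graph never executes. The backbone
nevertheless *retains* those weights (`BackboneSpec.include_vestigial_head`,
default on) because the reference complexity totals this package reproduces
were evidently computed on a model object that still held them; see
"Profiler calibration" below. They contribute 412,160 parameters and zero
MACs.

**Neck.** Two interchangeable context modules over the 320-channel stride-16
map, both projecting to 256 channels:

* `aspp`: the parallel baseline — a 1×1 branch, three separable 3×3 atrous
  branches at rates (12, 24, 36), and an image-pooling branch, concatenated
  and fused by a 1×1 convolution (each branch batch-normalised).
* `cwaspp` (default): the cascaded waterfall — a 1×1 reduction 320→48, then
  three separable 3×3 atrous convolutions 48→48 at the small progressive
  rates (2, 4, 6), *each consuming its predecessor's output*, plus an
  image-pooling branch 320→52; the reduced input, the three stage outputs
  and the pool branch (244 channels) are concatenated and fused by a 1×1
  convolution with bias + batch norm + ReLU. Small progressive rates avoid
  the gridding artifact of large dilations; the sequential wiring reuses
  each stage's features and cuts the module to 103,440 parameters versus the
  parallel module's 748,992.

  The channel widths (48/48/52) are **calibration constants**: the waterfall
  module's internals are not published, and this configuration is the one
  whose assembled totals reproduce the published parameter counts exactly
  (see below). The pool width 52 in particular is a numerical artifact of
  that calibration, not a design aesthetic.

**Head attention.** Applied to the 256-channel neck output, before the
trailing separable refinement. The registry carries seven mechanisms with
hard parameter contracts asserted at construction: none (0), SE (8,192 —
bias-free two-layer bottleneck, reduction 16), CBAM (8,290 — shared SE-style
MLP plus a 7×7 spatial gate on the 2-channel pooled map), ECA (5 — a 1-D
convolution of kernel 5 across pooled channels), GAM (32,870 — a per-pixel
channel MLP of reduction 4 plus a 102-parameter spatial gate), SimAM (0 —
parameter-free energy gating, stabiliser λ = 1e-4), and TAM (200 — two
rotated triplet-attention branches of 100 parameters each). The published
increment table does not determine every mechanism's internals uniquely; the
GAM decomposition (32,768 channel + 102 spatial) and the two-branch TAM are
the minimal standard variants that reproduce the printed increments, and are
documented as such. Only SE (the mechanism the final model adopts) and
"none" implement a backward pass; the others exist for evaluation and
complexity comparison.

**Decoder.** Separable 3×3 refinement of the attended features (+BN+ReLU),
bilinear ×4 upsampling, concatenation with the 1×1-reduced low-level map
(24→48 channels), separable 3×3 fusion to 256 channels, a 1×1 classifier
with bias to K classes, and a final bilinear ×4 upsampling back to input
resolution. Ties in the per-pixel argmax break toward the smaller class id.

## Profiler calibration

Parameters are counted as the sum over allocated trainable tensors and are
convention-free. Published MAC totals never are: they depend on which
operations the counting tool sees. The profiler therefore freezes two
conventions:

* `published` — reproduces the reference totals for this architecture
  family. Per-op rules: convolution `out_elements · (cin/groups) · k²`;
  batch norm `4 · elements`; bilinear resize `11 · out_elements`;
  module-level global pooling `(window+1) · out_elements`; biases,
  activations and elementwise gating free. Inside the backbone only the
  batch-norm terms count. That last rule is a calibration *finding*, not a
  preference: the reference baseline total (3.14G for the parallel-pooling
  assembly at 512²) is reproducible only if the backbone's convolutions are
  excluded, which is exactly what a module-hook profiler does when the
  backbone implementation wraps its convolutions in a custom same-padding
  subclass the hook table does not match. The per-class MAC slope between
  the published totals at 103/74/11 classes (≈7.08M per class =
  `256·128² + 11·512²`) independently pins the classifier resolution and
  the bilinear-11 rule.
* `full` — every executed operation under the same per-op rules; the
  physically meaningful cost (8.40G for the lightweight model at 512²).

With these conventions and the calibrated architecture, the package
reproduces: 6,793,767 parameters (exact) and all attention deltas (exact);
6.80M / 2.54G for the full model at 103 classes; 6.79M / 2.34G at 74; 1.89G
at 11 (parameters compute to 6.78M where 6.77M is printed — the reference
rounding is internally inconsistent at that entry); 7,439,319 ≈ 7.44M and
3.14G for the parallel-pooling baseline. One figure is irreducibly off:
the lightweight model's MAC total computes to 2541.91M against a printed
2541.89M (+0.0009%). An exhaustive search over waterfall-module families
(uniform and non-uniform widths, plain and separable stages, pooling and
normalisation placements) shows no 103,440-parameter stride-16 neck can
cost less than ≈105.9M MACs under any hook-style convention, while the
printed total leaves only ≈89.5M of budget — the printed parameter/MAC pair
cannot both be exact for one model. The exact parameter count was
prioritised.

## Training recipe

Cross-entropy over all pixels (no ignore index — the synthetic and target
datasets are fully labelled), SGD with momentum 0.9 and weight decay 1e-4,
batch size 8, and a polynomial learning-rate decay applied after every
iteration: `lr(t) = base_lr · (1 − t/T)^0.9`, reaching exactly zero when
training completes. Default base learning rate 0.05 (the small-dataset
setting of the recipe). Inputs are resized to a square side (bilinear for
images, nearest-neighbour for label maps — bilinear would invent fractional
class ids), scaled to [0, 1], and randomly flipped horizontally with
probability 1/2 during training; one seeded generator drives initialisation,
shuffling and flips, so runs are bit-reproducible on one device. Stochastic
depth and dropout are omitted (they matter at 100-epoch GPU scale, not at
the desk scale this package targets; parameters and MACs are unaffected).
He-normal initialisation for convolutions; batch-norm scale 1, shift 0.

**Desk-scale study conditions.** The training smoke test runs 16 synthetic
3-class scenes at input side 128 for 30 epochs (60 iterations) with base
learning rate 0.05, seed 0 — about 2.5 minutes on one CPU — and requires
train-set mIoU above 0.5, above the all-background predictor (≈0.40). The
shipped run reaches ≈0.82. Problem sizes throughout the test-suite are
chosen at this desk scale; benchmark-scale mIoU values require external
datasets and GPU-length training and are out of scope.

## Evaluation metric

Per image i and class k, `IoU = |y ∩ ŷ| / |y ∪ ŷ|`; classes with an empty
union in an image are excluded from that image's average (default), or
counted as 1 or 0 via `empty_union=` for comparability with other
codebases. Image scores are averaged over images. The background class
participates in the class average.

## Conformal uncertainty

The softmax stack is thresholded at λ̂ (default 0.01, the empirical
reference setting): a pixel keeps every class scoring above λ̂, giving a
multi-label mask Ẑ, per-pixel label counts NL, and the uncertainty stack
V = ẑ/NL ∈ [0,1] which sums to one over classes wherever NL > 0. The scalar
heatmap is u = 1 − 1/NL (0 for a confident single label); pixels with an
empty selection — impossible at λ̂ = 0.01 since softmax scores sum to 1, but
reachable at large thresholds — take V = 0 and u = 1 by convention.
`calibrate_lambda` returns the *largest* threshold on a 100-point log grid
over [1e-4, 0.5] whose selections cover at least the requested fraction of
calibration-pixel true labels (tightest sets at the requested coverage).

## Synthetic scenes

Each scene is a dark table with a bright circular plate and 1–3 elliptical
food items, one saturated base colour per class plus Gaussian pixel noise
(σ=9 intensity levels); later items occlude earlier ones; class identities
follow a long-tailed 1/rank frequency profile. Scenes are bit-reproducible
from (seed, index). What this emulates: colour/texture-separable food
classes, class imbalance, occlusion, plate/background separation. What it
does not: deformable shapes, inter-class visual similarity, lighting
variation, volume. Passing the synthetic suite therefore demonstrates that
the pipeline optimises, evaluates and calibrates correctly — not that the
architecture reaches any particular accuracy on real dishes.

## Nutrient estimation

From a label map: (1) the smallest circle enclosing all non-background
pixels, radius inflated 5%, stands in for the plate (deterministic and
computable from the mask alone); (2) each food's pixel count inside the
circle over the circle's pixel count gives an area fraction; (3) grams =
fraction × the food's reference full-plate serving weight, and energy/
protein/carbohydrate follow from per-100 g composition values. The chain is
linear in area, so estimate differences between two masks of the same scene
are bounded by their per-class area disagreement. Volume, stacking and
occlusion are deliberately not modelled; foods missing from the composition
table are flagged unknown and excluded from totals with a warning.

## Numerical choices and degenerate inputs

float32 throughout the network; softmax and cross-entropy are max-shifted;
the cross-entropy clamps probabilities at 1e-12 before the log. Bilinear
resizing uses half-pixel centres (corner alignment off) implemented as dense
1-D blend matrices, making the backward pass an exact transpose. The
smallest-enclosing-circle routine is the randomised incremental
construction, applied to convex-hull vertices when a mask has more than
2000 food pixels. All-background masks, empty manifests, empty calibration
sets, non-finite losses and invalid class ids raise immediately with
diagnostic messages.

## Known limitations

* Training-grade backward passes exist for the SE and no-attention heads
  only; CBAM/ECA/GAM/SimAM/TAM are evaluation- and profiling-only.
* Single-device reproducibility only; no parallel or mixed-precision paths.
* The published-convention MAC count is a reproduction of a hook-style
  tool's view (backbone convolutions unseen); use `convention="full"` for
  the physical cost.
* The waterfall-neck widths are calibrated constants, not a claim about the
  original implementation's internals.
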