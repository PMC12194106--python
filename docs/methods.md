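# Methods

## The model

`catransunet` implements a cross-attention TransU-Net: a four-stage
encoder–decoder for binary pest segmentation of RGB field images, built
from three components that each target one failure mode of plain U-Nets on
field pest imagery.

**Residual dilated Inception (RDI) encoder.** Each encoder stage runs four
parallel 3×3 convolutions with dilation rates 1, 3, 5, 7 (effective
extents 3, 7, 11, 15 pixels), each followed by batch normalization. The
branches are concatenated, fused by a 1×1 convolution + BN, a
1×1-projected residual of the stage input is added, and ReLU applied. The
multi-rate branches give every stage simultaneous access to fine texture
(tiny pests, thin appendages) and large context (large pests, body
outlines) without extra parameters. Each stage is followed by 2×2
max-pooling; four stages reduce a 256×256 input to 16×16.

**Dual Transformer-attention (DTA) bottleneck.** The deepest (pooled
stage-4) features `F ∈ R^{c×h×w}` pass through two parallel attention
paths over the n = h·w positions:

* *TSA* — scaled dot-product self-attention. 1×1 convolutions produce
  Q, K, V; the map `softmax(QᵀK / √d_k)` (row-wise over positions,
  d_k = per-head channel width) re-weights V. Head count is configurable
  (default 1, matching the single-head formulation).
* *GSA* — global position attention. A 1×1 convolution reduces channels
  to c′ = c/8; the reduced map, reshaped to (n × c′) and (c′ × n), forms
  logits whose row softmax is an n×n position-affinity map that
  aggregates a full-width 1×1-projected value branch.

The fused output is `γ₁·TSA(F) + γ₂·GSA(F) + F` with both scalar gates
**learned and initialized to exactly zero**, so the untrained bottleneck
is a bitwise identity and attention is blended in only as training finds
it useful. A consequence worth knowing: at γ = 0 the attention projections
receive exactly zero gradient on the first step; they begin to move once
the gates do. The gates themselves always receive gradient.

**Cross-attention skip connections (CASC).** Each decoder stage is fused
with the same-resolution encoder map. Both maps are first channel-gated
(spatial mean → bias-free linear map → sigmoid, multiplied per channel);
the encoder map then provides K and V and the decoder map Q for a
cross-attention `softmax(QᵀK/√c)·V` over positions; the attended encoder
map is concatenated with the decoder map and projected back to the stage
width (1×1 conv + BN + ReLU).

**Decoder and head.** Each decoder block applies two 3×3 convolutions
(Conv→BN→ReLU) with a residual across the pair (1×1-projected when widths
differ), then doubles resolution with a 2×2 stride-2 transposed
convolution (a nearest-neighbour + 1×1 alternative is available via
`upsample: nearest`). A 1×1 convolution + sigmoid yields the per-pixel
pest probability.

## Design choices where the design was open

* **Printed formula readings.** Three of the published formulas do not
  parse literally and were implemented in their only self-consistent
  reading: the attention normalizer is √d_k (a literal /d_k switch is kept
  as `attn_scale: linear`); the position-map softmax is row-wise (a
  whole-matrix normalization would contradict the map's stated meaning as
  per-row weights); and the DTA fusion adds the TSA output (the printed
  recurrence is self-referential). The loss is the standard *negative*
  mean BCE with `log(1−σ)`; the printed sign/nesting cannot be minimized
  meaningfully.
* **Bottleneck wiring.** Only the deepest stage feeds the bottleneck; the
  four pre-pooling stage outputs feed the skips. This is the standard
  U-Net topology and the only wiring consistent with the block diagram.
* **Channel gating target.** Channel selection is applied to both skip
  inputs (encoder before K/V, decoder before Q), covering both readings of
  "the key channel of K and Q".
* **CASC pooled grid.** Full-resolution position attention at the stage-1
  skip (n = 65 536) needs an n×n map — infeasible. K/Q/V are computed on
  an average-pooled grid of at most 32×32 (`casc_grid`), and the attended
  map is up-sampled (nearest) back before concatenation. This is an
  engineering necessity, not part of the published design.
* **Stage widths.** The published description fixes no widths; the only
  quantitative capacity constraints are 14.6 M parameters and 18.9 GFLOPs
  at 256×256. Defaults were calibrated once against both and frozen:
  `stage_widths [16, 48, 120, 576]`, `bottleneck_width 640` → 14 594 235
  parameters (14.6 M) and 18.6 GFLOPs. The family is deliberately slim at
  shallow stages (FLOPs are dominated by high-resolution convolutions) and
  wide at depth (parameters are dominated by the deep stages). When
  `bottleneck_width ≠ stage_widths[3]` a 1×1 conv + BN + ReLU adapter maps
  into the bottleneck.
* **Ablation variant semantics.** The ablation grid names rows, not
  definitions. Here: `inception` = rate-1 branches without residual,
  `dilated_inception` = dilated branches without residual, `plain_conv` =
  two 3×3 conv+BN+ReLU; `ASPP` = four dilated 3×3 branches (rates 1,3,5,7)
  with 1×1 fusion at the bottleneck width; `TSA_only`/`GSA_only` keep the
  zero-initialized gated-residual form with a single gate. "--" cells mean
  the plain U-Net component (plain stages / no bottleneck / plain
  concatenation skip).

## Training protocol

Adam (lr 1e-3, weight decay 1e-4 as classic L2 on gradients, β₁ 0.9,
β₂ 0.999), mini-batch 32, 3000 iterations (mini-batch steps), Kaiming
normal initialization of all convolutions (seeded, reproducible), loss =
mean binary cross-entropy on pre-sigmoid scores in stable softplus form.
"Balanced" weighting is off by default; `pos_weight` may be a float or
`"auto"` (per-batch background/foreground ratio) — with foreground
fractions of a few percent, `"auto"` is what makes small-pest training
move. Validation (a seeded 10% split of the training data;
`val_fraction 0` monitors the training loss instead) is evaluated every
`val_interval = 50` iterations; after `plateau_patience = 4` evaluations
(200 iterations) without improvement the learning rate is multiplied by
0.1. Five-fold cross-validation splitting is a seeded permutation cut into
five nearly equal folds.

## Numerical infrastructure

The network runs on a compact NumPy reverse-mode autodiff engine
(`catransunet.autodiff`): convolution (im2col, with dilation/stride), 2×2
transposed convolution, max/average pooling, nearest up-sampling, batch
normalization (batch statistics in training, running in evaluation,
momentum 0.1, ε 1e-5), softmax, sigmoid, matrix products and a stabilized
BCE-with-logits — every primitive's backward pass is verified against
central finite differences in the test suite. FLOP accounting is measured
by instrumenting the same primitives during an evaluation forward pass:
convolutions and matrix products count 2 FLOPs per multiply-accumulate
(bias adds not counted separately), batch norm 2/element, ReLU 1/element,
sigmoid 4/element, softmax 5/entry, pooling 1/element. Computation is
float32; oracle tests use float64.

## Synthetic scenes

The generator emulates the properties that make field pest imagery hard,
with exact masks (the mask is the rasterized shape set — there is no
annotation noise):

* backgrounds: multi-octave value noise plus warped oriented sinusoidal
  stripe fields (leaf blades/veins), in three styles (`leaf_stripes`,
  `soil_texture`, `clutter`); parameters are plausible, not measured from
  real fields;
* pests: oriented ellipse-based bodies in three shape families mapped
  from the class id (capsule / segmented chain / winged), semi-major axis
  = `scale`·canvas/2 with `scale` drawn from `pest_scale_range`
  (default 0.01–0.25 of a 640 canvas, i.e. a few pixels to a quarter of
  the frame), aspect 1.5–4, with 2–8 thin bent polyline appendages;
* low-contrast mode places pest luminance within ±10% of the local
  background; occlusion (probability 0.2) erases a band of the pest from
  both image and mask;
* preprocessing mirrors the target pipeline: random 640×640 crop, resize
  to 256×256, nearest-neighbour for the mask so it stays binary;
  augmentation applies flips/rotations (area-exact) and brightness jitter
  and can emit 14 distinct provenance-tagged variants per source for
  class balancing.

What passing tests on these scenes shows: the architecture can be
optimized end-to-end to segment small, thin-appendaged, low-contrast
shapes on cluttered textures, and the whole pipeline is deterministic and
correct. What it does not show: performance on real field photographs —
real pest appearance, lighting, annotation ambiguity and domain shift are
not modelled. Benchmark accuracies on real datasets are out of scope here.

## Problem sizes used in the checks

The capacity figures are computed at the full default configuration
(14.6 M parameters, 256×256 input). Structural and learning tests use slim
width families (e.g. [8, 16, 24, 32] at 64×64; [8, 16, 32, 64] at
128×128 for the eight-scene overfit check) — a package-level choice that
keeps the suite fast on one CPU while exercising identical code paths.
The overfit check trains on eight 128×128 scenes for 300 iterations with
full-batch Adam and a fixed foreground weight of 5 (with foreground
fractions of a few percent, a moderate weight gives tighter boundaries
than the full background/foreground ratio, which inflates probabilities
into a halo around small bodies) and requires training-set Dice ≥ 0.95 at
threshold 0.5.

## Known limitations

* Attention memory is quadratic in grid positions; the pooled-grid CASC
  cap (32×32) bounds it, at the cost of coarser cross-attention at shallow
  stages.
* The autodiff engine caches im2col buffers for backward; training memory
  is dominated by these (a reason the desk-scale tests use slim widths).
* Batch norm couples samples in training mode; evaluation mode is fully
  deterministic per sample.
* `five_fold_split` splits samples, not pest instances; with very small
  datasets folds can differ in class composition.
* No pretrained weights, mixed precision, or GPU path.
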