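# Methods

## Architecture family

All three model variants share one encoder: a stem of two 3×3 conv blocks
(stride 1 then stride 2), followed by three stages of a BottleneckCSP block
and a stride-2 conv block, giving total downsampling ×16. A conv block is
convolution → batch norm → LeakyReLU (slope 0.1); convolutions followed by
batch norm carry no bias; 3×3 convolutions use padding 1 (dilated ones use
padding = dilation), so spatial sizes are preserved exactly and stride 2
halves even sizes exactly. Inputs must be divisible by 16.

**BottleneckCSP.** The input is projected by two parallel 1×1 convolutions
to half the output width. One path runs `repeats` residual bottlenecks
(1×1 conv, 3×3 conv, additive identity skip — the feature-summation path);
the other is the plain cross-stage shortcut (a raw 1×1 conv with bias). The
two halves are concatenated, batch-normalised, activated, and fused by a
final 1×1 conv block.

**Decoder (branch II).** Four modules, one ASPP each. The deepest module
applies ASPP directly to the encoder output at H/16 — the only feature
available at that resolution — then upsamples; the three shallower modules
first concatenate the matching encoder CSP output (skips at H/8, H/4, H/2),
then ASPP, then upsample. ASPP runs a 1×1 branch plus one 3×3 dilated
branch per rate (6, 12, 18) at a configurable branch width and fuses by 1×1
projection. Upsampling is bilinear ×2 with half-pixel centres (no corner
alignment) followed by a conv block. A final 3×3 conv (bias, no norm) and a
sigmoid produce the vessel probability map; maps are binarized at 0.5, with
probabilities exactly at the threshold counted as vessel.

**Classification head (branch I).** One stride-2 conv block (to H/32), a
stack of 3×3 conv blocks, global average pooling, and a fully connected
layer to 5 logits under softmax. Global pooling before the FC layer keeps
the head's parameter count in the stated budget; flattening a 32×32 map
would not. Softmax (not per-class sigmoid) is used for the grade
probabilities, so they always sum to 1.

Weights are initialized Kaiming-fan-in from an explicit seeded generator;
every build is bit-reproducible from its seed.

## Calibration of the default channel schedule

Stage widths, CSP repeat counts, ASPP branch widths and head widths are not
uniquely determined by the architecture description, so the defaults were
fixed by calibration against the published complexity budgets using the
package's own accountant: encoder 9.1 M parameters / 22.4 GMACs at 512×512,
decoder 6.0 M / 23.6 G, head 9.7 M / 2.5 G (totals 15.1/18.8/24.8 M and
46.0/24.9/48.5 G). The calibrated schedule is widths (48, 160, 512, 1370),
repeats (1, 1, 2), ASPP branch widths (64, 118, 24, 12) with outputs
(512, 160, 64, 16), upsample outputs (160, 96, 32, 8), and head widths
(192, 384, 1924). The uneven numbers are a consequence of hitting six
rounded budget constraints simultaneously; nothing in the implementation
requires power-of-two channel counts.

One published figure cannot be reproduced by any fully convolutional
network in this family: a model with 46.0 GMACs at 512×512 necessarily has
46.0/4 = 11.5 GMACs at 256×256 (every layer's cost scales with output
pixels), whereas the size-comparison table prints 12.1. The accountant
reports 11.5; the discrepancy is inherent to the printed pair, not a
counting choice.

## Complexity accounting conventions

Parameters: k²·Cin·Cout per conv (+Cout bias if no batch norm follows,
+2·Cout batch-norm scalars otherwise), Nin·Nout+Nout per FC layer. MACs:
k²·Cin·Cout·Hout·Wout per conv, Nin·Nout per FC; batch norm (inference-
folded), activations, bilinear interpolation, pooling and softmax are
zero-MAC. "GFLOPs" is reported as giga-MACs (1 MAC = 1 reported FLOP), the
dominant profiler convention; a single flag (`flops_per_mac=2`) flips the
convention globally if a doubled count is wanted. "Parameters (M)" means
millions of scalars, not megabytes. All sums are exact integers; division
by 1e6/1e9 happens only in the report. The accountant never builds a
network — it expands the declarative spec — and the test suite asserts
exact agreement with a brute-force enumeration of every weight array of the
instantiated networks, at both tiny and calibrated widths.

## Losses

Segmentation: mean per-pixel binary cross-entropy on the sigmoid output
plus soft Dice `1 − (2Σpy+s)/(Σp+Σy+s)` with smoothing s = 1 (both terms
differentiable; Dice is computed on probabilities, not binarized maps).
Probabilities are clipped to [1e-7, 1−1e-7] before logarithms and the clip
zeroes the gradient there. Binary rather than two-class-softmax
cross-entropy matches the sigmoid + 0.5-threshold inference path. With deep
supervision the vessel loss generalises to Σ λk(L_ce^k + L_dice^k); the
default is a single output with λ = 1, reducing exactly to L_ce + L_dice —
no deep-supervision weights are prescribed anywhere, so multi-output
support exists but is off by default. Grading: −log p_label over the 5
softmax probabilities. Joint: the plain sum of the grading and vessel
terms, logged per step as (dr_ce, vessel, total).

## Metrics

Accuracy, IoU, Precision, Recall, F1 from pooled TP/FP/TN/FN pixel counts.
Dataset-level values pool counts over all images before applying the
formulas; this preserves count additivity and the identity
F1 = 2·IoU/(1+IoU), and matches reporting a single number per dataset.
Per-image averaging is available behind a flag. 0/0 ratios (empty
prediction and empty truth) return 0 and are flagged, keeping pooled
evaluation total. Field-of-view masks are not applied unless supplied —
every pixel counts. Grading is exact-match accuracy over grades 0–4.

## Training protocol

Adam (β = 0.9/0.999, ε = 1e-8, no weight decay) with cosine annealing
lr(t) = lr_min + ½(lr_max − lr_min)(1 + cos πt) from 1e-3 to 2e-7, stepped
per epoch over 60 epochs (defaults), batch size 4. The protocol:

1. **Stage 1** — branch I and the shared encoder train on retinopathy data
   (no parameters frozen).
2. **Stage 2** — branch II and the shared encoder train on vessel data;
   branch I untouched.
3. **Stage 3** — joint training: each optimizer step draws one retinopathy
   batch then one vessel batch (strict alternation, retinopathy first),
   computes both losses and backpropagates their sum once; when dataset
   sizes differ the smaller one cycles with reshuffling.
4. **Fine-tune** — the shared encoder is frozen (asserted bitwise on
   trainable parameters; batch-norm batch statistics still update, as is
   standard when only parameters are fixed) and both branches train; the
   three parameter groups are then merged into a single checkpoint.

After every epoch the monitored loss is evaluated and the minimum-loss
state kept, ties to the earliest epoch. By default the monitor split is
whatever dataset the caller passes as `monitor_data` (a held-out split is
recommended); passing the test split reproduces test-set-monitored
selection verbatim, which leaks test data into model selection and is
therefore not encouraged. Checkpoints store per-group weights *and*
batch-norm running statistics plus the model spec, stage id and seed —
restoring parameters without normalisation statistics produces garbage
evaluation, so both travel together.

Determinism: all shuffling and initialization flows through seeded
`numpy.random.Generator` streams keyed by (seed, stage, epoch); two runs
with the same seed and data produce bitwise-identical weights.

## Synthetic data

`generate_vessel_pair` draws a bright circular fundus field (≈185/255, mild
radial falloff) on a dark surround (≈35), grows a recursive binary
branching tree from near the disc centre — random-walk curvature, segment
width multiplied by 0.8 at each branch, depth 5, initial width 4 px — and
darkens the rasterized tree by 75 intensity units; the mask is the exact
pre-noise rasterization, and Gaussian pixel noise (σ = 5) is added to the
image only. `generate_dr_image` adds Poisson-count dark dots
(microaneurysm-like) and bright blobs (exudate-like) with per-grade mean
rates (0, 4, 9, 16, 28) — nondecreasing in grade. Grade composition of
generated datasets follows the published 1805:370:999:193:295 class
imbalance by largest-remainder apportionment. Every sample is a pure
function of (seed, kind, grade, index); regeneration is byte-identical.

What the generator does *not* emulate: optic disc and macula, vessel
tortuosity statistics, inter-image illumination and camera variation,
lesion morphology beyond dots/blobs, and label noise. Passing tests on this
data therefore demonstrate that the pipeline's mechanics (losses,
gradients, staging, checkpointing, metrics) are correct and that the
networks can learn cleanly separable structure — not clinical-grade
performance on real fundus photographs. Contrast and rates were chosen
once so that tiny CPU models learn the tasks in minutes; the generator is a
test instrument, not a clinical simulator.

## Scaled-down experiment sizes

The desk-scale experiments use the tiny schedule — encoder widths
(4, 8, 16, 32), single CSP repeats, ASPP branches of 8 — on 128×128 images:
20 vessel pairs and 50 graded images, batch 4, with lr_max 2e-3 (narrow
networks tolerate and benefit from larger steps than the full-width
default 1e-3; the full-scale defaults are unchanged). Stage budgets are
16/40/6/4 epochs; the whole 4-stage protocol runs in roughly six minutes on
one CPU. Under these conditions the joint model's vessel IoU and grading
accuracy match or exceed the single-task counterparts (e.g. IoU 0.85 vs
0.80, accuracy 1.00 vs 0.96 at seed 0, evaluated on the training pool) —
a no-catastrophic-interference check, not a claim about real-data
multi-task gains.

## Numerical choices and degenerate inputs

* Probability clipping 1e-7; Dice smoothing 1.0; batch-norm ε 1e-5,
  momentum 0.1.
* Ties at the binarization threshold map to vessel (≥, fixed for
  bit-exact tests).
* Best-checkpoint ties keep the earliest epoch (strict-improvement rule).
* Masks on disk are 0/255; in memory {0,1} via the >127 rule; loaders are
  pure functions of file content.
* Train split size is floor(n·fraction): 3662 at 0.8 gives 2929/733.
* The autodiff backend computes convolution via strided im2col views and
  tensordot; bilinear resampling is expressed as separable interpolation
  matrices, making its transpose (the gradient) exact.

## Known limitations

* No GPU path; the numpy backend is practical at tiny widths and
  ≤ 256×256 inputs, and the calibrated full-width networks are instantiated
  for counting and smoke-tested, not trained here.
* Per-figure layer counts of the original block diagrams are not readable
  at publication resolution; the blocks follow the textual description plus
  standard CSP/ASPP practice, and the channel schedule is pinned by the
  complexity budgets instead.
* The 256×256 GFLOPs figure discussed under *Calibration* is not
  reproducible by construction.
* Whether grade probabilities pass through softmax or sigmoid is described
  inconsistently in the source description; softmax was chosen (5-way
  exclusive grades), making the probability simplex exact.
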