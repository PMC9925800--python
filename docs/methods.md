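# Methods

This note documents the models, algorithms and design choices behind
`camagree`: what the synthetic data emulate, how the CAM methods are
defined, how agreement is scored, and where the genuinely open decisions
were resolved.

## Problem setting

A binary image classifier is trained to tell *fresh* tissue slices (y=0)
from *damaged* ones (y=1), where damage is a spatially smooth texture
transformation without a crisp boundary.  Class-activation maps extracted
from the trained classifier are thresholded into damage masks, and the
package quantifies (i) how well those masks recover a reference
segmentation, (ii) how strongly they agree *across CAM methods* for a
fixed model and *across models* for a fixed method, and (iii) whether the
implied per-sample damage burden tracks an external scalar damage proxy
(liquid loss).

## Synthetic data generator

Each sample is an elliptical "fillet" cross-section (random centre jitter,
semi-axes 0.26--0.42 of the image side, random orientation) on a dark
background (intensity 0.04), imaged as a stack of slices.  Tissue texture
is a Gaussian random field (correlation length 3 px, amplitude 0.06)
around a base intensity of 0.55.  Intensities are floats in [0, 1]; an
optional 12-bit quantisation (4096 levels) emulates scanner bit depth.

**Damage field.**  Per slice, a smooth standardised Gaussian random field
(correlation length `damage_field_smoothness`, default 8 px) is min-max
mapped to [0, 1] and multiplied by a radial kernel
`exp(-center_bias * (rho/0.7)^2)` of the elliptical radius `rho`, making
damage concentrate toward the slice centre -- the physically expected
pattern for freeze damage, where the sample interior spends longest in
phase transition.  `center_bias = 0` disables the bias.

**Mask and perturbation.**  Treatment severity is a scalar in [0, 1]
(defaults 0.9/0.5/0.1 for the three groups of 11/11/10 samples, emulating
slow, intermediate and fast freezing).  Each sample draws one damage
*extent* = severity x U(0.20, 0.55) (fraction of foreground); each slice
realises that extent with 10% multiplicative Gaussian jitter, and its
ground-truth mask keeps the top area-quantile of the damage field inside
the foreground.  Two consequences are deliberate: every damaged slice of a
treated sample carries signal (freeze--thaw studies report near-perfect
class separability even for the mildest treatment), and samples within a
group differ in damage burden, which is what makes a liquid-loss
correlation measurable at all.  The image perturbation is
`clean * (1 + 0.3*sev*E) + sev*E*(0.40 + 0.20*blotch)` where `E` is the
damage-field excess above the mask threshold, rescaled to [0, 1]: it is
exactly zero at the mask boundary (the boundary is soft by construction)
and confined to the mask.  Severity 0 produces an empty mask and an image
identical to the fresh one up to acquisition noise (Gaussian, sd 0.01,
applied independently to both members of a pair).  Fresh and damaged
slices share the base texture, so sample identity carries no class signal.

**Liquid loss.**  Per sample, `LL% = base + slope * damage_fraction +
N(0, sd)` clipped to [0, 100], defaults base 2%, slope 20, sd 1.5 -- at
the default severities this yields roughly 2--13% loss, the realistic
drip-loss range, ordered by freezing severity.  With sd = 0 the coupling
is exactly affine; the arithmetic form `100*(m0-mL)/m0` for measured
masses is also provided.

**What the generator does not emulate:** MRI signal physics, 3-D freezing
fronts, vacuum-pack artifacts, partial-volume effects, inter-scan motion.
Passing tests therefore demonstrate correctness of the *method stack* and
behaviour under controlled soft-boundary conditions, not performance on
clinical MRI.

## Preprocessing

Background masking: convert to 8-bit, 3x3 max filter, 3x3 grey erosion,
Gaussian blur (sigma 0.5, sized for 64--128 px images; scale it with
resolution), then 1-D k-means (k=2) on intensities with deterministic
initialisation at the intensity extremes; the cluster with the higher mean
is foreground.  A constant image raises a degenerate-clustering error.
Augmentation emits independent copies per transform (rotation in +/-45°,
horizontal/vertical flips, shifts up to 20% with zero fill, contrast
stretching at the 2--98 percentiles, histogram equalisation, CLAHE); the
order-of-composition question is resolved as independent copies.
Splitting assigns whole samples to train/val/test (largest-remainder
counts honouring 80/10/10, every positive-fraction partition non-empty),
so no sample's slices straddle partitions.

## Classifier backend

A reverse-mode autodiff tape over numpy arrays (float32 or float64)
implements convolution (im2col), ReLU, 2x2 max-pooling, batch
normalisation, residual addition, branch concatenation, global average
pooling, flatten and dense layers.  Three registry architectures preserve
the structural families of the large ImageNet backbones commonly used in
CAM studies at ~10^4 parameters: `plain` (VGG-like stack), `residual`
(identity-skip block), `branch` (parallel 1x1/3x3/5x5 convolutions).  All
end in GAP + dense, expose named conv layers, and record the last
convolution of each resolution stage (the default Layer-CAM layer set).
Users can assemble arbitrary graphs via `GraphBuilder` and plug in larger
backbones behind the same contract: `scores` (pre-softmax), `activations`,
`class_gradient`, `masked_scores`, plus activation injection
(`score_with_activation`) which the finite-difference oracles use.

Training is SGD with momentum 0.9 on softmax cross-entropy, learning rate
5e-3, batch 32, early stopping on validation accuracy with best-weight
restore.  BatchNorm is integral here: without it, SGD at this learning
rate barely moves a small from-scratch CNN.  The loss typically sits near
chance for the first ~10--25 epochs before separating, so the defaults are
max 120 epochs with patience 25; with them all three architectures reach
validation accuracy >= 0.97 on severity-0.9 data across 10 seeds, in
roughly 20--50 s per model on one CPU core (float32).  Training and CAMs
are bit-deterministic for fixed seeds.  Models serialise as `.npz` weights
plus a JSON architecture descriptor.

## CAM methods

All methods compute a map for the damaged class (y=1) only, then share the
post-processing: bilinear upsampling to input resolution and min-max
normalisation to [0, 1] (an identically-zero raw map stays zero), so that
cross-method IoUs are well defined.  Index convention: row-major (row,
column), 0-based.

* **Grad-CAM**: `w_k = mean_ij dY^(c)/dA_k(i,j)` of the *pre-softmax*
  score; map `ReLU(sum_k w_k A_k)`.  On a GAP+linear-head network this is
  the classic CAM weight projection up to a constant, which the tests use
  as an analytic oracle.
* **Grad-CAM++**: `w_k = sum_ij alpha_k(i,j) ReLU(g_k(i,j))` with the
  closed form `alpha = g^2 / (2 g^2 + sum_ab A(a,b) g^3)` (elementwise,
  0/0 -> 0), which is exact for the second/third derivatives of the
  exponentialised score of a piecewise-linear network -- the common
  exponential factors cancel.  As in the original authors' released
  implementation, alpha is then normalised per channel over
  positive-gradient locations, which makes `w_k` a weighted average of
  positive gradients and reduces Grad-CAM++ to Grad-CAM exactly when the
  gradient field is spatially constant.
* **Score-CAM** (gradient-free): each channel's activation map is
  upsampled, min-max normalised (a constant channel maps to an all-zero
  mask), multiplied elementwise with the input, and scored; the channel
  weights are the softmax over channels of those pre-softmax class scores,
  hence a probability vector.  Map `ReLU(sum_k w_k A_k)`.
* **Faster Score-CAM**: Score-CAM restricted to the 10 channels (default)
  with the highest spatial activation variance, ties broken by lowest
  channel index; the softmax runs over the retained channels only, and all
  channels are used when K <= 10.
* **Layer-CAM**: per-location weights `ReLU(g)`.  The default "paper" mode
  takes `g` as the gradient's deviation from its per-channel spatial mean
  (with sub-epsilon residues of the subtraction zeroed, so a constant
  gradient yields an exactly empty map); "classic" mode uses the raw
  gradient as in the original formulation -- both are provided because the
  two readings genuinely differ.  Per layer, `M = ReLU(sum_k w_k A_k)` is
  upsampled and rescaled by `tanh(gamma * M / max M)` (gamma = 2), so each
  contributing layer's maximum is exactly `tanh(gamma)`; layers (default:
  last conv of each resolution stage) fuse by elementwise maximum
  (configurable to mean), preserving fine shallow-layer detail.

Binarisation uses `value >= t_CAM` (the `>=` reading; a strict mode is
available) over the grid {0.1, ..., 0.9}, optionally restricted to a
foreground mask.  Nesting `mask(t') subset mask(t)` for `t <= t'` is a
tested invariant.

## Agreement statistics

IoU of two equal-shape binary masks, with the 0/0 case (both masks empty)
scored 1.0 by default -- at high thresholds empty masks are common and two
methods that both report "no damage" do agree; an exclusion policy is
available and both are exercised in tests.  mIoU averages per-slice IoUs.
`phi_m` (model fixed, methods vary) and `phi_c` (method fixed, models
vary) average the upper triangle of the pairwise IoU matrix, i.e. divide
by `C(n,2)`; both are order-invariant and computed only on damaged-class
slices, since no CAM is defined for the fresh class.  The per-sample
damage score used against liquid loss is the mean over the sample's slices
of the masked damage fraction within the foreground.  Correlation is
Spearman's rank (a Shapiro--Wilk normality p-value is computed and logged
alongside, but rank correlation is always reported -- bounded fractions
cannot be assumed normal); constant inputs yield a flagged undefined
result rather than a number.  Group differences use the tie-corrected
Kruskal--Wallis H; its empirical type-I error under an exchangeable null
is verified at the nominal 5% level in the tests.

## Pipeline

`run_pipeline` executes generate -> train -> cam -> agree -> report.  Each
stage writes artifacts (HDF5 images/heatmaps, CSV tables, JSON summary and
manifest) keyed by a content hash of its config subsection plus its
upstream hash, so re-runs resume from cache and any config change
invalidates exactly the downstream stages.  Heatmaps are computed for
every damaged slice of every (model, method) pair; warnings are logged for
all-zero heatmaps.  The manifest records seeds, pair counts (`C(|C|,2)`
and `C(|M|,2)`) and artifact checksums.  Training augmentation is off by
default at desk scale (the synthetic classes are separable without it) and
can be enabled in the config.

## Problem sizes

Defaults mirror the emulated study design scaled to one CPU core: 32
samples in groups of 11/11/10, 8 slices per sample (4 in the acceptance
script) at 64x64, three architectures of ~10^4 parameters, five CAM
methods, nine thresholds.  The acceptance script completes in minutes; the
full test suite, including a ten-seed end-to-end recovery check, runs in
roughly ten minutes.

## Known limitations

* The CNN engine is CPU-only and eager; it is sized for desk-scale
  experiments, not for ImageNet backbones (those can be wrapped behind the
  same contract but bring their own runtimes).
* The generator's parameters are plausible rather than calibrated -- no
  public quantitative spatial statistics of real freeze-damage fields
  exist to fit them to.
* Smoothed/integrated CAM variants (Smooth Grad-CAM++, Integrated
  Score-CAM, Axiom-based Grad-CAM), guided backpropagation and
  deconvolution are out of scope, as is any downstream fully supervised
  segmentation stage seeded by the CAM masks.
* Heatmap comparability across methods relies on the shared min-max
  normalisation; methods whose raw scales differ are only compared after
  that normalisation, which is itself a choice.
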