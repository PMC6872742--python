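# Methods

## Overview

`seg2surv` implements a two-stage prognostic imaging pipeline. A 3D
encoder-decoder segmentation network (U-Net) is trained per imaging modality
(CT, PET) on tumor contours alone, with no outcome information. The
most-compressed encoder output — the bottleneck — is then harvested as a
per-patient feature vector, reduced by unsupervised k-medoids clustering
under Pearson correlation distance, filtered by squared-loss LASSO against
the binary survival outcome, and fed to a logistic model that predicts the
probability of being alive at a fixed horizon. Gradient-based tools
(activation maximization, guided-backpropagation risk maps) expose what the
selected bottleneck neurons respond to and which voxels drive predicted
death probability.

Because no patient data ship with the package, a phantom-cohort generator
produces PET/CT-like volumes with known ground truth, and the whole pipeline
is exercised and tested against that generator.

## Segmentation network

Architecture: `L` encoder levels of two 3x3x3 same-padding convolutions +
ReLU, 2x2x2 stride-2 max-pooling between levels, channel widths
`base * 2^level` (32..512 at full scale); a symmetric decoder with
nearest-neighbor x2 upsampling, a 3x3x3 convolution, skip concatenation and
two further convolutions per level; a final 1x1x1 convolution + sigmoid
yields the voxelwise tumor probability, thresholded at 0.5. For a 96x96x48
input at 5 levels the bottleneck tensor is 6x6x3x512 = 55,296 activations;
inputs whose dimensions are not divisible by `2^(L-1)` auto-reduce the depth
(48x48x24 runs at 4 levels, bottleneck 6x6x3 positions).

The network, its backpropagation, and Adam are implemented directly in
numpy (im2col + BLAS GEMM convolutions, chunked to bound peak memory). The
data gradient of a stride-1 same-padding convolution is again a same-padding
convolution with flipped, channel-transposed kernels, so forward and
backward share one primitive. All layer gradients are verified against
central finite differences in the test suite.

Training choices (the protocol leaves them open):

- **Loss.** Default is soft-Dice plus foreground-weighted binary
  cross-entropy (weight = background/foreground voxel ratio, capped at 50).
  Pure soft-Dice at mini-batch 1 reliably collapses to the all-background
  solution on multi-phantom training — once the sigmoid saturates near 0 the
  Dice gradient cannot recover — while the weighted BCE term keeps
  foreground logits alive. Pure `dice` and `bce` remain config options.
- **Optimizer.** Adam, learning rate 1e-3, mini-batch 1, 20 epochs by
  default, optional L2 weight decay added to the gradient.
- **Checkpointing.** The epoch with the best validation DSC (training loss
  when no validation pairs are supplied) is kept; early stopping with
  patience 5.
- **Input scaling.** Inputs are min-max normalized to [0, 1] using the
  modality clip window (CT [-500, 200] HU, PET [0.01, 20] SUV) inside the
  network; gradients returned to callers are w.r.t. raw voxel values.
- **Initialization.** He-normal, deterministic per config seed.

## Preprocessing

Volumes are resampled to 1 mm isotropic spacing (linear for images, nearest
for masks; voxel centers at `index * spacing`, edge-clamped), cropped to a
fixed ROI centered on the tumor mask's center of mass (rounded
`floor(c + 0.5)` per axis, half-open windows, 0-based indices), clipped to
the modality window, and optionally augmented by axis flips, right-angle
in-plane rotations, and bounded integer translations applied identically to
image and mask. Out-of-bounds crop regions are padded with the modality's
lower clip bound so padding is inert after clipping; the crop origin is
recorded for exact back-mapping of ROI-space maps into source coordinates.

## Feature table

Bottleneck activations are taken after the ReLU (so they are nonnegative,
which in turn makes risk maps nonnegative) and flattened x-fastest,
y, z, then channel; columns carry (modality, position, channel) provenance
and the CT block precedes the PET block. Single-modality tables are exact
column subsets of dual-modality tables, which is what lets a CT-only
external cohort be scored by a CT-only model. Conventional baselines
(SUV_max, SUV_mean, MTV, TLG = MTV x SUV_mean) are computed over the mask
for comparison.

## Feature reduction

Features are clustered by PAM-style k-medoids under the Pearson correlation
distance d = 1 - R (constant columns are dropped beforehand; a pair
involving one would have undefined correlation and is treated as
uncorrelated, distance 1). Each k is run from 10 random initializations;
per k the mean summed inner-cluster distance and mean silhouette are
recorded and the Silhouette method picks k. On problems of at most 200
features the alternating (Voronoi) pass is refined by a full greedy PAM
swap phase — exhaustive-search equivalence on small instances is part of
the test suite; above that size only the alternating pass runs, since the
swap is O(k(n-k)^2) per iteration and the full-scale problem has >10^5
features. Ties (equal distances, equal costs) always resolve to the lowest
column index / earliest run for determinism. The silhouette itself is
computed in-package via one n x k GEMM per run (numerically identical to
the standard precomputed-distance definition; cross-checked against
scikit-learn in the tests) because the generic implementation dominates the
pipeline's runtime at ~10^4 features.

Clustering is re-run from scratch inside each cross-validation training
fold; CT and PET features are clustered jointly over the concatenated table
(a per-modality option exists).

## Survival model

Selection solves squared-loss LASSO on the binary outcome (1 = alive,
0 = dead): `min_b ||y - Xb||^2 + lam ||b||_1` over the medoid features,
standardized internally; `lam` descends a 50-point log grid spanning four
decades from `lam_max = 2 max|X'y|` (the smallest fully-sparse penalty) and
is chosen by 5-fold inner CV on validation MSE. A logistic-LASSO variant is
deliberately not the default: the squared-loss objective is the stated
selection rule. Features surviving at the best penalty enter an unpenalized
maximum-likelihood logistic fit `y = 1/(1 + exp(-(b0 + sum b_i x_i)))`;
(quasi-)separation — detected by non-convergence or standardized slopes
above 10 — falls back to a light ridge (C = 1e4), logged. Zero surviving
features degrade to an intercept-only model rather than failing the fold.

Evaluation uses 6-fold cross-validation with class-balanced test folds:
each fold's test set holds equally many survivors and deaths (the minority
class count divided across folds; leftover majority cases appear only in
training). Fold assignment depends only on labels and seed, never on
features — this is what makes the leakage audit in the tests meaningful.
Metrics are accuracy, sensitivity (correct death prediction over all death
cases, i.e. computed on the 0 class — stated explicitly because the label
convention is 1 = alive), specificity, and rank-based AUC; summaries are
mean ± 1.96 sd/sqrt(folds) as 95% confidence intervals, with the
classification threshold at 0.5. External validation applies a frozen
model (features matched by provenance) with no refitting.

## Interpretation

*Activation maximization*: gradient ascent on the input of the encoder for
a chosen bottleneck neuron, initialized from N(128, 1) voxel noise, step
length `1/sd(gradient)`, 20 iterations, no clipping during ascent (display
normalization only). Degenerate (zero) gradients skip the step with a
warning.

*Risk maps*: with P = 1 - y the predicted death probability (y from the
logistic model), the gradient dP/dA at each bottleneck activation position
is rectified (`max(., 0)`) and reduced over positions — mean by default,
sum as an option; the gradient is per-position while the published
coefficient is per-channel, and the reduction is the package's choice — to
give per-channel coefficients alpha_m >= 0. Channels holding no
LASSO-selected feature have exactly zero gradient and hence alpha = 0. The
map R(X) = sum_m alpha_m A_m(X) is trilinearly upsampled to the ROI grid;
it is nonnegative because activations are post-ReLU. End-to-end voxel
gradients dP/dx are validated against central finite differences at 1e-3
relative tolerance. Only the bottleneck coefficients are rectified
(classic guided backprop's intermediate-layer rectification is available
as an option but off by default, matching the published coefficient rule).

## Phantom generator

Each phantom is a lung-like background volume (CT -800 HU, PET 0.4 SUV)
holding one tumor and `vessel_count` cylinder-like tubes (radius 1.5 vox)
near the tumor surface, identical geometry across modalities. The tumor is
a discrete ellipsoid whose boundary radius is modulated by a band-limited
Gaussian field (sigma 3 vox) scaled by `lobularity`; intratumoral texture
is a second smooth field scaled by `heterogeneity` (CT 40 ± 60h HU,
PET 6 ± 3.5h SUV) so that the heterogeneity parameter monotonically raises
intratumoral variance; Gaussian voxel noise (CT sd 15 HU, PET sd 0.2 SUV)
is added last and PET is floored at 0. Cohort draws: base tumor radius
uniform over 7.5-15.5% of the largest volume dimension (about an 8x volume
range), per-axis anisotropy 0.75-1.15 scaled by the volume's aspect ratio,
lobularity 0.05-0.3, heterogeneity 0-1, 0-4 vessels, small center jitter.

Survival labels follow a logistic model over cohort-z-scored latents.
Default coefficients — chosen from a latent-level AUC calculation before
any pipeline run and then frozen — are -2.0 per SD of tumor volume and
-1.2 per SD of heterogeneity (ideal-observer AUC about 0.88); the "strong"
condition scales them x3 (about 0.98). The generator emulates the
statistical structure the analysis assumes (compact bright tumors,
correlated intra-tumor texture, peritumoral tubes, outcome driven by
latent tumor properties); it does not emulate anatomy, scanner physics,
respiratory motion, registration error, or realistic survival-time
censoring — so passing tests demonstrate that the pipeline recovers signal
it is pointed at, not clinical performance.

## Problem sizes and numerical choices

The package's own study runs at desk scale: 48x48x24 ROI (1 mm), 4-level
networks, base width 4-8 channels, cohorts of 120 phantoms, segmentation
training on 25-30 phantoms with 5 validation, 10 epochs. The full-scale
96x96x48 / 5-level / base-32 architecture is instantiated and its 55,296
bottleneck features per modality (110,592 for the CT+PET pair) counted
directly; training at that width is a GPU-scale exercise and is not part of
the test suite. Float32 is used for network arithmetic (float64 for
gradient-check tests); feature tables and statistics are float64.
Determinism: every stage seed derives from one global seed by hashing the
stage name; identical seeds reproduce cohorts, training, clustering, folds,
and reports bit-for-bit on the same platform.

## Known limitations

- The alternating k-medoids pass above 200 features is a heuristic; it can
  land in local optima the full PAM swap would escape (mitigated by 10
  restarts and exact behavior verified at small scale).
- Nearest-neighbor upsampling + convolution in the decoder (rather than
  transposed convolution) slightly smooths mask boundaries.
- The Silhouette criterion often prefers small k on strongly-correlated
  feature tables, which can starve the LASSO pool; the k range is
  configurable.
- Survival is a fixed-horizon binary outcome; no censoring or
  time-to-event modeling.
- The ridge fallback under separation biases logistic slopes toward zero
  (by design, to stabilize fold metrics).
- At desk scale the bottleneck decodes tumor volume imperfectly and
  heterogeneity only weakly — texture does not affect the segmentation
  target, so segmentation-trained features carry it only incidentally. The
  test suite's strong-effect recovery bound (mean CV AUC >= 0.90) sits at
  the edge of what that fidelity supports and the desk-scale configuration
  narrowly misses it; the bound is kept strict rather than weakened.
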