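# Methods

This note documents the models implemented in `fieldgan`, the parameters
that matter, the synthetic data the package tests itself on, and the
numerical and design choices made where the problem left them open.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The translation-plus-classification model

Given a pair of same-subject T1 volumes — a lower-quality "low-field" scan
*x* and a higher-quality "high-field" scan *y*, both already linearly
registered to a common template — the generator *G* predicts a residual
**transformation mask** *M = G(x)* and the generated volume is
*x\* = x + M*.  Learning the difference rather than the image itself means a
zero-output generator is already the identity mapping, which stabilizes
early training and makes the mask directly interpretable as "what changes
between field strengths".

Three networks are trained together on randomly sampled cubic patches:

* **Generator** — three 3D convolutional blocks, kernel 3, stride 1,
  paddings (2, 0, 1).  The per-block size changes are +2, −2, 0, so the
  output matches the input spatially for any side ≥ 3 and the mask can be
  added directly onto the input.  Blocks are conv → batch norm → ReLU,
  except the final block, which is a plain convolution (no rectifier, so
  the mask can be negative) with zero-initialized weights (so training
  starts at the identity).
* **Discriminator** — five fully convolutional blocks
  (conv → batch norm → leaky ReLU, slope 0.2), strides (2, 2, 2, 2, 1); the
  final block is a plain convolution producing a spatial score map that is
  mean-pooled to a single real/fake logit.  Normalizing the logit map would
  erase the overall score, hence the linear final block.
* **Classifier** — a fully convolutional stack (conv k3 → batch norm →
  ReLU → 2× average pooling, three times) closed by a convolution whose
  kernel spans the remaining spatial extent, so a patch of the configured
  side maps to exactly one spatial position with 2 class logits.  The
  receptive-field-equals-patch-side property is enforced by construction
  and asserted at run time.

Per batch, the discriminator takes one binary-cross-entropy step on
(real = *y*, fake = *x\**), then the generator and classifier take one joint
step minimizing

    w_adv · BCE(D(x*), real)  +  w_l1 · mean|x* − y|  +  w_cls · CE(C(x*), label)

with default weights (1, 10, 1) — the L1-heavy weighting standard for
conditional image-to-image adversarial training.  The classification
gradient reaches the generator through the residual addition; this is the
mechanism that lets diagnostic information shape the translation, and it is
asserted directly in the tests (generator parameters move under a
classification-only loss).  The decoupled variant trains the GAN alone
first (w_cls = 0) and then the classifier on patches produced by the frozen
generator; with an *identity* generator this degenerates into classifying
the raw low-field patches, which serves as the comparison baseline.

Optimization uses Adam with learning rate 2·10⁻⁴ and betas (0.5, 0.999) —
conventional adversarial-training settings — one update per network per
batch, D first.  Non-finite loss components abort the run with the
offending term named.

### Data handling

Patches (default 47³, the configured receptive field of the classifier) are
sampled uniformly over all valid origins; paired sampling uses one shared
origin per draw so spatial correspondence is never broken.  Splits are by
**subject**, never by patch: validation and test receive ⌊n/5⌋ subjects
each and training the remainder (151 → 91/30/30), stratified by label via
round-robin assignment.  After each epoch the generator is scored by mean
center-slice SNR of generated validation volumes (the generator is
size-agnostic, so it is applied to whole volumes) and the classifier by
validation accuracy of the subject-level score at threshold 0.5; the states
with the best validation SNR and best validation accuracy are kept.  The
subject-level score is the mean classifier probability over a configurable
number of random patches (default 20) — the simplest unbiased pooling,
consistent with the fully convolutional design.

Training runs are bit-reproducible for a fixed seed in single-threaded
execution; repeated-run summaries use consecutive seeds and t-based 95%
confidence intervals, including paired differences between variants.

## Preprocessing

Volumes are assumed registered; the package then applies, in order:
z-score normalization over **all** voxels (population SD; background
included, taking the natural reading of whole-volume normalization),
background removal, and clipping to [−1, 2.5].  Background removal is an
explicit-stack depth-first search seeded at the eight corner voxels that
expands through voxels below a threshold (default 0.5 z-units) until the
bright scalp signal blocks it; visited voxels are set to −1, and dim
voxels enclosed by the shell are never reached.  The explicit stack avoids
call-stack overflow on ≥96³ grids; the inner loop is compiled with numba.
6-connectivity is the default (most conservative against leaking through
diagonal gaps); 26 is available.  The fill value equals the clip floor, so
re-clipping is idempotent.  A corner voxel at or above the threshold raises
an error, since the search cannot be seeded when the head touches the
volume boundary.  The DFS is verified against an independent
connected-component flood-fill oracle on random volumes.

## Quality metrics

* **SNR** — mean/SD of in-brain pixels on the center axial slice, where
  "center" is the middle index of the non-background bounding box and
  "in-brain" is the complement of the background mask.  Background is a
  constant −1 after preprocessing and would distort both moments, hence the
  restriction to brain pixels.
* **MSCN / BRISQUE features** — local mean-subtracted, contrast-normalized
  coefficients with a 7×7 Gaussian window (SD 7/6) and stabilizer C = 1 on
  a 0–255 intensity scale (slices are affinely rescaled before the
  natural-scene-statistics metrics).  Features are the generalized-Gaussian
  fit of the MSCN field (shape, variance) plus asymmetric
  generalized-Gaussian fits (shape, mean, left/right scale) of its four
  pairwise-product orientations, at two scales (2×2 block-average
  downsampling): 18 × 2 = 36 features.  Shape parameters are estimated by
  moment matching against a lookup of the Gamma-function ratio on a grid
  α ∈ [0.2, 10] step 0.001.  The final BRISQUE *score* requires a
  regressor trained on a subjectively rated image corpus; the module
  extracts features and accepts an external scorer, and the package's own
  checks rely on SNR and NIQE instead.
* **NIQE** — mean and covariance of the 36 features over tiles (default
  96 px; smaller tiles are appropriate for small phantom slices) of
  pristine slices, keeping the sharpest 75% of tiles by mean local SD.  The
  score of a test slice is √((ν₁−ν₂)ᵀ((Σ₁+Σ₂)/2)⁺(ν₁−ν₂)).  The test-slice
  covariance Σ₂ enters only when the slice yields more tiles than feature
  dimensions; estimated from fewer samples it is rank-deficient noise that
  inflates the pooled matrix and can make scores *fall* as distortion
  grows, so in that regime it is shrunk to zero and the pristine
  covariance alone whitens the distance.  Absolute score comparability
  with other NIQE implementations is not claimed; orderings are.

One empirical caveat: the MSCN transform divides each pixel by a local SD
estimate that includes the pixel itself, which lightens the tails of the
coefficient distribution; for an i.i.d. Gaussian noise image the fitted
shape parameter therefore sits near 2.9 rather than at the theoretical
Gaussian value 2 (the fitters themselves recover α = 2 on true Gaussian
draws, as tested).

## The phantom generator

The phantom emulates the *structure* of the paired-field-strength problem,
not MRI physics.  Each subject is a set of concentric ellipsoids — bright
scalp shell (intensity 1.0), cortical gray (0.40), white matter (0.55) —
with a centered spherical ventricle (0.12) whose radius carries the class
signal: 6 voxels for controls, 10 for disease, on the default 96³ grid.
Per-subject anatomy varies by uniform ±5% jitter of the ellipsoid
semi-axes.  The low-field rendering adds Gaussian noise of SD 0.15 inside
the head; the high-field rendering applies a contrast gain of 1.1 around
the interior mean (background untouched) and adds noise of SD 0.02.  The
pair is stored with its exact difference, so generator recovery can be
scored against ground truth.

The noise/gain defaults are mutually constrained: for the high-field
rendering to have the *higher* in-brain SNR — the physically meaningful
ordering — the structural variance inflation by the gain must stay below
the noise-variance reduction, (g² − 1)·σ_s² < σ_low² − σ_high², which the
defaults satisfy with about a twofold margin given the phantom's structural
in-head SD of ≈ 0.23.  Under these conditions the preprocessed phantoms
show mean center-slice SNRs near 1.36 (low) and 1.44 (high) on 48³ test
grids, values in the range reported for real 1.5 T/3 T cohorts.

Noise is injected only inside the head; the exterior stays exactly at the
background level.  This keeps the corner-seeded background search
deterministic and mirrors registered clinical scans whose air background
is near-constant.  What the phantom does **not** emulate — and what passing
tests therefore do not show about real data — includes k-space/Rician noise
statistics, bias fields, partial-volume effects, registration error, and
anatomical variability beyond affine jitter and ventricle size.  Results on
phantoms demonstrate that the machinery works (the mask is recoverable, the
gradient pathways function, quality orderings are detected); they do not
certify clinical performance.

## Problem sizes used by tests and the acceptance script

End-to-end checks run at desk scale, chosen as the smallest sizes at which
the properties under test are comfortably expressed: 48³ grids (the
smallest grid that can hold a 47³ patch), 31³ patches, generator channels
(6, 6, 1), discriminator (4, 8, 16, 16, 1), classifier (6, 8, 8), batch 4,
3–6 epochs of 30–40 steps.  Mask-recovery checks use a 20-pair cohort with
gain 1.2 and no noise (an exactly recoverable, noise-free target);
classification and SNR checks use 30 training subjects plus a separately
generated 20-subject held-out cohort under the default noisy conditions,
repeated over 3 seeds.  NIQE checks use full 96² slices with 24-pixel
tiles so each slice contributes 16 tiles.  The shape-preservation property
is exhaustive over sides 3–64.

## Known limitations

* The numpy engine is single-device and unbatched across subjects; it is
  sized for method verification, not for training at clinical scale.
* Subject-level aggregation by mean patch probability is one defensible
  choice; dense sliding-window inference is deliberately out of scope.
* BRISQUE scoring requires an externally supplied regressor.
* The 3:1:1 split's floor rule assigns remainders to training; other
  conventions would shift one or two subjects between parts.
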