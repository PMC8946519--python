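# Methods

## The pipeline

`eafcn` implements a two-stage classifier for two-class (AD vs NC)
structural neuroimaging, operating on co-registered 3D volumes plus a
subject table of demographics (age, sex, MMSE).

**Stage 1 — patch FCN.** A fully convolutional network of four blocks
(3D conv → 3D max-pool → batch norm → Leaky ReLU (slope 0.01) → dropout
(p = 0.1)) followed by two convolution-realized fully connected layers
(head 30 → 2 channels at full scale).  The cascade has receptive field
47 voxels per axis and cumulative stride 4; training samples 47³ patches
uniformly from subject volumes, each patch inheriting its subject's
diagnosis (weak supervision — no voxel labels exist).  Optimization is
Adam with cross-entropy on two logits; validation patch accuracy is
measured every 20 steps on a fixed patch set and the best-scoring weights
are kept (ties: earliest).

Because the head is convolutional, the trained patch model applies
densely to whole volumes: the two-channel logit lattice under softmax
gives a per-site p(AD) — the *disease probability map*.  Lattice site
`i` corresponds to voxel `23 + 4·i` (the center of the first 47³ window,
0-based, then stride 4).  Dense and patchwise inference agree exactly at
lattice sites for the attention-free network in evaluation mode; this is
asserted at 1e-5 in float64.

**Attention blocks.** Either variant may be inserted after the complete
fourth block (post-dropout, pre-fc1):

- *Self-attention*: 1×1×1 projections f, g, h (channel reduction
  C′ = ⌈C/8⌉), score matrix s_ij = f(x_i)ᵀg(x_j) over the N = D·H·W
  pixels, softmax over i, value aggregation, 1×1×1 output integration,
  and a learnable residual gain γ initialized to 0 (the block starts as
  the identity, which stabilizes early training and gives an exact test
  anchor).  Cost is quadratic in N.
- *External attention*: learnable memories M_k, M_v of k units
  (default k = 64, bias-free) shared across samples, wrapped by 1×1×1
  input/output transformations.  Scores F′M_kᵀ (N×k) are normalized
  either by a column softmax alone or by *double normalization* (column
  softmax, then row-wise L1), which guards against domination by extreme
  feature values.  Cost is linear in N at fixed k.  Following the block
  diagram, no residual add (a `residual` flag exists for
  experimentation).

With an attention block the dense/patchwise equivalence no longer holds
exactly — the block sees different global context in a 47³ patch versus a
whole volume — so the equivalence is asserted only for the attention-free
network; probability maps for attention variants use whole-volume dense
application, consistent with training-time statistics being patch-level.

**Stage 2 — MCC heatmap, ROI, fusion MLP.** Across subjects of a
validation fold, each lattice site's thresholded prediction
(AD iff p > 0.5) is compared with the subject labels; the site's Matthews
correlation coefficient forms the *MCC heatmap*.  The k sites with the
highest MCC (ties broken lexicographically; default k = 200 at full
scale, 10 at desk scale, clamped to the lattice size) are the ROI.  The
fusion classifier is a two-layer MLP (hidden width 32, batch norm, Leaky
ReLU, dropout 0.1) over, per mode: (A) the p(AD) values at ROI sites,
(B) demographics — z-scored age, sex ∈ {F=0, M=1}, z-scored MMSE — or
(C) both concatenated.  ROI probabilities are already in [0, 1] and are
not rescaled; demographic standardization uses training-fold statistics
only (a constant feature gets scale 1 and standardizes to 0).  Exactly
tied logits predict NC by convention.

**Evaluation.** Metrics from integer confusion counts with AD positive:
accuracy, sensitivity TP/(TP+FN), specificity TN/(TN+FP),
F1 = 2TP/(2TP+FN+FP), MCC.  Every degenerate denominator yields 0, not
NaN, so aggregation stays total.  (One published formula sheet in this
family prints the specificity denominator as TP+FP; the standard
TN/(TN+FP) is implemented, and the discrepancy is noted here rather than
silently absorbed.)  Cross-validation is stratified five-fold over
sorted subject ids (deterministic given the seed and invariant to input
order); per fold, one non-test fold is the FCN validation fold — the only
data the heatmap and ROI ever see — preventing selection leakage into the
held-out fold.  Results are reported as mean ± SD over repeats × folds.

## Numerical core

No GPU framework is used: `eafcn._nn` is a compact numpy compute core
with hand-written backpropagation for 3D convolution, max-pooling, batch
normalization, dropout, linear layers, both attention blocks, and Adam.
Every gradient is verified against central finite differences in float64
in the test suite.

Convolution has two code paths:

- an **FFT path** (training default): valid cross-correlation via padded
  real FFTs; with FFT length ≥ the input extent all three products
  (forward, weight gradient, input gradient) read only alias-free
  regions.  This minimizes memory traffic, the binding constraint at
  these feature-map sizes on one CPU core.
- a **GEMM path** (shift-and-matmul column tensors): simple, reproducible
  arithmetic used by the float64 evaluation entry points where dense and
  patchwise outputs are compared at tight tolerance.

Softmaxes subtract the per-axis maximum before exponentiation.  Batch
normalization follows the usual convention: biased variance for
normalization, unbiased in the running estimates, momentum 0.1,
eps 1e-5; evaluation mode uses running statistics (dropout is inactive
in evaluation, including when validation metrics are sampled).
Weights are fan-in-scaled uniform, seeded; every stage derives a child
seed deterministically from the global seed, so runs are reproducible
per platform (bit-exactness across BLAS/FFT implementations is not
promised).

## Synthetic cohorts

The generator emulates just enough structure to exercise every stage:
per-subject volumes are Gaussian noise fields (mean 0.5, SD 0.2) in which
disease-class subjects have the intensity inside one or more lesion
spheres reduced by a fixed effect size (0.6 by default) before a light
Gaussian smoothing (σ = 1 voxel) — smoothing after insertion keeps the
lesion border from being a trivially sharp edge.  Demographics are drawn
from class-conditional truncated normals matching a published 307 AD /
243 NC cohort summary: age 76.3 (57–92) vs 79.4 (65–87), MMSE 22.8
(19–27) vs 28.6 (26–30), male fractions 180/307 vs 101/243; the
truncation SD is range/4 so ~95% of untruncated mass lies in the printed
range.  MMSE barely overlaps between classes, so demographic-only fusion
has genuine signal, as it does clinically.

The default *desk cohort* is 20+20 subjects on 64³ grids with one lesion
sphere of radius 8 centered at voxel (24, 24, 24).  What the generator
does **not** model: MRI physics, partial-volume effects, scanner/site
effects, anatomical variability, or an intermediate (MCI) class.
Passing tests on this cohort demonstrate that the machinery recovers a
planted, localized, class-consistent contrast — not clinical-grade
performance on real scans.

A caveat specific to the geometry: with a 47³ receptive field inside a
64³ volume, every lattice site's window contains most of the volume, so
spatial localization of the MCC heatmap rests on the effective receptive
field being concentrated near the window center rather than on hard
visibility differences.  Larger volumes sharpen this contrast.

## Scale profiles and training settings

| setting | full scale | desk scale |
|---|---|---|
| block channels | 20/40/80/160 | 4/8/16/32 |
| head | 30 → 2 | 8 → 2 |
| iterations | 3000 | 200 |
| learning rate (FCN) | 1e-4 | 1e-3 |
| learning rate (MLP) | 1e-4 | 1e-2 |
| ROI size k | 200 | 10 |
| batch size | 10 | 10 |

The desk profile shares the full profile's geometry (receptive field 47,
stride 4) and exists so the whole pipeline trains in minutes on one CPU
core.  The faster desk learning rates are part of that calibration: a
200-iteration run at 1e-4 leaves the loss essentially at initialization
(1e-4 is matched to the 3000-iteration full-scale schedule), while 1e-3
brings the desk FCN to ceiling validation accuracy on the default cohort
within ~100 iterations.  Each training batch draws 10 patches from 10
distinct training subjects (one each), maximizing subject diversity per
step.  Validation uses 6 fixed patches per validation subject.

The standard desk study (`eafcn.experiments.desk_study`) runs three
training seeds on the default cohort; per seed, three folds train the
FCN, one fold provides the validation heatmap/ROI, and one fold is held
out for the fusion MLPs.  It reports validation patch accuracy, the
distance of the top heatmap site to the planted lesion center, and
held-out MLP-A/B/C accuracies — the quantities the acceptance script
writes.

## Known limitations

- The full-scale profile (182×218×182 inputs, 3000 iterations) is
  declared and shape-checked but not trained here; training it is a
  GPU-scale undertaking.
- Registration to a common template, skull stripping, and bias-field
  correction are assumed done upstream; the package validates only
  shapes and finiteness.
- The whole-volume CNN baseline is constructed and shape-verified but
  has no desk-scale training recipe (its flattening head fixes the input
  shape to the registered template).
- ROI probabilities are used sitewise; averaging per connected region is
  not implemented.
- Predicted probabilities are not calibrated.
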