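# Methods

This note documents the models and procedures the package implements, the
defaults it chooses where the underlying method leaves details open, and
what the synthetic experiments do and do not establish.

## Preprocessing

Volumes are assumed already registered to atlas space (the synthetic
generator produces them there); the package performs only the computable
per-voxel steps. Each voxel series is linearly detrended by ordinary least
squares. Band-pass filtering is a frequency-domain boxcar: DFT, zero every
bin outside the closed band, inverse DFT. The boxcar was chosen over an IIR
design because it is exactly idempotent and testable bin by bin. The
default band is **0.01–0.08 Hz**, the standard resting-state low-frequency
window; it is a config field, not a constant.

The wiring is fixed and asserted by tests: ALFF/fALFF consume detrended,
*unfiltered* series (a fractional amplitude computed after band-passing
would be ≈ 1 everywhere and meaningless); FC and DC consume detrended,
band-passed series; ReHo consumes detrended, band-passed, *unsmoothed*
series — rank concordance over a neighborhood has its own smoothing effect,
and pre-smoothing would inflate it. Spatial Gaussian smoothing
(`smooth_fwhm_voxels`, default 0 = off) is available for the FC/DC branch.

## Features

**FC.** Region series are arithmetic voxel means within each positive atlas
label (label 0 is background). The printed form of the region-signal sum in
some descriptions of this pipeline omits the normalization; the mean is the
only reading consistent with "average signal" and is what is implemented.
Pearson correlation uses the sample formula with an explicit error on
zero-variance series (never a silent 0). No Fisher z-transform is applied.
The feature vector is the strictly lower triangle in row-major order; the
mapping is lossless given symmetry and the unit diagonal.

**DC** thresholds the *signed* voxel-pair correlation at r > 0.25 (strict),
so perfect anticorrelation contributes nothing; this follows the stated
rule d_ij = 1 iff r > 0.25. Because the common alternative thresholds |r|,
an `absolute` switch is provided. Zero-variance voxels get DC = 0 and are
flagged. The implementation is a chunked standardized matrix product; an
all-pairs brute-force oracle pins it exactly (integer match).

**ReHo** is Kendall's coefficient of concordance
W = 12 Σ_t (R_t − R̄)² / (K²(T³−T)) over the rank sums of the K series in
the voxel's neighborhood (7, 19 or 27; default 27). Published formulas for
this statistic are sometimes garbled in print; the standard rank-sum form is
what the ReHo literature defines and what is implemented. Midranks are used
for ties without a tie-correction term — ties have probability zero for
continuous data, and the omission is documented rather than hidden.
Boundary voxels use the truncated neighborhood actually inside the grid
(padding would invent data); K varies accordingly.

**ALFF / fALFF.** The one-sided DFT amplitude |X[h]| is summed over bins
whose frequency h·fs/T lies in the closed band. The amplitude sum (not the
power sum) is the default because fractional ALFF is defined as a ratio of
amplitude totals; a `power_mode` switch restores the squared variant. fALFF
excludes the DC bin from its denominator by default (the mean is not a
fluctuation), guaranteeing values in [0, 1]; constant voxels are flagged
and set to 0 with a warning.

## Capsule network

Stem: valid-mode conv → ReLU; capsule conv → 8-dimensional primary capsule
vectors squashed by s ↦ s·‖s‖/(1+‖s‖²); votes from each primary capsule to
each class capsule via learned 16×8 transformation matrices; dynamic
agreement routing (3 iterations: couplings are per-input-capsule softmaxes
of logits that grow by vote·output agreement). Class-capsule lengths in
[0, 1) are the class scores; ties in the argmax break toward the lower
class index. The loss is the margin objective with m+ = 0.9, m− = 0.1,
λ = 0.5, summed over class capsules and averaged over the batch; there is
no reconstruction regularizer — the loss is exactly the stated objective.

Choices left open by the architecture description and fixed here (all
config-exposed):

- **Stem size.** Defaults are desk-scale — 32 stem channels with kernel 5,
  8 capsule channels with kernel 5 stride 2 — sized so the network fits the
  12×12 mid-slices of the default synthetic cohorts. The classic
  large-image variant (256 channels, kernel 9; kernel-9 stride-2 primary
  capsules) needs ≥ 25×25 inputs and is reachable through the same config
  fields.
- **Input representation.** Each subject's 3D feature maps are z-scored
  within subject (so ALFF's scale cannot dominate DC's) and reduced to the
  axial mid-slice, stacked as channels; `slices="triplanar"` stacks the
  three orthogonal mid-slices instead. 2 classes by default.
- **Optimization.** Adam (lr 1e-3), batch 16, 60 epochs by default; the
  experiments in the test-suite and acceptance script use 30 epochs, which
  is past convergence for the cohort sizes involved. Initialization is He
  for convs and σ = 0.1 normal for capsule transforms, all from the config
  seed; training and inference are bit-reproducible given the seed.

The network and its gradients run on a minimal reverse-mode autodiff
engine written for this package (elementwise ops, matmul, reductions,
softmax, an im2col conv2d, Adam); gradient correctness is pinned by
finite-difference checks in the test suite.

## Ensemble and metrics

Per-feature models are fused by weighted averaging. Capsule lengths do not
sum to one, so each member's score vector is normalized to unit sum first —
otherwise "weighted average" is ill-defined across members; weights default
to uniform. The three reported metrics are correct rate (TP+TN)/n, recall
TP/(TP+FN) and precision TP/(TP+FP) — the only assignment under which the
three headline quantities of this family of studies are all distinct.
Undefined ratios are NaN with a warning. The evaluation protocol is a
single stratified held-out split (default 20%), deliberately simple and
clearly the package's own choice; a cross-validation hook is left open.

## Group statistics

Pooled-variance two-sample t by default (the classic SPM-style choice),
Welch via a switch. Zero-variance voxels are flagged, not NaN-propagated.
Clusters are connected components of {t > θ} and {t < −θ} separately
(default 26-connectivity), dropped below a minimum extent; the peak is the
max-|t| voxel and Z is the signed standard-normal quantile of the t's
two-sided tail probability (monotone, Z(0) = 0, clamped to the finite
range). No multiple-comparison correction is applied by default, mirroring
uncorrected cluster-table reporting; `fdr_mask` provides
Benjamini–Hochberg over voxel p-values for the corrected path. Voxel counts
are reported as counts (convertible to volume given voxel size).

## Synthetic cohort model

Each region carries a low-frequency oscillation: 3 sinusoids with
frequencies drawn uniformly in 0.01–0.08 Hz and uniform phases, amplitude
0.4 each, on top of unit-variance white Gaussian voxel noise. These
baseline values put band-passed within-region voxel correlations near
0.4–0.5 — synchronous enough for ReHo/DC to be meaningful, noisy enough
that nothing separates classes when the effects are zero. The three group
effects, applied only in affected regions of patients (labels (1, 2) of the
8-block default atlas):

- `effect_alff` ≥ 0 multiplies the oscillation amplitude by (1 + effect);
- `effect_fc` ∈ [−1, 1] mixes a subject-level shared oscillation into each
  affected region as √(1−|w|)·own + sign(w)·√|w|·shared, which is
  variance-preserving and makes the induced inter-region correlation equal
  w itself;
- `effect_reho` ∈ [0, 1] replaces a variance share e of each voxel's noise
  with a region-shared component (√(1−e)·private + √e·shared).

Amplitude raising also raises within-region synchrony (the oscillation is
region-shared), so DC and ReHo respond to `effect_alff` too; the knob
*independence* guaranteed and tested is narrower: `effect_alff` alone does
not move the off-diagonal FC group mean, because region-mean oscillations
remain independent across regions.

Everything is deterministic given (cohort seed, subject seed, label); the
default cohort is 70 patients / 30 controls on a 12×12×12 grid of 8 block
regions, TR 2 s, 128 time points. Chance-level (null) experiments use
balanced 30+30 cohorts instead, because a 50% chance check is only
meaningful at a balanced base rate.

What the generator does **not** emulate: hemodynamic response shape,
autocorrelated (AR) noise, head motion, cardiac/respiratory physiology,
scanner drift, anatomical variability or registration error. Passing tests
therefore demonstrate that the implementations are correct and that the
pipeline recovers known injected effects — not that these features or this
classifier separate real patient cohorts at any particular accuracy.

## Problem sizes

The test-suite and acceptance experiments use 12³ grids with 128 time
points and cohorts of 60–100 subjects for classification, 30 subjects per
group for cluster recovery, and 15 per group across 10 seeds for the null
cluster guard; oracle-equivalence checks run on 100 random volumes up to
6³×64. These sizes give stable statistics on a single CPU while exercising
every code path at realistic shapes.

## Known limitations

- The capsule network is CPU-bound numpy; it is meant for slice-scale
  inputs, not full-resolution 3D volumes.
- Degree centrality is O(V²) in voxels per subject; fine at 12³–20³,
  not intended for whole-brain 2 mm grids without masking.
- ReHo's tie handling (midranks, no correction term) very slightly biases W
  downward when ties occur; irrelevant for continuous simulated data.
- The stratified split protocol is a single split; accuracy estimates on
  small test sets are correspondingly coarse-grained (1/n_test steps).
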