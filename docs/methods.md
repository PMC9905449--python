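# Methods

This note documents the models, conventions and numerical choices behind
`qspect`, in the spirit of a package reference: what is computed, under
which assumptions, and where the open design decisions were settled.

## Data model and conventions

Volumes are Z-major arrays `values[slice, row, col]` with spacing
`(dz, dy, dx)` in mm; all coordinates are 0-based `(slice, row, col)`. CT is
in Hounsfield units (DICOM rescale slope/intercept applied at read time),
SPECT in counts until normalized. ROI annotations are 2D: a labelled pixel
set on one axial slice. Annotations are stored as integer label volumes on
the CT grid (0 = unlabelled, 1–6 = class codes) — the simplest lossless
encoding consistent with pixel-wise sampling; each 8-connected same-label
component within a slice is one ROI, and same-label components on different
slices are distinct ROIs. The six classes are: 1 healthy lung, 2 pulmonary
embolism (PE), 3 pneumonia, 4 abnormal-CT/low-perfusion, 5 background,
6 body tissue. Classes 4–6 exist to absorb windows that are none of the
three clinical targets; diagnostic statistics are computed over classes 1–3
only.

## Preprocessing

**CT lung segmentation.** Threshold HU ∈ [−950, −300] (closed interval;
this selects aerated parenchyma — the other reading of the printed bounds,
+950 HU, would select bone), keep the largest 26-connected 3D component,
then morphological closing with a discrete ball of radius 5 voxels
(dilation then erosion, computed on a zero-padded grid so border behaviour
matches an unbounded domain; closing is extensive and idempotent).

**SPECT lung segmentation.** Counts strictly above 20, applied after
resizing to the CT grid (the threshold is a physical count level; resizing
with linear interpolation preserves its meaning). The alternative order is
a one-line change in the pipeline.

**Resizing.** Trilinear interpolation with axis endpoints aligned (target
index `i` samples source index `i·(n_src−1)/(n_tgt−1)`), so constant
volumes stay constant and linear ramps interpolate exactly.

**Mask registration.** An affine transform (in voxel units, resampling
convention `out(x) = moving(A·x + t)`) is estimated by minimising the mean
squared error between the fixed and transformed moving masks, both
converted to float and Gaussian-smoothed (σ = 1 voxel per pyramid level
scale) to make the cost differentiable. Optimization is multi-resolution
(downsampling factors 4, 2, 1 with at most 200/80/40 L-BFGS iterations),
uses analytic gradients of the resampled moving image, scales the matrix
parameters by a characteristic radius of 10 voxels so matrix and
translation steps are commensurate, and is initialized at centre-of-mass
alignment. Everything is deterministic: the cost uses every voxel of the
joint bounding box (plus an 8-voxel margin), never a random sample. If the
finest level stops at its iteration cap the best transform found is
returned with `converged=False` and a warning. On same-mask recovery tests
(random affines, |t| ≤ 10 voxels, scale 0.9–1.1) the post-registration Dice
exceeds 0.98 whenever the mask is finely enough sampled that double binary
resampling itself does not cost more than ~1% Dice.

**Normalization.** Statistics (min, max, 99th percentile with linear
interpolation between order statistics) are computed over the *full*
volume by default — per-scan statistics without masking; restricting them
to a mask (e.g. the lungs) is available via the `statistics_mask` argument
of `normalize_spect`. MAX output is exactly
[0, 1]; PERCENTILE99 maps the 99th-percentile intensity to exactly 1 and
leaves larger values unclipped, as the formula implies. Both modes are
invariant to adding a constant to all intensities.

## Windowed radiomics

"3 × 3" and "5 × 5" name the full square side (offsets ±1 and ±2). A
sample is an ROI pixel whose full centred window lies inside the ROI, in
row-major order of the centre. For rectangles this gives
`(w−s+1)(h−s+1)` samples; 5×5 centres are always a subset of 3×3 centres.

**Discretization.** Fixed global bin edges per modality — CT: 25 HU bins
over [−1050, 400]; normalized SPECT: 0.05-wide bins over [0, 1.5] — rather
than per-window min-max, because 9–25-pixel windows make per-window ranges
unstable and features incomparable across samples. Out-of-range values are
clamped into the end bins (logged once per modality). Bin widths are sized
to resolve the tissue contrasts at play (lung vs. consolidation ≈ 300+ HU;
perfusion defect multiplier ≤ 0.3 of the normalized unit scale).

**Texture conventions.** GLCM: distance 1, four 2D directions (0°, 45°,
90°, 135°), symmetrized, pooled across directions, normalized to sum 1.
GLRLM: maximal equal-level runs per direction, features computed per
direction then averaged. GLDM: dependence size of a pixel = 1 + number of
8-neighbours (inside the window) whose level differs by at most α = 0; the
dependence-zone count equals the pixel count. First order: Entropy
`−Σ p·log2(p + ε)` with ε = 2.2e−16, Uniformity `Σ p²` over the level
histogram, TotalEnergy `voxel_volume · Σ x²` over raw values (voxel volume
from the CT header, 1.0 in unitless tests). CT features use raw HU. The
feature vector is 14 CT values then 14 SPECT values in the fixed order
shipped in `feature_schema.json`. Every feature is verified against
independent brute-force pair/run/neighbourhood enumerations in the test
suite (tolerance 1e−10).

## Classifier

`TissuePatternNet` is a scikit-learn-compatible estimator implementing
input(28) → dense(128) → ReLU → dense(128, linear) → dense(6) → per-class
sigmoid (the most literal reading of "two fully connected layers with 128
neurons linked with one ReLU"; scores deliberately need not sum to 1, the
hard label is the argmax with ties to the lowest class code). Features are
z-scored with training statistics, frozen at fit time.

**Loss.** `Loss = Σᵢ wᵢ·Lossᵢ`, where `Lossᵢ` is the mean `−ln s_true`
over samples of class i and `wᵢ ∝ 1/ρᵢ` (inverse class frequency,
normalized to sum one). The direct-frequency variant `wᵢ = ρᵢ` is available
behind `inverse_frequency_weights=False`; inverse weighting is the standard
imbalance correction and matches the stated purpose of the weights, so it
is the default. Two useful closed forms: a uniform 6-class predictor scores
exactly `ln 6`, and equal class counts reduce the loss to the unweighted
mean cross-entropy. As a *training objective* the printed form is
degenerate for sigmoid outputs (only the true class receives gradient, so
all logits drift upward); the trainer therefore normalizes scores per
sample (`s/Σs`) inside the loss — the same normalization applied by common
deep-learning frameworks when categorical cross-entropy is fed
probabilities — which leaves both closed forms unchanged. The evaluation
function `weighted_cross_entropy` defaults to the unnormalized form.

**Optimization.** Adam (β₁ = 0.9, β₂ = 0.999), learning rate 1e−3, batch
size 256, at most 200 epochs with early stopping on a 10% stratified
hold-out split (patience 20, best weights restored). Mini-batch gradients
weight each sample by `w_class / n_class(train)` so an epoch sums to the
per-class-mean weighted loss. All randomness (initialization, shuffling,
validation split) comes from one `random_state`; fits are bit-reproducible.

## Diagnosis and evaluation

Lesion-level diagnosis is a majority vote over an ROI's predicted hard
labels (a vote over patterns, not averaged scores); ties break by clinical
severity PE > pneumonia > abnormal > healthy > body > background, which
favours sensitivity for the most dangerous pattern. Extra-category votes
are kept: if they win, all three clinical calls are negative.

Proportions carry exact Clopper–Pearson 95% CIs; AUC is the Mann–Whitney
pair statistic (ties ½) with DeLong variance for CIs and for paired tests
of AUC equality against the gold model, Bonferroni-adjusted over the
non-gold models. Models of the same window size are sample-paired (the
count-matching subsample selects identical window centres for both
normalizations); models of different window sizes share no window centres,
so those comparisons use an unpaired z-test on the DeLong variances.
Cross-validation is leave-one-patient-out: a fold holds out every sample of
one patient; pooled out-of-fold predictions give one ROC per model. Per
class, ROC scores are that class's sigmoid output, positives are samples of
the class and negatives the other *clinical* classes.

The gold model is selected automatically as the highest mean clinical-class
LOSO AUC rather than by inspection.

## Phantom generator

The phantom stands in for the unavailable clinical cohort and encodes each
class's defining contrast: two ellipsoidal lungs (CT ≈ N(−800, 60) HU,
joined by an airway bridge so parenchymal thresholding yields one connected
component) inside a soft-tissue body (N(40, 20)) on air (≈ −1015);
a smooth perfusion field (level 120 counts, ±35% smooth variation) over the
lungs with Poisson noise; peripheral wedge-shaped perfusion defects
(SPECT × 0.15, CT drawn from the *same* distribution as healthy lung) for
PE; consolidation blobs (CT ≈ N(−450, 80), perfusion untouched) for
pneumonia; blobs with both changes for class 4; and 1–3 hotspot voxels at
30–60× the mean lung count — the artifact that justifies percentile
normalization. The SPECT is emitted on a half-resolution grid misaligned by
a known small affine (scale 0.98–1.04, in-plane shift ≤ 2.5 voxels), so
resizing and registration are genuinely exercised. ROI disks/wedges are
placed by rejection sampling with a hard attempt cap.

Default sizes — 18×64×64 CT grid, ~10 ROIs and ~250 clinical window
samples per patient at 3×3 after count matching, cohorts of 20 training and
20 test patients — mirror the per-patient sample scale of real annotated
Q-SPECT/CT studies while keeping the full four-model experiment around ten
minutes on one CPU.

**What the phantom does not emulate:** real anatomy (lobes, airways,
gravity-dependent perfusion gradients), attenuation and scatter, partial
volume at lesion boundaries, inter-reader annotation variability, or
COVID-specific consolidation texture. Passing phantom tests therefore shows
the pipeline is correct and the model can learn the *defining* contrasts of
each pattern; it does not certify clinical performance.

## Known limitations

- The registration is affine only (by design); strongly deformable
  misalignment would need a different model.
- Count matching drops 3×3 samples from strata where the 5×5 table is
  empty, and requires every 5×5 stratum to exist at 3×3 (guaranteed by the
  centre-subset property).
- Sample-level metrics pool LOSO predictions across folds (one CI per
  model) rather than averaging per-fold estimates.
- `predict_proba` returns per-class sigmoid scores that need not sum to 1;
  downstream consumers expecting a probability simplex should normalize.
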