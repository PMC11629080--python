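# Methods

This note documents the models, numerical choices and known limits of the
`petrad` pipeline: what each stage computes, why the defaults are what they
are, and what the synthetic validation does and does not demonstrate about
real scans.

## SUV standardization and resampling

PET activity concentration C (Bq/mL) becomes the standardized uptake value
SUV = C · w[g] / (D · 2^(−Δt/T½)) with injected dose D (Bq), body weight w,
uptake interval Δt (min) and T½ = 109.77 min for ¹⁸F. The decay correction
references the dose to scan start via the uptake interval; sites that record
dose already decay-corrected to scan time can set `uptake_interval_min = 0`.
Lean-body-mass and body-surface-area SUV variants are out of scope.

Both modalities are resampled to 1×1×1 mm³. "Bilinear" interpolation of a 3D
volume is read as linear interpolation along all three axes (trilinear) —
a literal bilinear scheme is not defined in 3D. Intensities interpolate
linearly; label masks use nearest neighbor so labels stay integral. The
output grid covers the input's voxel-center extent with the same origin, so
a volume already at 1 mm passes through unchanged and the operation is
idempotent. Out-of-range samples clamp to the boundary value.

## MTV segmentation

* **Reference region**: a sphere of radius 10 mm (a 2-cm sphere) around the
  user-supplied liver seed; mean μ and SD σ over the enclosed voxel centers.
  A sphere clipped by the volume boundary is rejected rather than silently
  truncated.
* **Detection threshold**: SUV > μ + 2σ (strict). PERCIST's alternative
  1.5μ + 2σ form is available (`use_percist_form=True`) but is not the
  default. Candidates are 26-connected components; components below 64
  voxels (0.064 mL at 1 mm; configurable, 0 disables) are treated as noise.
* **Physiologic exclusion**: in the clinical workflow a radiologist removes
  brain/bladder/inflammatory uptake by hand. Here a candidate is removed
  when more than an `overlap_threshold` (default 0.5) fraction of its voxels
  falls inside supplied exclusion masks — a deliberate automation of a
  manual step, and the one place the pipeline departs from an
  operator-driven process.
* **Refinement**: per lesion, keep voxels with SUV ≥ 0.41 · SUVmax
  (inclusive, so the SUVmax voxel always survives), then keep only the
  26-connected component containing the SUVmax voxel. Adjacent lesions are
  re-thresholded per component, not jointly. Refinement is contractive and
  monotone in the fraction by construction.
* **MTV** is the sum of refined lesion volumes (voxel count × voxel volume),
  reported in mL. Largest-lesion selection per compartment (nodal /
  extranodal) breaks volume ties toward the lower lesion id.

## Radiomic features (306 per modality: 38 Size, 9 Shape, 259 Texture)

The exact feature list is the package's contract, frozen in
`petrad/data/feature_manifest.json` and enforced by tests. It is composed
from IBSI-style definitions to the fixed 38/9/259 category split:

* **Size (38)**: voxel count and volume, mesh volume, surface area, max 3D
  diameter, three max in-plane diameters, three principal axis lengths
  (4·√λ from the voxel-coordinate covariance), bounding-box dimensions and
  volume, equivalent-sphere diameter, total lesion glycolysis
  (volume × mean intensity), mean centroid-to-surface distance, and
  threshold-fraction volumes (absolute and relative) at 10 fractions of the
  in-mask maximum (0.30–0.75 in steps of 0.05).
* **Shape (9)**: sphericity, compactness 1 and 2, spherical disproportion
  (= 1/sphericity), surface-to-volume ratio, elongation, flatness,
  asphericity, and a radial irregularity index (SD/mean of surface-voxel
  distance to centroid). All are mask-only and therefore identical between
  CT and PET when the grids coincide.
* **Texture (259)**: 14 first-order histogram statistics; 10 GLCM statistics
  per 13 unique 3D directions plus their directional average (the average is
  the mean of the per-direction values); 6 GLRLM statistics × 14 likewise;
  16 GLSZM statistics and 5 NGTDM statistics (both rotation-invariant, no
  directional expansion). Intensities are discretized to 64 equal-width bins
  over the in-mask range (configurable); a constant lesion occupies bin 1.

Degenerate conventions: constant lesions give zero for entropy-type
features, one for energy/uniformity-type features, and GLCM correlation is
defined as 1 when the marginal variance vanishes. Surface meshes come from
marching cubes on the mask after a 0.8-voxel Gaussian pre-smoothing, which
removes the staircase-area bias of meshing a raw binary volume (a digital
10-mm ball then measures sphericity ≈ 0.99 instead of ≈ 0.92); masks too
small to mesh fall back to voxel-face area, and single-voxel masks report
axis lengths equal to the voxel spacing. Non-finite feature values are
imputed with the cohort median (`impute_cohort_median`) before reduction.

## Reduction

Features with coefficient of variation 100·SD/|mean| ≤ 3% across patients
are removed; columns with zero mean and zero SD are removed, while zero mean
with positive SD (CoV undefined) counts as high-variation and is kept. PCA
z-scores the surviving columns and eigen-decomposes their correlation
matrix — standardization matters because size, shape and texture features
differ by orders of magnitude in scale. Components are computed to
min(rank, 10) so higher-order diagnostics exist; models consume PC1–3.
Signs are fixed (largest-magnitude loading positive) so repeated runs are
bit-identical, and the per-feature mean/SD are stored so held-out patients
project without refitting — the property the cross-validation relies on.
PCA is fit per sub-cohort, per modality, per category.

## Outcome models

The primary endpoint is the 1-year composite (progression or death within
12 months); OS at 1 year can be substituted. MTV enters as log MTV (burden
spans orders of magnitude; in a univariate model the monotone transform
leaves ranks, hence AUC, unchanged). Logistic fits are maximum likelihood;
on non-convergence (separation) the fit falls back to a ridge penalty of
1e-4 and is flagged. Stratified 5-fold cross-validation (seeded,
reproducible) standardizes and projects PCs on training folds only;
sensitivity/specificity use a 0.5 probability threshold (an ROC-optimal
threshold is a trivial variant but 0.5 is primary); AUC is the Mann-Whitney
rank statistic with half-credit ties. Summaries report the fold mean, the
min–max band across folds, and a normal-approximation CI.

Risk groups split at the median predicted probability of the full-cohort
fit. Survival comparisons use Kaplan-Meier product-limit curves and the
two-sample log-rank test; univariate Cox models report exp(β) with Wald 95%
CIs. Cox ties are handled by lifelines' Efron approximation (tie-free
validation data make Efron and Breslow coincide). The model-variant suite
runs the four predictor sets (MTV; PC1–3; MTV+PC1–3; MTV+PC1–3+LDH) per
sub-cohort × modality × category and attaches risk-group OS/PFS log-rank
p-values; missing sub-cohorts are skipped with a note.

## Synthetic cohorts: what they emulate

Whole-body phantoms (default 128³ voxels at 2 mm) contain a Normal(2.0,
0.25) liver ellipsoid (detection threshold 2.5), brain/bladder-analog hot
spheres always above threshold (so exclusion is exercised on every
phantom), and 1–5 lesions with volumes ≈1–100 mL (log-uniform radii
8–28 mm; up to ≈500 mL supported), irregularity uniform on [0, 0.4], SUV
peaks uniform on [4, 10], and a multiplicative correlated intralesional
texture field (relative SD 0.12, correlation length 4 mm). CT mirrors the
PET geometry with soft-tissue contrast (background 30 HU, liver 55, lesions
70, SD 8 noise); no anatomical realism is attempted — downstream stages
only need co-registered intensity structure. One global seed splits into
per-patient seeds, so cohorts are reproducible and extensible.

Lesion surfaces are star-shaped: radius(u) = r₀(1 + α·f(u)) with f a seeded
sum of low-order Legendre ridges normalized to max|f| = 1, clipped at
0.05·r₀. The construction is smooth, reproducible, and monotone: sphericity
decreases as α grows. For fixed-volume designs the discrete voxel count is
calibrated to the target volume (±0.1%), so voxelized MTV carries no
systematic trend with irregularity — without this calibration a ≈1%
monotone rasterization bias induces spurious rank correlation between
shape scores and MTV.

Outcomes follow an exponential proportional-hazards model, log h = log h₀ +
β_mtv·log MTV + β_shape·α, with h₀ = 0.03/month, independent exponential
censoring (0.01/month), death following progression after an exponential
delay (mean 6 months), and LDH lognormal (median ≈266, mean ≈400 U/L)
mildly coupled to log burden. Setting both betas to zero makes outcomes
independent of imaging; this is the null used for calibration checks. At
β_shape ∈ {2, 4, 6} the achievable AUC from the true irregularity alone is
≈0.61/0.73/0.82, which bounds what any shape feature can recover.

Statistical-stage validation uses lesion-level cohorts (one index lesion
per patient rendered in a local 1-mm volume of interest) rather than full
whole-body renders — the chain under test is geometry → features → PCs →
outcome, and this keeps n = 150 cohorts tractable on one CPU; segmentation
is validated separately on whole-body phantoms (20 patients at 128³).

What passing does **not** show: phantoms have no scanner point-spread
function, attenuation or motion artifacts, no inter-scanner variation, no
partial-volume blur at lesion boundaries, and lesion texture is a
stationary Gaussian field — so recovery here is necessary, not sufficient,
evidence for performance on clinical scans, and the published cohort's
patient-level statistics are not reproducible from synthetic data.

## Problem sizes used in validation

Feature contracts: one ≈10 mL lesion (≈10⁴ voxels). Oracle equivalence:
≤6³ grids and ≤10-patient toys, tolerance 1e-10. Segmentation recovery: 20
phantoms at 128³, noise-controlled (zero sensor noise and texture).
Planted-effect recovery: 3 effect sizes × 10 seeds at n = 150; null
calibration: 10 AUC replicates and 40 log-rank replicates on re-simulated
outcomes. Decoupling: n = 200 per design. These sizes balance statistical
resolution against single-CPU runtime.
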