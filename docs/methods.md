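# Methods

`vsgrowth` implements an end-to-end pipeline for predicting whether an
untreated sporadic vestibular schwannoma (VS) under wait-and-scan
management will grow: pharmacokinetic mapping of dynamic contrast-enhanced
(DCE) MRI, conditioning of the tumour region of interest (ROI),
volume-threshold growth labelling, radiomic feature extraction, and a
nested cross-validated support-vector-machine classifier with full
discrimination, calibration and decision-analytic evaluation.  Because no
public VS DCE dataset exists, the package ships a first-class synthetic
cohort generator that reproduces the statistical structure such a study
assumes; all tests and the acceptance script run on generated cohorts.

## Pharmacokinetic model

Tissue contrast-agent concentration follows the extended Tofts model (ETM)

    C_t(t) = v_p C_p(t) + K^trans ∫₀ᵗ C_p(τ) exp(−k_ep (t−τ)) dτ,
    k_ep = K^trans / v_e,

with `K^trans` (volume transfer constant, 1/min), `v_e` (extravascular
extracellular volume fraction) and `v_p` (plasma volume fraction).  The
convolution is evaluated by trapezoidal quadrature on the acquisition time
grid; tests validate it against adaptive quadrature at 0.1% tolerance on a
1 s grid.  Voxelwise fitting is bounded trust-region nonlinear least
squares (`K^trans ∈ [0, 2]` 1/min, `v_e ∈ [10⁻³, 1]`, `v_p ∈ [0, 0.5]`,
generous margins around reported tumour values), initialised from the
Murase linear reformulation with a midpoint-of-bounds fallback.
Non-convergence produces NaN sentinels plus a per-voxel flag, never silent
values; an all-zero curve returns `(0, NaN, 0)` with `v_e` flagged
unidentifiable.

The arterial input function is a documented population biexponential
(Weinmann-style amplitudes 3.99/4.78 kg/L, rates 0.144/0.0111 1/min,
dose 0.1 mmol/kg) with a smooth exponential bolus rise (8 /min) so that
`C_p` is continuous at onset — a discontinuous bolus would make the
grid-native convolution needlessly inaccurate near onset.  Signal
modelling uses the SPGR steady-state equation; pre-contrast T1 comes from
the linearised variable-flip-angle regression (slope = E1), refusing
slopes outside (0, 1).  Signal→concentration inversion clips frames
outside the invertible SPGR range and flags them.  Time grids are seconds
at module boundaries and minutes internally; rate constants are 1/min.

## ROI conditioning

The structural tumour annotation is conditioned before map-based feature
extraction: cystic components are subtracted (cysts lack cellularity and
microvascularity), and the mask is eroded with a 3×3 cross-shaped
structuring element to guard against partial-volume contamination at the
rim.  Erosion is slice-wise in-plane by default (dynamic imaging
resolution is anisotropic, with partial-volume effects dominated
in-plane); a 6-connected 3D mode is available.  If erosion would leave
fewer than 8 voxels the un-eroded (cyst-removed) mask is kept, so tiny
tumours remain analysable.  Z-score normalisation of T2 images uses the
nonzero image support as the default reference region (configurable).
Mask projection between grids is nearest-neighbour with given affine
descriptors; estimating the registration itself is out of scope.

## Growth labelling

Volumetry error is relatively larger for small tumours, so a significant
change is defined against a patient-specific volume-dependent threshold
θ(V) spanning ≈5–30% relative change.  The exact published
limits-of-agreement formula is not reproduced; the model is injectable and
the default is the power law θ(V) = clamp(a·V^(−b), 0.05, 0.30) anchored
at θ(0.2 cm³)=0.30 and θ(2.3 cm³)=0.05 (the interquartile endpoints of the
reference cohort), giving a≈0.0921, b≈0.734.  A tumour is *growing*
(*shrinking*) when its relative change versus the diagnosis volume exceeds
+θ (falls below −θ) on at least two consecutive follow-up scans, otherwise
*stable*; growth takes precedence over shrinkage and the conflict is
flagged.  Fewer than two follow-ups yield a distinct *undetermined* label
that is excluded from training with a logged count.  The binary target is
growth vs nongrowth (stable or shrinking).

## Radiomics

Each patient contributes 101 features per channel (T2, K^trans, v_e, v_p):
18 first-order, 8 shape, 24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM and 14 GLDM
— 404 values in a frozen, versioned name order (`feature_names()`).
Definitions follow the Image Biomarker Standardisation Initiative with 3D
direction-averaged aggregation (13 unique directions at distance 1);
every matrix feature is verified against an independent brute-force
definition-summation oracle at 10⁻¹⁰ relative tolerance in the test suite.

Discretization uses a modality-dependent fixed bin width: the mean in-ROI
intensity range over the *training* patients of the current fold divided
by the hyper-parameter `N_bins`; levels are min-anchored
(`floor((x−min)/w)+1`) with no clipping or outlier exclusion, making all
texture features intensity-shift invariant.  Conventions that affect
values and are therefore fixed and documented:

* the gray-level axis spans 1..max occupied level (empty levels carry zero
  mass); normalised inverse-difference features use that axis length;
* GLCM correlation of a single-level ROI is 1 by convention; such
  degenerate events are handled, not raised;
* the GLDM (not standardised by IBSI) uses dependence size = number of
  26-neighbours within tolerance α=0 of the centre level, with emphasis
  weights j = size + 1 so isolated voxels contribute j = 1;
* the 8 shape features are voxel-count volume, mesh surface area,
  surface-to-volume ratio, sphericity, maximum 3D diameter, major axis
  length, elongation and flatness.  Surface meshes come from marching
  cubes on the 0.5-isosurface of the indicator pre-smoothed with a
  σ=0.7-voxel Gaussian, which suppresses staircase inflation (a radius-10
  ball's sphericity is then within 2% of 1 instead of ~9% low); tiny masks
  that would smooth below the iso-level fall back to the binary surface.

## Classification pipeline

Per training fold, in order: fixed-bin-width discretization (widths from
the fold's training patients), Z-score standardisation (zero-variance
columns dropped with a log), ANOVA F-test selection of the top-k features
(ties broken by fixed feature order), PCA to n < k components (training
covariance basis; retained variance reported), and a class-weighted SVM
(balanced weights N/(2·N_class)).  Probabilities come from Platt sigmoid
calibration fitted on internal cross-validated decision values
(`CalibratedClassifierCV(..., ensemble=False)`), since the probability
mapping is otherwise unspecified for margin classifiers.  The per-fold
probability cutoff maximises Youden's J on the training fold's
out-of-inner-fold predictions (less optimistic than refit predictions;
refit mode is available), with the convention prob ≥ cutoff ⇒ growth and
the lowest maximising cutoff on ties.

Model selection is nested stratified 5-fold cross-validation: inner 5-fold
CV picks the hyper-parameters (kernel, C, rbf bandwidth as multiples of
the scale heuristic, `N_bins`, k, n) maximising mean inner AUC per outer
training set.  Every fitted statistic applied to a validation patient —
bin widths, standardisation, F ranking, PCA basis, SVM, cutoff — derives
from that fold's training patients only; a deliberately leaky variant
exists solely so tests can prove the guard detects leakage.  The full
default grid spans kernel ∈ {linear, gaussian}, C ∈ {0.1, 1, 10},
bandwidth multipliers {0.5, 1, 2}, `N_bins` ∈ {16, 32, 64}, k ∈ {20, 30,
100}, n ∈ {2, 5, 25} (n < k).  The worked examples and the acceptance run
use `compact_grid()` — eight configurations around the reference
operating point (`N_bins`=32, k=100, n=25, gaussian kernel) — which keeps
a 110-patient nested run in the minutes range on one core; this is the
package's chosen desk-scale problem size.

Ablation baselines rerun the identical pipeline on restricted inputs:
baseline tumour volume alone (selection and PCA bypassed), the 101
T2-based features, or the 54 first-order statistics of the three
DCE-derived maps (k is capped below the subset size).

## Evaluation

Fold-level accuracy, sensitivity, specificity, AUC and AUCPR (average
precision) are aggregated as mean ± SD across outer folds; the
confusion-cell statistics (FPR, FNR, diagnostic odds ratio with
Haldane–Anscombe 0.5 correction on empty cells, flagged), calibration
(calibration-in-the-large = observed event rate − mean predicted
probability; Brier score; 10 equal-width-bin reliability curve) and the
decision curve (net benefit TP/N − (FP/N)·t/(1−t) with treat-all /
treat-none references) are pooled over out-of-fold predictions — both
aggregations are emitted because either may be wanted.  Post-hoc rule-out
(maximise specificity s.t. sensitivity ≥ constraint) and rule-in
(symmetric) operating points are searched over observed probabilities and
reported as infeasible when the constraint cannot be met.  Models are
compared by paired patient-level bootstrap of the AUC difference (N=1000,
percentile CI, two-sided p = 2·min(frac ≤ 0, frac ≥ 0) floored at 1/N;
single-class resamples are redrawn and counted).

Feature-level analysis reports the exact intersection of the five
per-fold top-k sets (rank-ordered), Cohen's d with pooled SD per feature
(NaN-flagged at zero pooled SD), representation-group summaries whose
representative is the member with the largest |d|, and signed permutation
importance of the SVM's principal components (mean AUC drop over 20
permutations; sign from the rank correlation between component and
predicted probability).

## Synthetic cohort generator

The generator emulates the reference study design, and its defaults are
the package's study conditions: 110 patients with growth prevalence 0.64
(exactly round(n·prevalence) growing), baseline volumes log-normal with
median 0.7 cm³ and log-SD 1.81 (matching an IQR of 0.2–2.3 cm³), clipped
to the clinically plausible 0.05–30 cm³, drawn *independently of class* so
a volume-only classifier carries no information by construction.  Tumours
are voxelized ellipsoids with axis ratios uniform in [0.5, 1] on a 1.5 mm
isotropic grid (≈200 voxels at the median volume); 20% carry an interior
spherical cyst occupying 5–25% of the tumour.

Parameter maps are Gaussian random fields: white noise smoothed at a
class-specific correlation length, scaled to a patient-level mean drawn
from the class distribution, and clipped to physical range.  Setpoints
follow the reported class-conditional statistics and effect directions:
growing tumours have higher K^trans (mean 0.15 vs 0.09 1/min) and v_p
(0.046 vs 0.026), while stable/regressing tumours have larger and more
spatially clustered v_e dispersion (within-map SD 0.14 vs 0.07,
correlation length 5 vs 2 mm) and less coherent T2 texture (correlation
length 1.5 vs 4 mm).  Where the literature reports only summary
statistics, the within-map SDs and correlation lengths were chosen once as
plausible values reproducing the reported effect *directions*; the
generator is calibrated to signs, not to published effect sizes.  These
are deliberately strong class effects: passing pipeline checks on this
cohort demonstrates correctness of the machinery, not expected performance
on real patients, where effects are weaker, shapes irregular, maps carry
fit noise, and scanner/annotation variability exists — none of which the
generator emulates.

Follow-up volume trajectories are constructed to round-trip through the
labelling rule: growing (and shrinking) cases cross the patient-specific
threshold on the last two of three scans (12/24/48 months) with a safety
margin, stable cases fluctuate within half the threshold; 37.5% of
nongrowing tumours regress (15/40 in the reference cohort).  DCE series
are forward-simulated per voxel (ETM → T1 modulation → SPGR signal, plus
Gaussian noise) and are off by default in cohort generation; the
prediction pipeline consumes parameter maps directly, the precomputed-maps
input path, while the DCE fitting chain is validated separately at the
voxel/map level (noiseless round trips recover parameters within 1%,
SNR-20 series give <10% median K^trans error over 500 voxels).

## Numerical and degenerate-input policy

Seeded `numpy` Generators everywhere; a fixed seed reproduces cohorts,
folds and fits bit-for-bit (default seed 2024).  Ties in feature selection
and Youden maximisation are broken deterministically (fixed order, lowest
cutoff).  Degenerate inputs have defined behaviour rather than crashes:
empty masks and single-class training sets raise named errors; constant
images raise in Z-scoring; single-level ROIs take documented limit values;
empty confusion cells trigger the flagged Haldane correction; infeasible
operating constraints are reported as infeasible.

## Known limitations

Ellipsoidal tumours make shape features nearly uninformative by design;
the generator does not simulate registration error, motion, B1
inhomogeneity, scanner drift or annotation variability; the LOAM threshold
is a parameterised stand-in anchored to the published 5–30% range, not the
published formula; reported discrimination on synthetic cohorts with
strong effects approaches the ceiling and should not be read as a clinical
performance claim.
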