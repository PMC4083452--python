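# Methods

## Study design being emulated

The package implements the computation of a cross-sectional moderation
study in non-demented adults aged 65 and over (n = 71 at the default
configuration): pulsed-ASL CBF quantification with partial volume
correction, extraction of mean corrected CBF in six a-priori ROIs,
aggregation of six binary vascular risk factors with dichotomization at
two or more factors, three-block hierarchical regressions testing an
age x risk-burden interaction on regional CBF, and risk-stratified
CBF–cognition correlations.  Raw participant data for such a study are
not public, so all inputs are produced by the synthetic module and all
claims about correctness are made by parameter recovery against known
ground truth, plus exact reproduction of the published group-comparison
statistics from their printed summaries.

## ASL forward model and quantification

The acquisition model is QUIPSS II pulsed ASL: saturation pulses fix
the labeled bolus width at TI1 and imaging occurs at TI2, so the
difference signal between control and tag in a voxel on slice s is

    dM = 2 * alpha * M0b * (f_unc / u) * TI1 * exp(-TI2_s / T1b)

with alpha the inversion efficiency, M0b the equilibrium magnetization
of arterial blood, f_unc the uncorrected perfusion in mL/100 g/min,
u = 6e6 the constant converting that figure to 1/ms at unit tissue
density, TI2_s = TI2 + s * slice_time the slice-specific inversion
time, and T1b the longitudinal relaxation of arterial blood.  The
quantifier inverts this expression exactly, and the generator uses the
identical constants — the binding contract is round-trip exactness, not
the particular constant values.  Defaults: TI1 = 600 ms, TI2 = 1600 ms,
TR = 2500 ms, 20 tag/control pairs, T1b = 1664 ms (3 T), alpha = 0.95,
CSF-to-blood scale 1.06.  These kinetic constants are conventional 3 T
PASL values; the timing parameters are the emulated protocol's.

Processing order is fixed: surround subtraction → M0 calibration →
kinetic inversion → coil correction → partial volume correction →
smoothing → negative clamping → physiological filtering.  A regression
test pins the order (a voxel with uncorrected CBF 8 and tissue
denominator 0.5 survives only if correction precedes filtering).

Numerical and boundary choices:

- **Surround subtraction.** Each interior frame is differenced against
  the average of its two opposite-label neighbours; the first and last
  frames are excluded from the time average.  A two-point difference at
  the endpoints would be biased by +slope under a linear temporal
  drift; excluding the endpoints keeps the estimator *exactly*
  drift-invariant, which we treat as the defining property of the
  method.
- **M0 calibration.** Median (not mean) of the CSF reference scan
  within the CSF mask (fraction >= 0.9), scaled by a single
  CSF-to-blood factor that folds together proton-density and relaxation
  corrections.  The median is robust to segmentation spill-over; a
  constructed outlier test pins this.
- **Coil correction.** Voxelwise division by the minimum-contrast gain
  field normalized by its mean over valid voxels, so a flat field of
  any level is a no-op and calibration units are preserved.  In the
  generator the gain is applied to the ASL series only; the CSF
  reference is emitted gain-free (treated as already corrected), which
  keeps the calibration chain exact.
- **Partial volume correction.** CBF_corr = CBF_uncorr/(GM + 0.4 WM),
  i.e. zero CSF perfusion and GM flow 2.5x WM flow.  Voxels with
  denominator below 0.1 are effectively non-brain and are invalidated
  rather than amplified.
- **Smoothing.** Gaussian, sigma = FWHM/(2 sqrt(2 ln 2)) per axis,
  mask-weighted (smooth(map*mask)/smooth(mask)) so invalid voxels
  contribute nothing and constant regions are preserved exactly.
  Whether masking should precede smoothing is genuinely open in such
  pipelines; mask-weighted smoothing is our choice and is what the
  round-trip guarantees assume.
- **Physiological filter.** Values strictly below 10 or strictly above
  150 mL/100 g/min are invalidated; the boundaries are retained
  (reading "below 10 or greater than 150" as strict).  Idempotent by
  construction.
- Normalization to a common atlas space is replaced by generation in a
  common 4 mm grid; resampling is a no-op at native resolution.

## Synthetic cohort

True GM-referenced CBF of participant i in ROI r:

    cbf_ir = mu_r + beta_sex * I(male_i) + beta_age_low * (age_i - 75)
             + I(high_i) * beta_int * (age_i - 75) + eps_ir

The interaction slope (default -0.8 mL/100 g/min per year) applies in
the four cortical ROIs only; ages are drawn from N(75, 7.8^2) truncated
at 65.  Risk factors are independent Bernoulli draws at marginal
prevalences 0.59/0.07/0.10/0.085/0.07/0.03 (hypertension, diabetes,
CVD, atrial fibrillation, TIA/stroke, smoking); correlation structure
between factors is deliberately not modelled.  Blood pressures and the
medication flag are drawn *consistently* with the hypertension
indicator (treated participants may be controlled; untreated
hypertensives are re-drawn until SBP >= 140 or DBP >= 90; normotensives
strictly below both cutoffs; pulse pressure forced above 10 mmHg so
rounding cannot produce SBP <= DBP).

**Noise calibration.**  Within-ROI residual SDs are not published for
such designs, so the generator calibrates them from what *is*
published: the moderation table's interaction standard errors.
Inverting SE = sigma / D through the n = 71 design's empirical
information factor (D ≈ 20.6 per unit SD, estimated by simulation)
gives per-ROI residual SDs of 7.5 / 9.5 / 8.0 / 4.5 / 11.5 / 7.0
mL/100 g/min for medial temporal / inferior parietal / posteromedial /
frontal / thalamus / caudate.  This makes the simulated study's
interaction t-statistics match the emulated study's (≈ 2.2–3.1)
rather than being an arbitrary noise floor.

**Cognition link.**  Within the high-risk group only, Trails B (s) is
driven negatively by the mean of frontal and inferior-parietal CBF
(slope -2 s per mL/100 g/min, residual SD 14) and CVLT-II trials 1–5
positively by medial-temporal CBF (slope 0.35, residual SD 9.5); slopes
and noise are set so the high-group correlations land near the
published magnitudes (r ≈ -0.7 and +0.3).  Low-risk participants get
the same marginal distributions with no CBF dependence.  One high-risk
participant's Trails B is dropped by default, emulating incomplete
testing.  WML volume is log-normal with a positive age slope (0.04/yr
on the log scale) and no risk interaction, available for ~58% of
participants.

**Phantom.**  The tissue model is a deliberately non-anatomical
lattice phantom on a 32 x 32 x 20 grid at 4 mm isotropic: each of the
14 ROI subregions is a 3-voxel GM-dominant box (GM 0.9/WM 0.1), plus a
WM-dominant core (WM 0.95) and a CSF-filled ventricle, every structure
separated by >= 2 background voxels so the 4 mm FWHM kernel (radius 2
voxels after truncation) cannot mix structures.  Within a structure the
true CBF is constant, so mask-weighted smoothing is exact and the
noise-free pipeline reproduces ROI ground truth to machine precision —
the 1e-3 acceptance margin is comfortable headroom, not the observed
error (~1e-14).

What passing tests therefore do and do not show: they validate the
algebra and ordering of the processing chain, the estimator properties
of the statistics, and the power/type-I behaviour of the design at the
study's size.  They do not validate behaviour under real ASL artifacts
(motion, transit-delay variation, segmentation error, anatomically
realistic partial-volume profiles), which the phantom deliberately
omits.

## Statistics

- Group comparisons: pooled-variance Student t (which reproduces the
  published continuous-row statistics, so Welch is not used) and
  Pearson chi-square without continuity correction (ditto for the
  categorical rows).  The published CVLT row is the one exception: its
  printed t (0.43) is not recoverable from the printed T-score
  summaries (recomputation gives 0.09); it was plausibly computed on
  raw trial scores, so it is excluded from the reproduction checks and
  retained in the reference table for completeness.
- Hierarchical regression: three nested OLS fits; Delta R^2 per block;
  coefficients reported from the block of first entry (moderation-table
  convention) with full-model coefficients retained.  Age enters
  uncentered by default to match the emulated convention; a centering
  switch shifts main-effect coefficients but provably not the
  interaction test (pinned by test).  Missing outcomes are deleted
  listwise.  Rank deficiency raises rather than silently dropping
  terms.
- Stratified correlations: Pearson r per risk subgroup on
  pairwise-complete pairs; subgroups with n < 3 or zero variance are
  skipped with an explicit notice, never coerced to zero.
- Alpha = 0.05 throughout, no multiple-testing correction, matching the
  emulated analysis plan.

## Reproducibility

All randomness flows from a master seed: the cohort from
SeedSequence([seed, 1]), each participant's acquisition from
SeedSequence([seed, 2, crc32(id)]).  Identical config + seed reproduce
the cohort TSV byte-for-byte and every NIfTI stage checksum (gzip
writing is timestamp-free).  Run manifests record the config hash and
per-stage SHA-256 checksums.

## Problem sizes

Default analyses run at the emulated study's size (n = 71, 40-frame
acquisitions on the 32 x 32 x 20 grid).  Calibration experiments use
100 replicates for sign recovery and 1000 for type-I error;
parameter-recovery tests use n = 500 cohorts at table level.  The
imaging round-trip checks use 4-participant noise-free runs, which
exercise every stage of the chain at full grid size.

## Known limitations

- No motion, transit-delay, or multi-TI modelling; the QUIPSS II
  single-compartment assumptions are taken as given.
- The phantom's geometry is a lattice of boxes; spatial claims
  (smoothing behaviour at realistic tissue interfaces) are out of
  scope.
- Risk factors are simulated independently; real cohorts show
  comorbidity structure.
- The WML model enters lesion volume as a number only; no image-based
  lesion simulation.
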