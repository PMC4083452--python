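# aslrisk

Does elevated vascular risk burden make the aging brain's blood supply
decline faster?  `aslrisk` is an analysis package for a cross-sectional
design that asks exactly that: quantify cerebral blood flow (CBF) from
pulsed arterial spin labeling (ASL) MRI in non-demented adults aged 65+,
score each participant's vascular risk burden from six Framingham-derived
binary factors, and test whether the age→CBF slope is *moderated* by
carrying two or more risk factors — then ask whether regional CBF tracks
cognition within the high-risk group.

Because raw participant MRI and clinical data for such studies are not
public, the package ships a first-class synthetic-data module: it
forward-models the ASL acquisition with the same QUIPSS II kinetics the
quantifier inverts and generates a cohort whose ground truth embeds the
target effect structure, so every stage is testable by parameter
recovery.

## What it computes

**ASL quantification.** Tag/control difference via surround subtraction
(each interior frame differenced against the mean of its opposite-label
neighbours — exactly immune to linear scanner drift), CSF-referenced
calibration of blood magnetization M0b, and inversion of the QUIPSS II
kinetic model with slice-specific inversion time:

    f = u * dM / (2 alpha M0b TI1 exp(-TI2_s / T1b))

followed by coil-gain correction, partial volume correction
`CBF_corr = CBF_uncorr / (GM + 0.4 WM)` (GM flow assumed 2.5x WM, CSF
flow zero), 4 mm FWHM mask-weighted smoothing, clamping of negative
values to zero, and a boundary-inclusive physiological filter keeping
10–150 mL/100 g/min.

**Risk scoring.** Hypertension (SBP >= 140, DBP >= 90, or
antihypertensive use), diabetes, cardiovascular disease, atrial
fibrillation, TIA/minor stroke, current smoking; each coded 0/1; low
burden = 0–1 factors, high burden = >= 2.

**Statistics.** Pooled-variance t and Pearson chi-square (no continuity
correction) group comparisons; per-ROI three-block hierarchical OLS
(block 1: sex, APOE e4; block 2: age, risk; block 3: age x risk) with
per-block ΔR²; and risk-stratified Pearson correlations of CVLT-II with
medial-temporal/posteromedial CBF and Trails B with frontal/inferior-
parietal CBF.  Six a-priori ROIs: medial temporal, inferior parietal,
posteromedial, frontal, thalamus, caudate.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_quantify_phantom.py
python analysis/04_interaction_models.py
```

prints, among other things:

```
max relative ROI-mean error vs ground truth: 2.339e-14
round trip exact (< 1e-3 relative): True

age x risk interaction per ROI (block 3):
              roi  delta_r2      B    SE      p
          caudate    0.0008  0.114 0.354 0.7486
          frontal    0.1415 -0.908 0.239 0.0003
inferior_parietal    0.0088 -0.350 0.449 0.4385
  medial_temporal    0.0897 -0.941 0.320 0.0045
    posteromedial    0.0459 -0.828 0.429 0.0577
         thalamus    0.0003 -0.077 0.537 0.8860
```

The round-trip line shows the quantification chain exactly inverting
the noise-free forward model.  The moderation table shows the injected
structure recovered on one noisy simulated cohort of 71: negative
age x risk interaction coefficients (mL/100 g/min per year) in cortical
ROIs — significant here for frontal and medial temporal — and null
interactions in the subcortical ROIs, where none was injected.
`analysis/05_replicate_calibration.py` repeats this over seeds: the
three target cortical ROIs are jointly negative in 95/100 replicates,
and under a null generator the interaction test rejects at 5.6% against
the nominal 5%.

The same steps are scriptable via the CLI:
`aslrisk simulate|quantify|analyze|run-full|make-fixtures`.

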