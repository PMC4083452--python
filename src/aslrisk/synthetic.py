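"""Synthetic cohort, phantom and ASL-acquisition generator.

Emulates a cross-sectional study of non-demented adults aged 65+ in
which regional cerebral blood flow declines with age only among
participants carrying two or more vascular risk factors, and cognition
tracks regional CBF only within that high-risk group.  Ground truth is
retained so every downstream stage (quantification, ROI extraction,
group statistics) can be tested by parameter recovery.

The generative model for true GM-referenced CBF in ROI r is

    cbf = mu_r + beta_sex * I(male) + beta_age_low * (age - c)
          + I(high risk) * beta_int * (age - c) + eps,   eps ~ N(0, sd)

with age centered at c = 75 years and the interaction slope applied in
the cortical ROIs only by default.  ASL acquisitions are forward-
modelled with the same QUIPSS II kinetics the quantifier inverts, so
noise-free data round-trip exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, DimensionError, SizingError
from .quantify import AcquisitionParams, ASLDataset, QuantConfig
from .roi import ATLAS_LABELS, CORTICAL_ROIS, DEFAULT_ROIS, ROI_NAMES

RISK_FACTOR_NAMES = ("hypertension", "diabetes", "cvd", "afib",
                     "tia_stroke", "smoker")

# Marginal prevalences of the six risk factors in the emulated cohort.
DEFAULT_RISK_PREVALENCES: dict[str, float] = {
    "hypertension": 0.59,
    "diabetes": 0.07,
    "cvd": 0.10,
    "afib": 0.085,
    "tia_stroke": 0.07,
    "smoker": 0.03,
}

DEFAULT_ROI_BASELINE_CBF: dict[str, float] = {
    "medial_temporal": 45.0,
    "inferior_parietal": 55.0,
    "posteromedial": 60.0,
    "frontal": 50.0,
    "thalamus": 65.0,
    "caudate": 60.0,
}

# Per-ROI residual SD of true CBF about the regression surface,
# calibrated so the emulated study's interaction-coefficient standard
# errors match the published ones at n = 71 (the published moderation
# table's SEs, inverted through the design's information matrix).
DEFAULT_CBF_NOISE_SD: dict[str, float] = {
    "medial_temporal": 7.5,
    "inferior_parietal": 9.5,
    "posteromedial": 8.0,
    "frontal": 4.5,
    "thalamus": 11.5,
    "caudate": 7.0,
}


@dataclass(frozen=True)
class CognitionLink:
    """Slopes/noise tying cognition to regional CBF in the high-risk group.

    Trail Making B (seconds; higher = worse) is driven negatively by the
    mean of frontal and inferior-parietal CBF; CVLT-II trials 1-5 is
    driven positively by medial-temporal CBF.  Low-risk participants get
    the same marginal means but no CBF dependence.
    """

    trails_slope: float = -2.0        # s per mL/100g/min
    trails_noise_sd: float = 14.0
    trails_mean: float = 80.0
    trails_sd_low: float = 30.0
    cvlt_slope: float = 0.35          # points per mL/100g/min
    cvlt_noise_sd: float = 9.5
    cvlt_mean: float = 46.0
    cvlt_sd_low: float = 11.8


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic study, with study-scale defaults."""

    n_participants: int = 71
    seed: int = 0
    age_mean: float = 75.0
    age_sd: float = 7.8
    age_min: float = 65.0
    age_center: float = 75.0
    prop_female: float = 0.58
    prop_apoe4: float = 0.35
    risk_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RISK_PREVALENCES))
    roi_baseline_cbf: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ROI_BASELINE_CBF))
    beta_sex: float = -8.0            # male offset, mL/100g/min
    beta_age_low: float = 0.0         # mL/100g/min per year (low-risk slope)
    beta_interaction: float = -0.8    # additional per-year slope, high risk
    interaction_rois: Sequence[str] = CORTICAL_ROIS
    cbf_noise_sd: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CBF_NOISE_SD))
    cognition_link: CognitionLink = field(default_factory=CognitionLink)
    drs_mean: float = 139.7
    drs_sd: float = 4.1
    sbp_mean: float = 129.0
    sbp_sd: float = 15.0
    dbp_mean: float = 76.0
    dbp_sd: float = 9.0
    p_meds_given_hypertension: float = 0.88
    n_trails_missing: int = 1
    prop_wml_available: float = 0.58
    wml_log_mean: float = 8.0         # log mm^3 at the age center
    wml_age_slope: float = 0.04       # per year, on the log scale
    wml_log_sd: float = 0.8
    wm_core_cbf: float = 50.0         # GM-referenced CBF in the WM phantom core
    grid_dims: tuple[int, int, int] = (32, 32, 20)
    voxel_size: float = 4.0           # mm, isotropic
    n_pairs: int = 20
    ti1: float = 600.0
    ti2: float = 1600.0
    tr: float = 2500.0
    slice_time: float = 45.0
    m0_blood: float = 1000.0          # signal units
    baseline_tissue_scale: float = 0.9
    gain_amplitude: float = 0.15      # receive-coil inhomogeneity depth
    asl_noise_sd: float = 2.0         # signal units per frame
    drift_slope: float = 0.05         # signal units per frame

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ConfigError(f"n_participants must be >= 2, got {self.n_participants}")
        if self.n_pairs < 1:
            raise ConfigError(f"n_pairs must be >= 1, got {self.n_pairs}")
        for name in ("prop_female", "prop_apoe4", "prop_wml_available",
                     "p_meds_given_hypertension"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        missing = set(RISK_FACTOR_NAMES) - set(self.risk_prevalences)
        if missing:
            raise ConfigError(f"risk_prevalences missing factors: {sorted(missing)}")
        for k, v in self.risk_prevalences.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"risk_prevalences[{k!r}] must be in [0, 1], got {v}")
        if set(self.roi_baseline_cbf) != set(ROI_NAMES):
            raise ConfigError("roi_baseline_cbf must cover exactly the six ROIs")
        unknown = set(self.interaction_rois) - set(ROI_NAMES)
        if unknown:
            raise ConfigError(f"interaction_rois has unknown ROIs: {sorted(unknown)}")
        if any(d < 1 for d in self.grid_dims) or len(self.grid_dims) != 3:
            raise ConfigError(f"grid_dims must be 3 positive ints, got {self.grid_dims}")
        if isinstance(self.cbf_noise_sd, Mapping):
            if set(self.cbf_noise_sd) != set(ROI_NAMES):
                raise ConfigError("cbf_noise_sd mapping must cover the six ROIs")
            if any(v < 0 for v in self.cbf_noise_sd.values()):
                raise ConfigError("cbf_noise_sd values must be >= 0")
        elif self.cbf_noise_sd < 0:
            raise ConfigError("cbf_noise_sd must be >= 0")
        if self.asl_noise_sd < 0:
            raise ConfigError("asl_noise_sd must be >= 0")
        if self.age_sd <= 0 or self.age_mean < self.age_min:
            raise ConfigError("require age_sd > 0 and age_mean >= age_min")

    def noise_sd(self, roi: str) -> float:
        if isinstance(self.cbf_noise_sd, Mapping):
            return float(self.cbf_noise_sd[roi])
        return float(self.cbf_noise_sd)

    def acquisition_params(self) -> AcquisitionParams:
        return AcquisitionParams(ti1=self.ti1, ti2=self.ti2, tr=self.tr,
                                 slice_time=self.slice_time,
                                 n_slices=self.grid_dims[2],
                                 voxel_size=self.voxel_size)


@dataclass
class ParticipantRecord:
    """One subject's demographics, risk factors and cognition."""

    id: str
    age: float
    sex: str                     # "female" | "male"
    apoe4: bool
    sbp: float
    dbp: float
    antihypertensive: bool
    diabetes: bool
    cvd: bool
    afib: bool
    tia_stroke: bool
    smoker: bool
    drs_total: float
    cvlt_trials_1_5: float
    trails_b_seconds: float | None
    wml_volume_mm3: float | None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ConfigError(f"sex must be female/male, got {self.sex!r}")
        if not (self.sbp > self.dbp > 0):
            raise ConfigError(f"require sbp > dbp > 0, got {self.sbp}/{self.dbp}")


@dataclass
class GroundTruth:
    """Generative truth retained for parameter-recovery testing."""

    roi_cbf: dict[str, dict[str, float]]   # participant id -> roi -> CBF
    risk_group: dict[str, str]             # participant id -> low|high
    risk_count: dict[str, int]
    coefficients: dict[str, float]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TissueMaps:
    """GM/WM/CSF fractions plus integer atlas labels on the study grid."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    atlas_labels: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        shapes = {self.gm.shape, self.wm.shape, self.csf.shape,
                  self.atlas_labels.shape}
        if len(shapes) != 1:
            raise DimensionError(f"tissue volumes disagree on grid: {shapes}")
        total = self.gm + self.wm + self.csf
        if total.max() > 1.0 + 1e-9 or min(self.gm.min(), self.wm.min(),
                                           self.csf.min()) < 0:
            raise ConfigError("tissue fractions must be >= 0 and sum to <= 1")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float = -np.inf, high: float = np.inf) -> float:
    for _ in range(10_000):
        v = rng.normal(mean, sd)
        if low <= v <= high:
            return float(v)
    raise RuntimeError("truncated normal rejection failed")  # pragma: no cover


def _draw_blood_pressure(rng: np.random.Generator, config: CohortConfig,
                         hypertensive: bool):
    """BP and medication use consistent with the hypertension indicator."""
    if hypertensive:
        on_meds = bool(rng.random() < config.p_meds_given_hypertension)
        if on_meds:
            # treated: pressure may be controlled
            while True:
                sbp = _truncated_normal(rng, config.sbp_mean + 4, config.sbp_sd, 80, 220)
                dbp = _truncated_normal(rng, config.dbp_mean, config.dbp_sd, 40, 130)
                if sbp > dbp + 10:
                    return sbp, dbp, True
        while True:  # untreated: must be elevated
            sbp = _truncated_normal(rng, 150.0, 10.0, 80, 220)
            dbp = _truncated_normal(rng, 85.0, 8.0, 40, 130)
            if sbp > dbp + 10 and (sbp >= 140.0 or dbp >= 90.0):
                return sbp, dbp, False
    while True:  # normotensive, unmedicated: strictly below both cutoffs
        sbp = _truncated_normal(rng, config.sbp_mean - 4, 10.0, 80, 139.9)
        dbp = _truncated_normal(rng, config.dbp_mean, 7.0, 40, 89.9)
        if sbp > dbp + 10:
            return sbp, dbp, False


def generate_cohort(config: CohortConfig) -> tuple[list[ParticipantRecord], GroundTruth]:
    """Draw the participant table and its generative ground truth.

    Deterministic given ``config.seed``.  Risk factors are independent
    Bernoulli draws at the configured prevalences; hypertension is made
    consistent with the emitted blood pressures and medication flag.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    link = config.cognition_link
    ids = [f"sub-{i + 1:03d}" for i in range(config.n_participants)]
    width = len(str(config.n_participants))

    records: list[ParticipantRecord] = []
    roi_cbf: dict[str, dict[str, float]] = {}
    risk_group: dict[str, str] = {}
    risk_count: dict[str, int] = {}
    frontal_base = config.roi_baseline_cbf["frontal"]
    parietal_base = config.roi_baseline_cbf["inferior_parietal"]
    mtl_base = config.roi_baseline_cbf["medial_temporal"]

    for pid in ids:
        age = _truncated_normal(rng, config.age_mean, config.age_sd,
                                low=config.age_min)
        sex = "female" if rng.random() < config.prop_female else "male"
        apoe4 = bool(rng.random() < config.prop_apoe4)
        flags = {name: bool(rng.random() < config.risk_prevalences[name])
                 for name in RISK_FACTOR_NAMES}
        sbp, dbp, on_meds = _draw_blood_pressure(rng, config,
                                                 flags["hypertension"])
        count = sum(flags.values())
        group = "high" if count >= 2 else "low"

        age_c = age - config.age_center
        is_male = 1.0 if sex == "male" else 0.0
        truths = {}
        for roi in ROI_NAMES:
            beta_int = (config.beta_interaction
                        if roi in config.interaction_rois else 0.0)
            mu = (config.roi_baseline_cbf[roi] + config.beta_sex * is_male
                  + config.beta_age_low * age_c
                  + (beta_int * age_c if group == "high" else 0.0)
                  + rng.normal(0.0, config.noise_sd(roi)))
            truths[roi] = float(np.clip(mu, 1.0, 199.0))

        drs = _truncated_normal(rng, config.drs_mean, config.drs_sd, high=144.0)
        if group == "high":
            driver = 0.5 * (truths["frontal"] + truths["inferior_parietal"])
            trails = (link.trails_mean
                      + link.trails_slope * (driver - 0.5 * (frontal_base + parietal_base))
                      + rng.normal(0.0, link.trails_noise_sd))
            cvlt = (link.cvlt_mean
                    + link.cvlt_slope * (truths["medial_temporal"] - mtl_base)
                    + rng.normal(0.0, link.cvlt_noise_sd))
        else:
            trails = link.trails_mean + rng.normal(0.0, link.trails_sd_low)
            cvlt = link.cvlt_mean + rng.normal(0.0, link.cvlt_sd_low)
        trails = max(trails, 20.0)
        cvlt = float(np.clip(cvlt, 0.0, 80.0))

        if rng.random() < config.prop_wml_available:
            wml = float(np.exp(rng.normal(
                config.wml_log_mean + config.wml_age_slope * age_c,
                config.wml_log_sd)))
        else:
            wml = None

        records.append(ParticipantRecord(
            id=pid, age=round(age, 2), sex=sex, apoe4=apoe4,
            sbp=round(sbp, 1), dbp=round(dbp, 1), antihypertensive=on_meds,
            diabetes=flags["diabetes"], cvd=flags["cvd"], afib=flags["afib"],
            tia_stroke=flags["tia_stroke"], smoker=flags["smoker"],
            drs_total=round(drs, 1), cvlt_trials_1_5=round(cvlt, 1),
            trails_b_seconds=round(trails, 1),
            wml_volume_mm3=None if wml is None else round(wml, 1)))
        roi_cbf[pid] = truths
        risk_group[pid] = group
        risk_count[pid] = count

    # emulate incomplete testing: drop Trails B for high-risk participants
    high_ids = [r.id for r in records if risk_group[r.id] == "high"]
    n_drop = min(config.n_trails_missing, len(high_ids))
    if n_drop > 0:
        for pid in rng.choice(high_ids, size=n_drop, replace=False):
            records[ids.index(str(pid))].trails_b_seconds = None

    truth = GroundTruth(
        roi_cbf=roi_cbf, risk_group=risk_group, risk_count=risk_count,
        coefficients={
            "beta_sex": config.beta_sex,
            "beta_age_low": config.beta_age_low,
            "beta_interaction": config.beta_interaction,
            "age_center": config.age_center,
        })
    del width
    return records, truth


# ---------------------------------------------------------------------------
# Phantom tissue maps

_BOX = 3          # subregion box edge length, voxels
_SPACING = 5      # lattice pitch; leaves a 2-voxel background gap
_MARGIN = 2

# placement order: 14 ROI subregions, then WM core and ventricle
_PHANTOM_STRUCTURES = [name for name, code in sorted(ATLAS_LABELS.items(),
                                                     key=lambda kv: kv[1])]


def _lattice_sites(grid_dims: tuple[int, int, int]):
    axes = [range(_MARGIN, dim - _BOX + 1, _SPACING) for dim in grid_dims]
    for z in axes[2]:
        for y in axes[1]:
            for x in axes[0]:
                yield x, y, z


def generate_tissue_maps(config: CohortConfig) -> TissueMaps:
    """Toy phantom standing in for segmentation outputs.

    Each ROI subregion is a contiguous GM-dominant box on a lattice;
    a WM-dominant core and a CSF-filled ventricle are placed the same
    way.  Boxes are separated by >= 2 voxels of background so the
    4 mm FWHM smoothing kernel cannot mix structures.
    """
    config.validate()
    dims = tuple(config.grid_dims)
    sites = list(_lattice_sites(dims))
    if len(sites) < len(_PHANTOM_STRUCTURES):
        raise SizingError(
            f"grid {dims} fits {len(sites)} structures; "
            f"{len(_PHANTOM_STRUCTURES)} required")

    gm = np.zeros(dims, dtype=np.float64)
    wm = np.zeros(dims, dtype=np.float64)
    csf = np.zeros(dims, dtype=np.float64)
    labels = np.zeros(dims, dtype=np.int16)

    for name, (x, y, z) in zip(_PHANTOM_STRUCTURES, sites):
        sl = (slice(x, x + _BOX), slice(y, y + _BOX), slice(z, z + _BOX))
        labels[sl] = ATLAS_LABELS[name]
        if name == "ventricle":
            csf[sl] = 1.0
        elif name == "white_matter_core":
            wm[sl] = 0.95
            gm[sl] = 0.03
        else:
            gm[sl] = 0.9
            wm[sl] = 0.1
    return TissueMaps(gm=gm, wm=wm, csf=csf, atlas_labels=labels,
                      voxel_size=config.voxel_size)


# ---------------------------------------------------------------------------
# Forward-modelled ASL acquisition

def _gain_field(dims: tuple[int, int, int], amplitude: float) -> np.ndarray:
    """Smooth multiplicative receive-coil field, mean exactly 1."""
    x, y, z = np.meshgrid(*(np.linspace(0, np.pi, d) for d in dims),
                          indexing="ij")
    g = 1.0 + amplitude * np.cos(x) * np.cos(y) * np.cos(0.5 * z)
    return g / g.mean()


def corrected_truth_volume(participant_id: str, truth: GroundTruth,
                           tissue: TissueMaps) -> np.ndarray:
    """Per-voxel true GM-referenced CBF implied by the ROI ground truth."""
    vol = np.zeros(tissue.atlas_labels.shape, dtype=np.float64)
    per_roi = truth.roi_cbf[participant_id]
    for roi_def in DEFAULT_ROIS:
        mask = np.isin(tissue.atlas_labels, list(roi_def.subregion_labels))
        vol[mask] = per_roi[roi_def.name]
    return vol


def generate_asl_dataset(participant: ParticipantRecord, truth: GroundTruth,
                         tissue: TissueMaps, config: CohortConfig,
                         rng: np.random.Generator | None = None) -> ASLDataset:
    """Forward-model one participant's tag/control acquisition.

    Uses the same QUIPSS II kinetics the quantifier inverts: the
    difference signal in a voxel on slice s is
    2*alpha*M0b*(f_unc/u)*TI1*exp(-TI2_s/T1b), where f_unc is the
    participant's true corrected CBF scaled down by (GM + 0.4*WM).
    Controls carry +dM/2, tags -dM/2 over a tissue baseline, plus a
    linear drift and white noise; the series is modulated by a smooth
    coil gain field emitted as the minimum-contrast scan.
    """
    config.validate()
    dims = tuple(config.grid_dims)
    if tissue.gm.shape != dims:
        raise DimensionError(f"tissue grid {tissue.gm.shape} != config grid {dims}")
    if rng is None:
        child = zlib.crc32(participant.id.encode()) & 0x7FFFFFFF
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, child]))
    qc = QuantConfig(fwhm=0.0)   # shared kinetic constants with the quantifier
    params = config.acquisition_params()

    corrected = corrected_truth_volume(participant.id, truth, tissue)
    wm_core = tissue.atlas_labels == ATLAS_LABELS["white_matter_core"]
    corrected[wm_core] = config.wm_core_cbf
    f_unc = corrected * (tissue.gm + qc.wm_gm_ratio_coef * tissue.wm)

    ti2s = config.ti2 + config.slice_time * np.arange(dims[2])
    decay = np.exp(-ti2s / qc.t1_blood)[np.newaxis, np.newaxis, :]
    dm = (2.0 * qc.inversion_efficiency * config.m0_blood
          * (f_unc / qc.unit_conversion) * config.ti1 * decay)

    baseline = (config.baseline_tissue_scale * config.m0_blood
                * (tissue.gm + tissue.wm))
    gain = _gain_field(dims, config.gain_amplitude)

    n_frames = 2 * config.n_pairs
    series = np.empty(dims + (n_frames,), dtype=np.float64)
    for t in range(n_frames):
        half = dm / 2.0 if t % 2 == 1 else -dm / 2.0   # tag first
        frame = gain * (baseline + half) + config.drift_slope * t
        if config.asl_noise_sd > 0:
            frame = frame + rng.normal(0.0, config.asl_noise_sd, size=dims)
        series[..., t] = frame

    csf_scan = np.full(dims, 0.05 * config.m0_blood)
    csf_scan[tissue.csf >= 0.9] = config.m0_blood / qc.csf_to_blood_scale
    min_contrast = 500.0 * gain
    return ASLDataset(series=series, csf_scan=csf_scan,
                      min_contrast_scan=min_contrast, params=params)
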