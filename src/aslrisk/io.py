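"""File interfaces: participant TSV, NIfTI volumes, JSON/YAML sidecars."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .risk import count_risk_factors
from .synthetic import CohortConfig, CognitionLink, GroundTruth, ParticipantRecord, TissueMaps

COHORT_COLUMNS = [
    "id", "age", "sex", "apoe4", "sbp", "dbp", "antihypertensive",
    "diabetes", "cvd", "afib", "tia_stroke", "smoker", "drs_total",
    "cvlt_trials_1_5", "trails_b_seconds", "wml_volume_mm3",
    "hypertension", "risk_count", "risk_group",
]


def cohort_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Participant table with appended hypertension/risk_count/risk_group."""
    rows = []
    for r in records:
        profile = count_risk_factors(r)
        row = dataclasses.asdict(r)
        row["hypertension"] = profile.hypertension
        row["risk_count"] = profile.count
        row["risk_group"] = profile.group
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cohort_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("apoe4", "antihypertensive", "diabetes", "cvd", "afib",
                "tia_stroke", "smoker", "hypertension"):
        if col in df:
            df[col] = df[col].astype(bool)
    return df


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return aff


def save_nifti(data: np.ndarray, voxel_size: float, path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size))
    nib.save(img, str(path))


def save_nifti_labels(labels: np.ndarray, voxel_size: float, path) -> None:
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), _affine(voxel_size))
    nib.save(img, str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def write_tissue_maps(tissue: TissueMaps, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("gm", "wm", "csf"):
        p = outdir / f"{name}.nii.gz"
        save_nifti(getattr(tissue, name), tissue.voxel_size, p)
        paths[name] = p
    p = outdir / "atlas_labels.nii.gz"
    save_nifti_labels(tissue.atlas_labels, tissue.voxel_size, p)
    paths["atlas_labels"] = p
    return paths


def read_tissue_maps(indir, voxel_size: float) -> TissueMaps:
    indir = Path(indir)
    return TissueMaps(
        gm=np.asarray(load_nifti(indir / "gm.nii.gz"), dtype=np.float64),
        wm=np.asarray(load_nifti(indir / "wm.nii.gz"), dtype=np.float64),
        csf=np.asarray(load_nifti(indir / "csf.nii.gz"), dtype=np.float64),
        atlas_labels=np.asarray(load_nifti(indir / "atlas_labels.nii.gz"),
                                dtype=np.int16),
        voxel_size=voxel_size)


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    d["risk_count"] = {k: int(v) for k, v in d["risk_count"].items()}
    return GroundTruth(**d)


def write_config(config: CohortConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["grid_dims"] = list(d["grid_dims"])
    d["interaction_rois"] = list(d["interaction_rois"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def read_config(path) -> CohortConfig:
    d = yaml.safe_load(Path(path).read_text())
    if "cognition_link" in d and isinstance(d["cognition_link"], dict):
        d["cognition_link"] = CognitionLink(**d["cognition_link"])
    if "grid_dims" in d:
        d["grid_dims"] = tuple(d["grid_dims"])
    if "interaction_rois" in d:
        d["interaction_rois"] = tuple(d["interaction_rois"])
    return CohortConfig(**d)
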