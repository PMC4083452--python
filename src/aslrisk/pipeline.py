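"""Orchestration: simulate -> quantify -> analyze as reproducible runs.

Every run writes a manifest recording the config hash, master seed and
a SHA-256 checksum per stage output, so identical (config, seed) pairs
can be verified byte-for-byte.  All randomness flows through seeds
derived from the master seed: the cohort generator draws from
SeedSequence([seed, 1]) and each participant's acquisition from
SeedSequence([seed, 2, crc32(participant id)]), so stages can be
re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as aio
from .quantify import QuantConfig, run_quantification
from .roi import DEFAULT_ROIS, build_roi_table, write_roi_table
from .stats import analyze_study, hierarchical_regression
from .synthetic import (CohortConfig, generate_asl_dataset, generate_cohort,
                        generate_tissue_maps)

PACKAGE_VERSION = "0.1.0"

MANIFEST_REQUIRED_KEYS = {"config_hash", "seed", "package_version", "stages",
                          "created_unix"}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str = PACKAGE_VERSION
    stages: list[dict] = field(default_factory=list)
    created_unix: float = field(default_factory=time.time)

    def add_stage(self, name: str, outputs: dict[str, Path]) -> None:
        self.stages.append({
            "name": name,
            "outputs": {str(p): _sha256(p) for p in outputs.values()},
        })

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def validate_manifest(d: dict) -> None:
    missing = MANIFEST_REQUIRED_KEYS - set(d)
    if missing:
        raise ValueError(f"manifest missing keys: {sorted(missing)}")
    for stage in d["stages"]:
        if not {"name", "outputs"} <= set(stage):
            raise ValueError(f"malformed stage entry: {stage}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def config_hash(config: CohortConfig) -> str:
    d = dataclasses.asdict(config)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_simulate(config: CohortConfig, outdir) -> RunManifest:
    """Emit cohort TSV, tissue/atlas NIfTI, per-participant ASL, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(config), seed=config.seed)

    cfg_path = outdir / "config.yaml"
    aio.write_config(config, cfg_path)

    records, truth = generate_cohort(config)
    cohort_path = outdir / "cohort.tsv"
    aio.write_cohort_tsv(aio.cohort_to_frame(records), cohort_path)
    truth_path = outdir / "ground_truth.json"
    aio.write_ground_truth(truth, truth_path)
    manifest.add_stage("cohort", {"config": cfg_path, "cohort": cohort_path,
                                  "truth": truth_path})

    tissue = generate_tissue_maps(config)
    tissue_paths = aio.write_tissue_maps(tissue, outdir / "tissue")
    manifest.add_stage("tissue", tissue_paths)

    asl_paths = {}
    for record in records:
        pdir = outdir / "asl" / record.id
        pdir.mkdir(parents=True, exist_ok=True)
        dataset = generate_asl_dataset(record, truth, tissue, config)
        aio.save_nifti(dataset.series, config.voxel_size, pdir / "series.nii.gz")
        aio.save_nifti(dataset.csf_scan, config.voxel_size, pdir / "csf.nii.gz")
        aio.save_nifti(dataset.min_contrast_scan, config.voxel_size,
                       pdir / "min_contrast.nii.gz")
        for stem in ("series", "csf", "min_contrast"):
            asl_paths[f"{record.id}/{stem}"] = pdir / f"{stem}.nii.gz"
    manifest.add_stage("asl", asl_paths)
    manifest.write(outdir / "manifest.json")
    return manifest


def quantify_cohort(records, truth, tissue, config: CohortConfig,
                    quant: QuantConfig | None = None) -> pd.DataFrame:
    """In-memory simulate-and-quantify: per-participant ROI mean table."""
    maps = {}
    for record in records:
        dataset = generate_asl_dataset(record, truth, tissue, config)
        maps[record.id] = run_quantification(dataset, tissue.gm, tissue.wm,
                                             tissue.csf, quant)
    return build_roi_table(maps, tissue.atlas_labels, DEFAULT_ROIS)


def run_quantify(simdir, outdir, quant: QuantConfig | None = None) -> Path:
    """Quantify every simulated participant; write the ROI mean table."""
    simdir, outdir = Path(simdir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = aio.read_config(simdir / "config.yaml")
    tissue = aio.read_tissue_maps(simdir / "tissue", config.voxel_size)
    from .quantify import ASLDataset  # local to avoid cycle at import time
    maps = {}
    for pdir in sorted((simdir / "asl").iterdir()):
        dataset = ASLDataset(
            series=aio.load_nifti(pdir / "series.nii.gz").astype(float),
            csf_scan=aio.load_nifti(pdir / "csf.nii.gz").astype(float),
            min_contrast_scan=aio.load_nifti(pdir / "min_contrast.nii.gz").astype(float),
            params=config.acquisition_params())
        maps[pdir.name] = run_quantification(dataset, tissue.gm, tissue.wm,
                                             tissue.csf, quant)
    table = build_roi_table(maps, tissue.atlas_labels, DEFAULT_ROIS)
    out = outdir / "roi_cbf.tsv"
    write_roi_table(table, out)
    return out


def recovery_report(roi_table: pd.DataFrame, cohort: pd.DataFrame,
                    truth) -> dict:
    """Compare estimated interaction slopes against the injected truth."""
    report = {"injected_beta_interaction": truth.coefficients["beta_interaction"],
              "rois": {}}
    wide = roi_table.pivot(index="participant_id", columns="roi",
                           values="mean_cbf")
    merged = cohort.set_index("id").join(wide, how="inner")
    sex01 = (merged["sex"] == "male").astype(float)
    risk01 = (merged["risk_group"] == "high").astype(float)
    for roi in sorted(wide.columns):
        res = hierarchical_regression(merged[roi], sex01,
                                      merged["apoe4"].astype(float),
                                      merged["age"], risk01)
        est = res.terms["age_x_risk"]
        report["rois"][roi] = {
            "estimated_B": est.B, "SE": est.SE, "p": est.p,
            "sign_matches_injection": bool(
                est.B * truth.coefficients["beta_interaction"] > 0)
            if truth.coefficients["beta_interaction"] != 0 else None,
        }
    return report


def run_full(config: CohortConfig, outdir,
             quant: QuantConfig | None = None) -> tuple[RunManifest, dict]:
    """Chain simulate -> quantify -> analyze; return manifest and bundle."""
    outdir = Path(outdir)
    manifest = run_simulate(config, outdir / "sim")
    roi_path = run_quantify(outdir / "sim", outdir / "quant", quant)
    manifest.add_stage("quantify", {"roi_table": roi_path})

    cohort = aio.read_cohort_tsv(outdir / "sim" / "cohort.tsv")
    roi_table = pd.read_csv(roi_path, sep="\t")
    truth = aio.read_ground_truth(outdir / "sim" / "ground_truth.json")

    bundle = analyze_study(cohort, roi_table)
    bundle["recovery"] = recovery_report(roi_table, cohort, truth)
    results_path = outdir / "results.json"
    results_path.write_text(json.dumps(bundle, indent=1))
    manifest.add_stage("analyze", {"results": results_path})
    manifest.write(outdir / "manifest.json")
    return manifest, bundle
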