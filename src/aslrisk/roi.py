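"""A-priori regions of interest and ROI-level CBF extraction.

Six regions are analyzed: four cortical (medial temporal, inferior
parietal, posteromedial, frontal) chosen for their vulnerability in
early Alzheimer's disease and aging, and two subcortical (thalamus,
caudate) chosen for their vulnerability to small-vessel disease.  Each
cortical ROI is the union of named subregions carried as integer atlas
labels; bilateral structures are single labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DimensionError

# Integer atlas codes for every subregion the ROI definitions use.
ATLAS_LABELS: dict[str, int] = {
    "hippocampus": 1,
    "parahippocampal_gyrus": 2,
    "uncus": 3,
    "supramarginal_gyrus": 4,
    "inferior_parietal_lobule": 5,
    "angular_gyrus": 6,
    "posterior_cingulate": 7,
    "precuneus": 8,
    "cuneus": 9,
    "anterior_cingulate": 10,
    "middle_frontal_gyrus": 11,
    "medial_frontal_gyrus": 12,
    "thalamus": 13,
    "caudate": 14,
    # non-ROI phantom structures
    "white_matter_core": 90,
    "ventricle": 91,
}

ROI_NAMES = (
    "medial_temporal",
    "inferior_parietal",
    "posteromedial",
    "frontal",
    "thalamus",
    "caudate",
)

CORTICAL_ROIS = ROI_NAMES[:4]


@dataclass(frozen=True)
class ROIDefinition:
    """A named ROI as a union of atlas subregion labels."""

    name: str
    subregion_labels: frozenset[int]

    def __post_init__(self) -> None:
        if not self.subregion_labels:
            raise ValueError(f"ROI {self.name!r} has no subregion labels")


def _roi(name: str, *subregions: str) -> ROIDefinition:
    return ROIDefinition(name, frozenset(ATLAS_LABELS[s] for s in subregions))


DEFAULT_ROIS: tuple[ROIDefinition, ...] = (
    _roi("medial_temporal", "hippocampus", "parahippocampal_gyrus", "uncus"),
    _roi("inferior_parietal", "supramarginal_gyrus", "inferior_parietal_lobule",
         "angular_gyrus"),
    _roi("posteromedial", "posterior_cingulate", "precuneus", "cuneus"),
    _roi("frontal", "anterior_cingulate", "middle_frontal_gyrus",
         "medial_frontal_gyrus"),
    _roi("thalamus", "thalamus"),
    _roi("caudate", "caudate"),
)


def roi_mean_cbf(pmap, atlas_labels: np.ndarray, roi: ROIDefinition):
    """Mean corrected CBF over the ROI's valid voxels.

    Returns ``(mean, n_valid)``; the mean is ``nan`` (a flagged missing
    value, never zero) when the ROI contains no valid voxel.
    """
    if atlas_labels.shape != pmap.cbf.shape:
        raise DimensionError(
            f"atlas grid {atlas_labels.shape} != map grid {pmap.cbf.shape}")
    in_roi = np.isin(atlas_labels, list(roi.subregion_labels))
    sel = in_roi & pmap.valid
    n_valid = int(sel.sum())
    if n_valid == 0:
        return math.nan, 0
    return float(pmap.cbf[sel].mean()), n_valid


def build_roi_table(
    maps: Mapping[str, object],
    atlas_labels: np.ndarray,
    definitions: Iterable[ROIDefinition] = DEFAULT_ROIS,
) -> pd.DataFrame:
    """Long-format table of per-participant, per-ROI mean corrected CBF.

    One row per participant x ROI, deterministically ordered by the
    mapping's iteration order then ROI definition order.  Participants
    whose ROIs are all invalid are retained with missing values.
    """
    rows = []
    for pid, pmap in maps.items():
        for roi in definitions:
            mean, n_valid = roi_mean_cbf(pmap, atlas_labels, roi)
            rows.append({"participant_id": pid, "roi": roi.name,
                         "mean_cbf": mean, "n_valid_voxels": n_valid})
    return pd.DataFrame(rows, columns=["participant_id", "roi", "mean_cbf",
                                       "n_valid_voxels"])


def write_roi_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_roi_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
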