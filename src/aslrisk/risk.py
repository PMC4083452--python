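"""Vascular risk factor scoring and burden grouping.

Six binary factors drawn from the Framingham Stroke Risk Profile are
counted: hypertension, diabetes, history of cardiovascular disease,
atrial fibrillation, TIA/minor stroke, and current smoking.  Each is
coded 0/1 and participants are dichotomized into a low-burden group
(0-1 factors) and a high-burden group (>= 2 factors).  Hypertension is
always derived from the measured pressures and medication flag, never
taken from a precomputed indicator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import MissingDataError, StatsError

HIGH_RISK_THRESHOLD = 2


@dataclass(frozen=True)
class RiskProfile:
    hypertension: bool
    diabetes: bool
    cvd: bool
    afib: bool
    tia_stroke: bool
    smoker: bool
    count: int
    group: str          # "low" | "high"


def is_hypertensive(sbp: float | None, dbp: float | None,
                    on_meds: bool | None) -> bool:
    """SBP >= 140 mm Hg, DBP >= 90 mm Hg, or antihypertensive use."""
    if on_meds is None:
        raise MissingDataError("antihypertensive medication flag is missing")
    if on_meds:
        return True
    if sbp is None or dbp is None:
        raise MissingDataError(
            "blood pressure missing and participant not on antihypertensives")
    if sbp <= 0 or dbp <= 0:
        raise MissingDataError(f"non-positive blood pressure {sbp}/{dbp}")
    return sbp >= 140.0 or dbp >= 90.0


def count_risk_factors(record) -> RiskProfile:
    """Score a participant's six risk indicators and assign a group."""
    flags = {"hypertension": is_hypertensive(record.sbp, record.dbp,
                                             record.antihypertensive)}
    for name in ("diabetes", "cvd", "afib", "tia_stroke", "smoker"):
        value = getattr(record, name, None)
        if value is None:
            raise MissingDataError(f"risk indicator {name!r} is unresolvable")
        flags[name] = bool(value)
    count = sum(flags.values())
    return RiskProfile(**flags, count=count,
                       group="high" if count >= HIGH_RISK_THRESHOLD else "low")


def group_cohort(records):
    """Partition a cohort into low/high burden groups.

    Returns ``(low_ids, high_ids, frequency)`` where ``frequency`` maps
    number-of-risk-factors -> participant count.  The partition is
    exhaustive and disjoint.
    """
    if not records:
        raise StatsError("cannot group an empty cohort")
    low, high, freq = [], [], Counter()
    for record in records:
        profile = count_risk_factors(record)
        freq[profile.count] += 1
        (high if profile.group == "high" else low).append(record.id)
    return low, high, dict(sorted(freq.items()))
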