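"""Published demographic summaries of the 71-participant study cohort.

These are the printed low/high vascular-risk group summaries the
synthetic generator's defaults emulate.  They serve as worked inputs
for the summary-statistic routines: the t and chi-square values the
source study reports can be recomputed from them exactly (pooled-
variance t; Pearson chi-square without continuity correction).

Continuous rows are (mean, sd, n) per group; categorical rows are
(positive, negative) counts per group.  The CVLT row is retained for
completeness but its printed t statistic is not reproducible from the
printed T-score summaries (it was likely computed on raw trial scores);
see docs/methods.md.
"""

from __future__ import annotations

from .stats import SummaryStat

N_LOW = 55
N_HIGH = 16

# variable -> ((low mean, low sd, low n), (high mean, high sd, high n))
CONTINUOUS_SUMMARIES: dict[str, tuple[tuple[float, float, int],
                                      tuple[float, float, int]]] = {
    "age_years": ((74.73, 7.92, 55), (75.94, 7.35, 16)),
    "education_years": ((16.31, 2.41, 55), (15.13, 2.03, 16)),
    "drs_total": ((139.82, 3.94, 55), (139.56, 4.50, 16)),
    "cvlt_trials_1_5_tscore": ((46.43, 11.87, 55), (46.13, 11.74, 16)),
    # one high-risk participant did not complete the Trail Making Test
    "trails_b_seconds": ((80.57, 29.81, 55), (78.67, 34.19, 15)),
    "geriatric_depression": ((3.40, 3.82, 55), (4.27, 3.54, 16)),
    "systolic_bp": ((129.16, 16.21, 55), (130.06, 12.45, 16)),
    "diastolic_bp": ((77.05, 9.30, 55), (71.31, 8.26, 16)),
}

# variable -> ((low positive, low negative), (high positive, high negative))
CATEGORICAL_COUNTS: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "women": ((33, 22), (8, 8)),
    # two low-risk participants were missing APOE genotype data
    "apoe4_carrier": ((16, 37), (9, 7)),
    "antihypertensive_meds": ((23, 32), (14, 2)),
    "hypertension": ((27, 28), (15, 1)),
    "diabetes": ((1, 54), (4, 12)),
    "cvd": ((0, 55), (7, 9)),
    "afib": ((3, 52), (3, 13)),
    "smoker": ((2, 53), (0, 16)),
    "tia_stroke": ((0, 55), (5, 11)),
}

# Distribution of the number of vascular risk factors across the cohort.
RISK_COUNT_DISTRIBUTION: dict[int, int] = {0: 22, 1: 33, 2: 14, 3: 2}


def continuous_summary_pair(variable: str) -> tuple[SummaryStat, SummaryStat]:
    """The (low, high) SummaryStat pair for a continuous variable."""
    (ml, sl, nl), (mh, sh, nh) = CONTINUOUS_SUMMARIES[variable]
    return (SummaryStat("low", nl, ml, sl), SummaryStat("high", nh, mh, sh))


def categorical_table(variable: str) -> list[list[int]]:
    """The 2x2 (group x indicator) count table for a categorical variable."""
    (lp, ln), (hp, hn) = CATEGORICAL_COUNTS[variable]
    return [[lp, ln], [hp, hn]]
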