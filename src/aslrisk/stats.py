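"""Statistical battery for the age x vascular-risk CBF study.

Implements the study's analysis plan: independent-samples pooled-
variance t-tests and Pearson chi-square tests (no continuity
correction) for group comparisons; a three-block hierarchical OLS
regression per ROI quantifying moderation of the age->CBF slope by
vascular risk burden via incremental R^2; and risk-stratified bivariate
Pearson correlations between regional CBF and cognition.  Alpha is 0.05
throughout with no multiple-testing correction, mirroring the design
this package emulates.

The hierarchical model enters sex and APOE e4 carrier status in block
1, age and risk group in block 2, and the age x risk product in block
3; Delta R^2 for block k is R^2_k - R^2_{k-1}, and each term's
coefficient is reported from the block in which it first enters (the
conventional moderation-table layout), with full-model coefficients
retained for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DataJoinError, StatsError

ALPHA = 0.05

ROI_COGNITION_PAIRS = (
    ("cvlt_trials_1_5", "medial_temporal"),
    ("cvlt_trials_1_5", "posteromedial"),
    ("trails_b_seconds", "frontal"),
    ("trails_b_seconds", "inferior_parietal"),
)


@dataclass(frozen=True)
class SummaryStat:
    """Group summary of one continuous variable."""

    group: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise StatsError(f"group {self.group!r} needs n >= 2, got {self.n}")
        if self.sd < 0:
            raise StatsError("sd must be >= 0")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class TermEstimate:
    B: float
    SE: float
    p: float
    block: int


@dataclass
class BlockRegressionResult:
    """Three-block hierarchical OLS fit."""

    n: int
    delta_r2: dict[int, float]
    terms: dict[str, TermEstimate]          # from the block of first entry
    full_model: dict[str, TermEstimate]     # all terms in the block-3 model
    total_r2: float
    n_dropped: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["delta_r2"] = {str(k): v for k, v in d["delta_r2"].items()}
        return d


@dataclass(frozen=True)
class CorrelationResult:
    subgroup: str
    r: float
    p: float
    n: int


def two_sample_t_summary(a: SummaryStat, b: SummaryStat) -> TTestResult:
    """Pooled-variance Student t-test from group summaries.

    sp^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2);
    t = (m1-m2) / (sp sqrt(1/n1 + 1/n2)); df = n1+n2-2; two-sided p.
    """
    t, p = sps.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                    equal_var=True)
    return TTestResult(t=float(t), df=a.n + b.n - 2, p=float(p))


def chi_square_2x2(counts) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Computes sum (O - E)^2 / E with expected counts from the margins;
    df = 1.  Both margins must be positive.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2, 2):
        raise StatsError(f"expected a 2x2 table, got shape {obs.shape}")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise StatsError("counts must be non-negative integers")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows <= 0).any() or (cols <= 0).any():
        raise StatsError("both margins must be positive")
    expected = np.outer(rows, cols) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return ChiSquareResult(chi2=chi2, df=1, p=float(sps.chi2.sf(chi2, 1)))


def _fit_r2(y: np.ndarray, X: np.ndarray):
    model = sm.OLS(y, X).fit()
    return model, float(model.rsquared)


def hierarchical_regression(outcome, sex, apoe4, age, risk,
                            center_age: bool = False) -> BlockRegressionResult:
    """Three-block moderation model for one outcome.

    Block 1: sex, APOE e4; block 2: + age, risk group; block 3:
    + age x risk.  ``sex`` and ``risk`` are 0/1 indicators, ``apoe4``
    boolean-like.  Rows with any missing value are dropped listwise.
    Age enters uncentered by default (a centering switch shifts the
    main-effect coefficients but not the interaction test).
    """
    df = pd.DataFrame({
        "outcome": np.asarray(outcome, dtype=float),
        "sex": np.asarray(sex, dtype=float),
        "apoe4": np.asarray(apoe4, dtype=float),
        "age": np.asarray(age, dtype=float),
        "risk": np.asarray(risk, dtype=float),
    })
    n_before = len(df)
    df = df.dropna()
    n = len(df)
    if n <= 6:
        raise StatsError(f"n = {n} too small for the 6-parameter block-3 model")
    age_v = df["age"].to_numpy()
    if center_age:
        age_v = age_v - age_v.mean()
    y = df["outcome"].to_numpy()
    ones = np.ones(n)
    X1 = np.column_stack([ones, df["sex"], df["apoe4"]])
    X2 = np.column_stack([X1, age_v, df["risk"]])
    X3 = np.column_stack([X2, age_v * df["risk"].to_numpy()])
    if np.linalg.matrix_rank(X3) < X3.shape[1]:
        raise StatsError("design matrix is rank deficient (collinear terms)")

    m1, r2_1 = _fit_r2(y, X1)
    m2, r2_2 = _fit_r2(y, X2)
    m3, r2_3 = _fit_r2(y, X3)

    names = ["const", "sex", "apoe4", "age", "risk", "age_x_risk"]

    def term(model, idx, block):
        return TermEstimate(B=float(model.params[idx]),
                            SE=float(model.bse[idx]),
                            p=float(model.pvalues[idx]), block=block)

    terms = {
        "sex": term(m1, 1, 1),
        "apoe4": term(m1, 2, 1),
        "age": term(m2, 3, 2),
        "risk": term(m2, 4, 2),
        "age_x_risk": term(m3, 5, 3),
    }
    full = {name: term(m3, i, 3) for i, name in enumerate(names)}
    return BlockRegressionResult(
        n=n,
        delta_r2={1: r2_1, 2: r2_2 - r2_1, 3: r2_3 - r2_2},
        terms=terms, full_model=full, total_r2=r2_3,
        n_dropped=n_before - n)


def stratified_correlation(x, y, groups):
    """Pearson r per risk subgroup on pairwise-complete observations.

    Returns ``(results, notices)``: a dict subgroup -> CorrelationResult
    (or None when skipped) and human-readable notices for skipped or
    degenerate subgroups (n < 3, zero variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    results: dict[str, CorrelationResult | None] = {}
    notices: list[str] = []
    for g in ("low", "high"):
        sel = (groups == g) & ~np.isnan(x) & ~np.isnan(y)
        n = int(sel.sum())
        if n < 3:
            results[g] = None
            notices.append(f"subgroup {g!r}: skipped, only {n} complete pairs")
            continue
        if np.std(x[sel]) == 0 or np.std(y[sel]) == 0:
            results[g] = None
            notices.append(f"subgroup {g!r}: undefined r (zero variance)")
            continue
        r, p = sps.pearsonr(x[sel], y[sel])
        results[g] = CorrelationResult(subgroup=g, r=float(r), p=float(p), n=n)
    return results, notices


# ---------------------------------------------------------------------------
# Full study battery

CONTINUOUS_COMPARISONS = ("age", "drs_total", "cvlt_trials_1_5",
                          "trails_b_seconds", "sbp", "dbp")
CATEGORICAL_COMPARISONS = ("sex", "apoe4", "antihypertensive", "hypertension",
                           "diabetes", "cvd", "afib", "tia_stroke", "smoker")


def _summaries(values: pd.Series, groups: pd.Series):
    out = {}
    for g in ("low", "high"):
        v = values[groups == g].dropna()
        out[g] = SummaryStat(group=g, n=len(v), mean=float(v.mean()),
                             sd=float(v.std(ddof=1)))
    return out


def group_comparison_table(cohort: pd.DataFrame) -> dict:
    """Per-variable low/high comparisons: pooled t or Pearson chi-square."""
    groups = cohort["risk_group"]
    table: dict[str, dict] = {}
    for var in CONTINUOUS_COMPARISONS:
        if var not in cohort:
            continue
        summ = _summaries(cohort[var], groups)
        res = two_sample_t_summary(summ["low"], summ["high"])
        table[var] = {"kind": "t",
                      "low": asdict(summ["low"]), "high": asdict(summ["high"]),
                      "t": abs(res.t), "df": res.df, "p": res.p}
    for var in CATEGORICAL_COMPARISONS:
        if var not in cohort:
            continue
        v = cohort[var]
        pos = v == "female" if var == "sex" else v.astype(bool)
        counts = [[int((pos & (groups == g)).sum()),
                   int((~pos & (groups == g)).sum())] for g in ("low", "high")]
        try:
            res = chi_square_2x2(counts)
            table[var] = {"kind": "chi2", "counts": counts,
                          "chi2": res.chi2, "df": res.df, "p": res.p}
        except StatsError as exc:
            table[var] = {"kind": "chi2", "counts": counts, "chi2": None,
                          "p": None, "notice": str(exc)}
    return table


def analyze_study(cohort: pd.DataFrame, roi_table: pd.DataFrame,
                  center_age: bool = False) -> dict:
    """Run the full analysis battery and return a JSON-serializable bundle.

    Produces (a) the low/high group-comparison table, (b) the three-
    block hierarchical regression for each of the six ROIs, (c) the
    same model with white-matter-lesion volume as the outcome plus a
    standardized age slope, and (d) risk-stratified CBF-cognition
    correlations (CVLT vs medial-temporal and posteromedial CBF;
    Trails B vs frontal and inferior-parietal CBF).
    """
    required = {"id", "sex", "apoe4", "age", "risk_group"}
    if not required <= set(cohort.columns):
        raise DataJoinError(f"cohort table missing columns "
                            f"{sorted(required - set(cohort.columns))}")
    orphans = sorted(set(roi_table["participant_id"]) - set(cohort["id"]))
    if orphans:
        raise DataJoinError(f"ROI table has orphan participant ids: {orphans}")

    wide = roi_table.pivot(index="participant_id", columns="roi",
                           values="mean_cbf")
    merged = cohort.set_index("id").join(wide, how="inner").reset_index()
    merged = merged.sort_values("id").reset_index(drop=True)

    sex01 = (merged["sex"] == "male").astype(float)
    apoe = merged["apoe4"].astype(float)
    risk01 = (merged["risk_group"] == "high").astype(float)

    roi_regressions = {}
    for roi in sorted(wide.columns):
        res = hierarchical_regression(merged[roi], sex01, apoe, merged["age"],
                                      risk01, center_age=center_age)
        roi_regressions[roi] = res.to_dict()

    wml_result = None
    if "wml_volume_mm3" in merged and merged["wml_volume_mm3"].notna().sum() > 8:
        res = hierarchical_regression(merged["wml_volume_mm3"], sex01, apoe,
                                      merged["age"], risk01,
                                      center_age=center_age)
        sub = merged.dropna(subset=["wml_volume_mm3"])
        std_beta = (res.full_model["age"].B * sub["age"].std(ddof=1)
                    / sub["wml_volume_mm3"].std(ddof=1))
        wml = res.to_dict()
        wml["age_standardized_beta"] = float(std_beta)
        wml_result = wml

    correlations = []
    for cog, roi in ROI_COGNITION_PAIRS:
        if cog not in merged or roi not in merged:
            continue
        results, notices = stratified_correlation(
            merged[roi], merged[cog], merged["risk_group"])
        correlations.append({
            "cognition": cog, "roi": roi,
            "subgroups": {g: (asdict(r) if r else None)
                          for g, r in results.items()},
            "notices": notices})

    return {
        "alpha": ALPHA,
        "n": int(len(merged)),
        "group_comparison": group_comparison_table(merged),
        "roi_regressions": roi_regressions,
        "wml_regression": wml_result,
        "correlations": correlations,
    }
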