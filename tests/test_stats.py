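"""Group comparisons, hierarchical moderation models and correlations."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from aslrisk.errors import DataJoinError, StatsError
from aslrisk.stats import (SummaryStat, analyze_study, chi_square_2x2,
                           hierarchical_regression, stratified_correlation,
                           two_sample_t_summary)
from aslrisk import io as aio
from aslrisk.roi import ROI_NAMES


class TestSummaryTTest:
    def test_matches_raw_data_t_test(self, rng):
        """Pooled t from summaries equals scipy's raw-data Student t to
        1e-10 when the summaries are computed from the same raw data."""
        a = rng.normal(50, 8, size=23)
        b = rng.normal(47, 10, size=17)
        res = two_sample_t_summary(
            SummaryStat("low", len(a), a.mean(), a.std(ddof=1)),
            SummaryStat("high", len(b), b.mean(), b.std(ddof=1)))
        t_raw, p_raw = sps.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(t_raw, abs=1e-10)
        assert res.p == pytest.approx(p_raw, abs=1e-10)
        assert res.df == 38

    def test_identical_summaries_give_zero(self):
        s = SummaryStat("low", 10, 5.0, 1.0)
        assert two_sample_t_summary(s, SummaryStat("high", 10, 5.0, 1.0)).t == 0.0

    def test_small_group_rejected(self):
        with pytest.raises(StatsError):
            SummaryStat("low", 1, 5.0, 1.0)


class TestChiSquare:
    def test_proportional_table_is_zero(self):
        res = chi_square_2x2([[10, 20], [5, 10]])
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_scipy_contingency(self, rng):
        for _ in range(50):
            table = rng.integers(1, 30, size=(2, 2))
            mine = chi_square_2x2(table)
            ref_chi2, ref_p, ref_df, _ = sps.chi2_contingency(table,
                                                              correction=False)
            assert mine.chi2 == pytest.approx(ref_chi2, rel=1e-12)
            assert mine.p == pytest.approx(ref_p, rel=1e-9)
            assert mine.df == ref_df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(StatsError):
            chi_square_2x2([[0, 0], [5, 10]])
        with pytest.raises(StatsError):
            chi_square_2x2([[0, 5], [0, 10]])


def _numpy_r2(y, X):
    """Independent R^2 oracle: explicit least-squares projection."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))


class TestHierarchicalRegression:
    def test_noiseless_linear_outcome_recovered(self, rng):
        age = rng.uniform(65, 95, size=40)
        sex = rng.integers(0, 2, size=40)
        apoe = rng.integers(0, 2, size=40)
        risk = rng.integers(0, 2, size=40)
        y = 2.0 + 3.0 * age
        res = hierarchical_regression(y, sex, apoe, age, risk)
        assert res.terms["age"].B == pytest.approx(3.0, abs=1e-8)
        assert res.total_r2 == pytest.approx(1.0, abs=1e-10)

    def test_delta_r2_additivity_and_against_numpy_oracle(self, rng):
        n = 80
        sex = rng.integers(0, 2, n).astype(float)
        apoe = rng.integers(0, 2, n).astype(float)
        age = rng.uniform(65, 95, n)
        risk = rng.integers(0, 2, n).astype(float)
        y = 50 - 0.5 * age + 4 * sex + rng.normal(0, 5, n)
        res = hierarchical_regression(y, sex, apoe, age, risk)
        assert all(v >= -1e-12 for v in res.delta_r2.values())
        assert sum(res.delta_r2.values()) == pytest.approx(res.total_r2,
                                                           abs=1e-10)
        X3 = np.column_stack([np.ones(n), sex, apoe, age, risk, age * risk])
        assert res.total_r2 == pytest.approx(_numpy_r2(y, X3), abs=1e-10)

    def test_orthogonal_predictors_decompose_marginally(self):
        """With mutually orthogonal centered predictors, each block's
        Delta R^2 equals the summed marginal R^2 of its terms."""
        n = 8
        sex = np.array([1, 1, 1, 1, -1, -1, -1, -1], dtype=float)
        apoe = np.array([1, 1, -1, -1, 1, 1, -1, -1], dtype=float)
        age = np.array([1, -1, 1, -1, 1, -1, 1, -1], dtype=float)
        risk = np.array([1, -1, -1, 1, -1, 1, 1, -1], dtype=float)
        inter = age * risk
        y = 1.0 * sex + 2.0 * apoe + 3.0 * age + 0.5 * risk + 0.25 * inter
        res = hierarchical_regression(y, sex, apoe, age, risk)
        tss = ((y - y.mean()) ** 2).sum()

        def marginal(x):
            return (x @ y) ** 2 / (x @ x) / tss

        assert res.delta_r2[1] == pytest.approx(marginal(sex) + marginal(apoe),
                                                abs=1e-10)
        assert res.delta_r2[2] == pytest.approx(marginal(age) + marginal(risk),
                                                abs=1e-10)
        assert res.delta_r2[3] == pytest.approx(marginal(inter), abs=1e-10)

    def test_listwise_deletion_and_rank_deficiency(self, rng):
        n = 30
        age = rng.uniform(65, 95, n)
        y = rng.normal(size=n)
        y[3] = np.nan
        res = hierarchical_regression(y, rng.integers(0, 2, n),
                                      rng.integers(0, 2, n), age,
                                      rng.integers(0, 2, n))
        assert res.n == n - 1 and res.n_dropped == 1
        with pytest.raises(StatsError):
            hierarchical_regression(y, np.zeros(n), np.zeros(n), age,
                                    np.zeros(n))

    def test_centering_leaves_interaction_test_unchanged(self, rng):
        n = 60
        sex = rng.integers(0, 2, n)
        apoe = rng.integers(0, 2, n)
        age = rng.uniform(65, 95, n)
        risk = rng.integers(0, 2, n)
        y = 50 - 0.8 * (age - 75) * risk + rng.normal(0, 5, n)
        plain = hierarchical_regression(y, sex, apoe, age, risk)
        centered = hierarchical_regression(y, sex, apoe, age, risk,
                                           center_age=True)
        assert plain.terms["age_x_risk"].B == pytest.approx(
            centered.terms["age_x_risk"].B, abs=1e-9)
        assert plain.terms["age_x_risk"].p == pytest.approx(
            centered.terms["age_x_risk"].p, abs=1e-9)
        assert plain.delta_r2[3] == pytest.approx(centered.delta_r2[3],
                                                  abs=1e-10)


class TestStratifiedCorrelation:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        groups = np.array(["high"] * 10)
        res, notices = stratified_correlation(x, 2 * x + 1, groups)
        assert res["high"].r == pytest.approx(1.0)
        assert res["low"] is None and any("low" in n for n in notices)

    def test_zero_variance_reported_missing(self):
        x = np.ones(8)
        y = np.arange(8.0)
        res, notices = stratified_correlation(x, y, np.array(["low"] * 8))
        assert res["low"] is None
        assert any("zero variance" in n for n in notices)

    def test_generator_link_detected_in_high_risk_group(self):
        """At the default effect size the high-risk subgroup shows a
        negative Trails-B vs frontal-CBF correlation at n = 500."""
        from aslrisk.synthetic import CohortConfig, generate_cohort
        records, truth = generate_cohort(CohortConfig(n_participants=500,
                                                      seed=11))
        frame = aio.cohort_to_frame(records)
        cbf = [truth.roi_cbf[r.id]["frontal"] for r in records]
        res, _ = stratified_correlation(cbf, frame["trails_b_seconds"],
                                        frame["risk_group"])
        assert res["high"].r < 0 and res["high"].p < 0.05


@pytest.fixture(scope="module")
def bundle(study_cohort):
    config, records, truth = study_cohort
    cohort = aio.cohort_to_frame(records)
    rows = [{"participant_id": r.id, "roi": roi,
             "mean_cbf": truth.roi_cbf[r.id][roi], "n_valid_voxels": 81}
            for r in records for roi in ROI_NAMES]
    return analyze_study(cohort, pd.DataFrame(rows))


class TestAnalyzeStudy:
    def test_bundle_covers_all_analyses(self, bundle):
        assert set(bundle["roi_regressions"]) == set(ROI_NAMES)
        assert bundle["n"] == 71
        assert len(bundle["correlations"]) == 4
        assert bundle["wml_regression"] is not None
        assert bundle["wml_regression"]["age_standardized_beta"] > 0

    def test_bundle_serializes_to_json_and_reloads_equal(self, bundle):
        text = json.dumps(bundle, indent=1)
        assert json.loads(text) == json.loads(json.dumps(json.loads(text)))

    def test_orphan_roi_rows_rejected(self, study_cohort):
        _, records, truth = study_cohort
        cohort = aio.cohort_to_frame(records)
        rows = [{"participant_id": "sub-999", "roi": "frontal",
                 "mean_cbf": 50.0, "n_valid_voxels": 10}]
        with pytest.raises(DataJoinError, match="sub-999"):
            analyze_study(cohort, pd.DataFrame(rows))
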