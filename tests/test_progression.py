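"""Group statistics, correlations, subset selection and longitudinal tests."""

import numpy as np
import pandas as pd
import pytest

import tcrm
from tcrm.progression import (
    CorrelationMethod,
    GroupTest,
    adjusted_r2,
    best_subset_by_adjusted_r2,
    compare_groups,
    correlate,
    longitudinal_compare,
)
from tcrm.scoring import score_cohort


class TestCompareGroups:
    def test_identical_constant_groups(self):
        r = compare_groups([1.0] * 4, [1.0] * 4, GroupTest.MANN_WHITNEY)
        assert r.p_value == 1.0

    def test_zero_variance_separation(self):
        r = compare_groups([0.0] * 4, [1.0] * 4, GroupTest.WELCH_T)
        assert r.exact_separation
        assert np.isinf(r.statistic)

    def test_welch_matches_scipy_and_sem(self):
        from scipy import stats
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 20), rng.normal(1, 2, 25)
        r = compare_groups(a, b, GroupTest.WELCH_T)
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        assert r.statistic == pytest.approx(stat)
        assert r.p_value == pytest.approx(p)
        assert r.sem_a == pytest.approx(a.std(ddof=1) / np.sqrt(20))

    @pytest.mark.parametrize("test", [GroupTest.WELCH_T,
                                      GroupTest.MANN_WHITNEY])
    def test_type_i_error_near_nominal(self, test):
        """Null simulation: rejection rate at alpha=0.05 is ~5%."""
        rng = np.random.default_rng(123)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a, b = rng.normal(size=50), rng.normal(size=50)
            if compare_groups(a, b, test).p_value < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.02)


class TestCorrelate:
    def test_linear_pearson(self):
        x = np.arange(10.0)
        r = correlate(x, 2 * x + 1, CorrelationMethod.PEARSON)
        assert r.r == pytest.approx(1.0)

    def test_monotone_cubic_spearman(self):
        x = np.linspace(-2, 2, 15)
        y = x ** 3
        assert correlate(x, y, CorrelationMethod.SPEARMAN).r == pytest.approx(1.0)
        assert correlate(x, y, CorrelationMethod.PEARSON).r < 1.0

    def test_bivariate_normal_simulation_recovers_rho(self):
        rng = np.random.default_rng(7)
        rho, n, reps = 0.72, 49, 500
        rs = []
        for _ in range(reps):
            x = rng.normal(size=n)
            y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
            rs.append(correlate(x, y).r)
        assert np.mean(rs) == pytest.approx(rho, abs=0.03)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [1.0, 2.0])


class TestAdjustedR2:
    def test_exact_fit(self):
        y = np.array([0, 0, 1, 1, 0, 1], dtype=float)
        assert adjusted_r2(y, 2 * y - 1) == pytest.approx(1.0)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(4)
        y = np.repeat([0.0, 1.0], 500)
        x = rng.normal(size=1000)
        assert abs(adjusted_r2(y, x)) < 0.01

    def test_matches_normal_equations_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(24)
        y = rng.binomial(1, 0.5, 24).astype(float)
        y[0] = 1 - y[0] if y.min() == y.max() else y[0]
        x = rng.normal(size=(24, 3)) + y[:, None]
        got = adjusted_r2(y, x)
        ref = sm.OLS(y, sm.add_constant(x)).fit().rsquared_adj
        assert got == pytest.approx(ref, abs=1e-12)

    def test_undefined_when_saturated(self):
        with pytest.raises(ValueError):
            adjusted_r2(np.arange(4.0), np.ones((4, 3)))


class TestBestSubset:
    def test_planted_two_gene_truth_noise_free(self):
        rng = np.random.default_rng(0)
        n = 24
        y = np.repeat([0, 1], n // 2).astype(float)
        u = rng.normal(size=n)
        x = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("ABCDE"))
        # y = (B + D)/2 exactly; neither planted gene suffices alone
        x["B"] = y + u
        x["D"] = y - u
        res = best_subset_by_adjusted_r2(x, y)
        assert set(res.best_subset) == {"B", "D"}
        assert res.best_adjusted_r2 == pytest.approx(1.0, abs=1e-9)

    def test_search_log_exhaustive_and_consistent(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 12).astype(float)
        x = pd.DataFrame(
            rng.normal(size=(24, 11)), columns=list(tcrm.CRM_GENES)
        )
        res = best_subset_by_adjusted_r2(x, y)
        assert len(res.search_log) == 2 ** 11 - 1
        # reported best matches an independent re-scan of the log
        idx = res.search_log["adjusted_r2"].idxmax()
        assert res.search_log.loc[idx, "adjusted_r2"] == pytest.approx(
            res.best_adjusted_r2)
        # pure noise: no large explanatory power, small subsets competitive
        assert res.best_adjusted_r2 < 0.6
        assert len(res.per_gene_single_r2) == 11

    def test_adjusted_never_exceeds_plain_r2(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 15).astype(float)
        x = rng.normal(size=(30, 4)) + 0.5 * y[:, None]
        adj = adjusted_r2(y, x)
        # plain R^2 from the same normal equations
        yc = y - y.mean()
        xc = x - x.mean(axis=0)
        coef, *_ = np.linalg.lstsq(xc, yc, rcond=None)
        r2 = 1 - ((yc - xc @ coef) ** 2).sum() / (yc ** 2).sum()
        assert adj <= r2


class TestLongitudinal:
    def test_default_cohort_progressors_score_higher(self, default_cohort,
                                                     default_expression):
        scores = score_cohort(default_expression)
        out = longitudinal_compare(scores, default_cohort.samples)
        for key in ("p_vs_np_6m", "p_vs_np_24m"):
            assert out[key].mean_a > out[key].mean_b
        assert out["paired_6_to_24_progressor"]["n"] == 12

    def test_identical_pairs_give_p_one(self):
        samples = pd.DataFrame({
            "sample_id": ["a6", "a24", "b6", "b24", "c6", "c24", "d6", "d24"],
            "patient_id": ["A", "A", "B", "B", "C", "C", "D", "D"],
            "phenotype": ["PIFTA_NP"] * 4 + ["PIFTA_P"] * 4,
            "timepoint_months": [6.0, 24.0] * 4,
            "split": "LONGITUDINAL",
            "banff_t": pd.array([None] * 8, dtype="Float64"),
            "banff_i": pd.array([None] * 8, dtype="Float64"),
        })
        scores = pd.DataFrame({
            "sample_id": samples["sample_id"],
            "subset_name": "tcrm11",
            "tcrm": [1.0, 1.0, 2.0, 2.0, 3.0, 3.5, 4.0, 4.5],
            "n_genes_used": 11,
            "defined": True,
        })
        out = longitudinal_compare(scores, samples)
        assert out["paired_6_to_24_non_progressor"]["p_value"] == 1.0

    def test_missing_pair_names_patient(self, default_cohort,
                                        default_expression):
        scores = score_cohort(default_expression)
        samples = default_cohort.samples
        drop = samples[(samples["split"] == "LONGITUDINAL")
                       & (samples["timepoint_months"] == 24.0)].iloc[0]
        truncated = samples[samples["sample_id"] != drop["sample_id"]]
        with pytest.raises(ValueError, match=drop["patient_id"]):
            longitudinal_compare(scores, truncated)
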