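"""ROC analysis, threshold selection and logistic regression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tcrm.classify import (
    DEFAULT_AR_THRESHOLD,
    auc_ci,
    evaluate_threshold,
    fit_logistic,
    roc_curve,
    select_threshold,
)


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(1.0)
        assert roc.n_pos == 2 and roc.n_neg == 2

    def test_chance_level_for_identical_distributions(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=4000)
        labels = np.repeat([0, 1], 2000)
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(0.5, abs=0.03)

    def test_sensitivity_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(5)
        labels = np.repeat([0, 1], 30)
        roc = roc_curve(rng.normal(size=60) + labels, labels)
        assert (np.diff(roc.sensitivity) <= 1e-12).all()

    def test_one_class_input_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [1, 1])


@settings(max_examples=60, deadline=None)
@given(
    data=st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=20),  # coarse -> many ties
            st.booleans(),
        ),
        min_size=4, max_size=60,
    )
)
def test_trapezoidal_auc_equals_mann_whitney_u(data):
    scores = np.array([s for s, _ in data], dtype=float)
    labels = np.array([int(b) for _, b in data])
    if labels.min() == labels.max():
        return
    roc = roc_curve(scores, labels)
    u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                           alternative="two-sided").statistic
    assert roc.auc == pytest.approx(u / (roc.n_pos * roc.n_neg), abs=1e-9)


class TestAucCI:
    def test_degenerate_perfect_auc(self):
        assert auc_ci(1.0, 30, 30) == (1.0, 1.0)

    def test_large_sample_limit_collapses(self):
        low, high = auc_ci(0.5, 10**6, 10**6)
        assert high - low < 1e-2

    def test_hand_evaluated_closed_form(self):
        # A=0.9, n1=27, n2=22 evaluated by hand from the closed form
        low, high = auc_ci(0.9, 27, 22)
        assert low == pytest.approx(0.8119783463444836, abs=1e-12)
        assert high == pytest.approx(0.9880216536555164, abs=1e-12)


class TestSelectThreshold:
    def test_perfect_separation_midpoint(self):
        roc = roc_curve([1.0, 2.0, 5.0, 6.0], [0, 0, 1, 1])
        d = select_threshold(roc)
        assert d.youden_j == pytest.approx(1.0)
        assert d.threshold == pytest.approx(3.5)
        assert d.sensitivity == 1.0 and d.specificity == 1.0

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(42)
        scores = np.concatenate([rng.normal(0, 1, 40), rng.normal(1.2, 1, 40)])
        labels = np.repeat([0, 1], 40)
        roc = roc_curve(scores, labels)
        d = select_threshold(roc)
        # independent exhaustive scan over every candidate cutpoint
        best_j = -np.inf
        for t in roc.thresholds[np.isfinite(roc.thresholds)]:
            j = (scores[labels == 1] > t).mean() + (
                scores[labels == 0] <= t).mean() - 1.0
            best_j = max(best_j, j)
        assert d.youden_j == pytest.approx(best_j, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30)])
        labels = np.repeat([0, 1], 30)
        d1 = select_threshold(roc_curve(scores, labels))
        d2 = select_threshold(roc_curve(np.exp(scores), labels))
        assert d1.sensitivity == d2.sensitivity
        assert d1.specificity == d2.specificity
        assert d1.youden_j == pytest.approx(d2.youden_j)


class TestEvaluateThreshold:
    def test_extreme_thresholds(self):
        scores = [1.0, 2.0, 3.0, 4.0]
        labels = [0, 0, 1, 1]
        low = evaluate_threshold(scores, labels, 0.0)
        assert low.sensitivity == 1.0 and low.specificity == 0.0
        high = evaluate_threshold(scores, labels, 10.0)
        assert high.sensitivity == 0.0 and high.specificity == 1.0
        assert np.isnan(high.ppv)  # no positive calls

    def test_small_example(self):
        m = evaluate_threshold([1.0, 3.0], [0, 1], 2.0)
        assert (m.tp, m.fp, m.tn, m.fn) == (1, 0, 1, 0)
        assert m.ppv == 1.0 and m.accuracy == 1.0

    def test_published_threshold_constant(self):
        assert DEFAULT_AR_THRESHOLD == 2.24


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        fit = fit_logistic(np.ones((10, 1)), y)
        assert fit.converged
        p = y.mean()
        assert fit.coefficients[0] == pytest.approx(np.log(p / (1 - p)),
                                                    abs=1e-8)

    def test_parameter_recovery_and_statsmodels_agreement(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2024)
        n, beta_true = 500, np.array([-0.5, 1.2, -0.8])
        x = np.column_stack([np.ones(n), rng.normal(size=n),
                             rng.normal(size=n)])
        p = 1 / (1 + np.exp(-x @ beta_true))
        y = rng.binomial(1, p)
        fit = fit_logistic(x, y)
        assert fit.converged and not fit.separation
        # recovered within 3 SE of the generating coefficients
        assert np.all(np.abs(fit.coefficients - beta_true)
                      < 3 * fit.standard_errors)
        ref = sm.Logit(y, x).fit(disp=0)
        assert np.allclose(fit.coefficients, ref.params, atol=1e-6)
        assert np.allclose(fit.standard_errors, ref.bse, rtol=1e-4)

    def test_perfect_separation_flagged(self):
        x = np.column_stack([np.ones(8), np.arange(8.0)])
        y = (np.arange(8) >= 4).astype(int)
        fit = fit_logistic(x, y)
        assert fit.separation
        assert not fit.converged

    def test_loglikelihood_monotone_over_iterations(self):
        rng = np.random.default_rng(9)
        x = np.column_stack([np.ones(200), rng.normal(size=200)])
        y = rng.binomial(1, 1 / (1 + np.exp(-(0.3 + 0.9 * x[:, 1]))))
        fit = fit_logistic(x, y)
        hist = np.array(fit.loglik_history)
        assert np.all(np.diff(hist) >= -1e-9)
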