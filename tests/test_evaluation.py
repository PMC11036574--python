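import itertools
import math

import numpy as np
import pandas as pd
import pytest

from immunorad.evaluation import (
    Dichotomization,
    TwoByTwoTable,
    chi_square_2x2,
    dichotomize_covariates,
    hematological_ratios,
    logistic_regression,
    percent_display,
    rank_sum_test,
    roc_curve,
    stratify_and_test,
    youden_cutoff,
)
from immunorad.volumes import PatientRecord


def make_record(**overrides):
    base = dict(
        patient_id="X", cd8_baseline=100, cd8_10f=150, cd68_baseline=80,
        cd68_10f=70, plt_baseline=200, anc_baseline=4, amc_baseline=0.5,
        alc_baseline=2, plt_10f=180, anc_10f=3, amc_10f=0.4, alc_10f=1,
        age_years=50, figo_stage=2, tumor_size_cm=4, ln_positive=False,
        response="CR",
    )
    base.update(overrides)
    return PatientRecord(**base)


class TestROC:
    def test_perfect_separation(self):
        roc = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert roc.auc == 1.0

    def test_null_scores_auc_half(self):
        rng = np.random.default_rng(0)
        n = 2000
        scores = rng.normal(size=n)
        labels = rng.integers(0, 2, n)
        roc = roc_curve(scores, labels)
        se = np.sqrt(0.25 / n)  # rough AUC standard error bound
        assert abs(roc.auc - 0.5) < 3 * 0.5 / np.sqrt(n)

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_concordant_pair_fraction(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=10)
        labels = np.array([0, 1] * 5)
        roc = roc_curve(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = sum(
            1.0 if a > b else (0.5 if a == b else 0.0)
            for a, b in itertools.product(pos, neg)
        )
        assert roc.auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        a1 = roc_curve(scores, labels).auc
        a2 = roc_curve(np.exp(scores * 2), labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_auc_within_ci(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=60) + np.repeat([0, 1], 30)
        labels = np.repeat([0, 1], 30)
        roc = roc_curve(scores, labels)
        lo, hi = roc.auc_ci95
        assert lo <= roc.auc <= hi

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])


class TestYouden:
    def test_separated_toy_returns_attained_threshold(self):
        roc = roc_curve([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert youden_cutoff(roc) == 0.8

    def test_anti_predictive_warns(self):
        roc = roc_curve([0.9, 0.8, 0.1, 0.2], [0, 0, 1, 1])
        with pytest.warns(UserWarning, match="anti-predictive"):
            cut = youden_cutoff(roc)
        j = roc.sensitivity + roc.specificity - 1
        assert j.max() <= 0

    @pytest.mark.parametrize("seed", range(10))
    def test_j_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, 20)
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        roc = roc_curve(scores, labels)
        cut = youden_cutoff(roc)
        pos, neg = scores[labels == 1], scores[labels == 0]

        def j_at(t):
            return (pos >= t).mean() + (neg < t).mean() - 1

        brute_best = max(j_at(t) for t in np.unique(scores))
        assert j_at(cut) == pytest.approx(brute_best, abs=1e-12)


class TestChiSquare:
    def test_independent_table(self):
        stat, p = chi_square_2x2(TwoByTwoTable(10, 10, 10, 10))
        assert stat == 0
        assert p == pytest.approx(1.0)

    def test_hand_computed_immune_table(self):
        # [[10, 2], [3, 15]] -> expected 5.2/6.8/7.8/10.2 -> 13.03
        stat, p = chi_square_2x2(TwoByTwoTable(low_pr=10, low_cr=2,
                                               high_pr=3, high_cr=15))
        assert stat == pytest.approx(13.03, abs=0.005)
        assert p < 0.001

    @pytest.mark.parametrize("seed", range(20))
    def test_algebraic_identity(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(1, 30, 4)
        stat, _ = chi_square_2x2(TwoByTwoTable(int(a), int(b), int(c), int(d)))
        n = a + b + c + d
        closed = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(float(closed), abs=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin"):
            chi_square_2x2(TwoByTwoTable(0, 0, 5, 5))

    def test_yates_flag_reduces_statistic(self):
        t = TwoByTwoTable(12, 7, 1, 10)
        plain, _ = chi_square_2x2(t)
        corrected, _ = chi_square_2x2(t, continuity_correction=True)
        assert corrected < plain


class TestStratify:
    def test_printed_immune_group_composition(self):
        # low: 2 CR + 10 PR; high: 15 CR + 3 PR
        scores = np.array([0.1] * 12 + [0.5] * 18)
        labels = np.array([1] * 2 + [0] * 10 + [1] * 15 + [0] * 3)
        rep = stratify_and_test(scores, labels, cutoff=0.307)
        assert rep.sensitivity == pytest.approx(15 / 17)
        assert round(rep.sensitivity, 3) == 0.882
        assert rep.specificity == pytest.approx(10 / 13)
        assert round(rep.specificity, 3) == 0.769
        assert rep.p < 0.001
        assert percent_display(rep.cr_rate_high) == 83
        assert percent_display(1 - rep.cr_rate_low) == 83

    def test_radscore_table_p_value(self):
        rep_table = TwoByTwoTable(low_pr=12, low_cr=7, high_pr=1, high_cr=10)
        stat, p = chi_square_2x2(rep_table)
        assert round(p, 3) == 0.004

    def test_boundary_belongs_to_high_group(self):
        rep = stratify_and_test([1.0, 2.0], [0, 1], cutoff=2.0)
        assert rep.table.high_cr == 1
        assert rep.table.low_pr == 1

    def test_empty_group_chi2_undefined(self):
        rep = stratify_and_test([5.0, 6.0], [0, 1], cutoff=0.0)  # all high
        assert math.isnan(rep.chi2)
        assert math.isnan(rep.p)

    @pytest.mark.parametrize("seed", range(5))
    def test_youden_cutoff_maximizes_j(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30) + np.repeat([0, 0.8], 15)
        labels = np.repeat([0, 1], 15)
        cut = youden_cutoff(roc_curve(scores, labels))
        rep = stratify_and_test(scores, labels, cut)
        j_star = rep.sensitivity + rep.specificity - 1
        for t in np.unique(scores):
            other = stratify_and_test(scores, labels, t)
            assert other.sensitivity + other.specificity - 1 <= j_star + 1e-12

    def test_counts_conserve_total(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=25)
        labels = rng.integers(0, 2, 25)
        labels[:2] = [0, 1]
        rep = stratify_and_test(scores, labels, 0.0)
        assert rep.table.total == 25


class TestRankSum:
    def test_identical_samples(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_complete_separation_exact_small_n(self):
        x = np.arange(10) + 100.0
        y = np.arange(10).astype(float)
        _, p = rank_sum_test(x, y)
        # exact two-sided minimum: 2 / C(20, 10)
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=12), rng.normal(size=15)
        _, p1 = rank_sum_test(x, y)
        _, p2 = rank_sum_test(np.exp(x), np.exp(y))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestRatios:
    def test_direct_arithmetic(self):
        r = make_record(anc_baseline=4, alc_baseline=2, plt_baseline=200,
                        amc_baseline=0.5)
        ratios = hematological_ratios(r, "baseline")
        assert ratios == {"NLR": 2.0, "PNR": 50.0, "PLR": 100.0, "LMR": 4.0}

    def test_zero_denominator_flagged(self):
        r = make_record(alc_10f=0.0)
        ratios = hematological_ratios(r, "10f")
        assert math.isnan(ratios["NLR"])
        assert math.isnan(ratios["PLR"])
        assert not math.isnan(ratios["PNR"])

    def test_reciprocal_identity(self):
        r = make_record()
        ratios = hematological_ratios(r, "baseline")
        assert ratios["LMR"] * (r.amc_baseline / r.alc_baseline) == pytest.approx(1.0)

    def test_bad_timepoint(self):
        with pytest.raises(ValueError):
            hematological_ratios(make_record(), "week3")


class TestDichotomize:
    def test_strong_signal_reproduces_labels(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 2, 100)
        cov = labels + rng.normal(0, 0.05, 100)
        out = dichotomize_covariates({"x": cov}, labels)
        assert isinstance(out["x"], Dichotomization)
        agreement = (out["x"].high == labels.astype(bool)).mean()
        assert agreement > 0.95

    def test_constant_covariate_skipped_with_warning(self):
        labels = np.array([0, 1, 0, 1])
        with pytest.warns(UserWarning, match="constant"):
            out = dichotomize_covariates({"flat": np.ones(4)}, labels)
        assert "flat" not in out

    def test_boundary_convention(self):
        labels = np.array([0, 0, 1, 1])
        values = np.array([1.0, 2.0, 3.0, 4.0])
        out = dichotomize_covariates({"v": values}, labels)
        cut = out["v"].cutoff
        np.testing.assert_array_equal(out["v"].high, values >= cut)


class TestLogisticRegression:
    def test_or_equals_cross_product_ratio(self):
        # binary covariate: OR must equal ad/bc from the 2x2 layout
        x = np.repeat([0, 0, 1, 1], [12, 8, 5, 15]).astype(float)
        y = np.repeat([0, 1, 0, 1], [12, 8, 5, 15]).astype(float)
        res = logistic_regression(pd.DataFrame({"x": x}), y)["x"]
        assert res.odds_ratio == pytest.approx((8 / 12) ** -1 * (15 / 5), rel=1e-4)

    def test_intercept_only_prevalence(self):
        import statsmodels.api as sm

        y = np.repeat([0.0, 1.0], [30, 10])
        fit = sm.Logit(y, np.ones((40, 1))).fit(disp=0)
        p_hat = 1 / (1 + np.exp(-fit.params[0]))
        assert p_hat == pytest.approx(0.25, abs=1e-9)

    def test_null_coverage(self):
        rng = np.random.default_rng(7)
        covered = 0
        reps = 60
        for _ in range(reps):
            x = rng.normal(size=300)
            y = rng.integers(0, 2, 300).astype(float)
            res = logistic_regression(pd.DataFrame({"x": x}), y)["x"]
            lo, hi = res.ci95
            covered += lo <= 1.0 <= hi
        # binomial(60, 0.95) two-sided 99% range
        assert covered >= 51

    def test_separation_flagged(self):
        x = np.array([0.0] * 10 + [1.0] * 10)
        y = x.copy()
        res = logistic_regression(pd.DataFrame({"x": x}), y)["x"]
        assert res.separation
        assert res.ci95[1] == math.inf

    def test_multivariate_fit(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
        eta = 1.2 * X["a"]
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
        res = logistic_regression(X, y, univariate=False)
        assert res["a"].p < 0.01
        assert res["a"].odds_ratio > 1.5


# ---------------------------------------------------------------------------
# Property-based invariants
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@given(
    a=st.integers(1, 50), b=st.integers(1, 50),
    c=st.integers(1, 50), d=st.integers(1, 50),
)
@settings(max_examples=200, deadline=None)
def test_chi2_matches_closed_form_property(a, b, c, d):
    stat, p = chi_square_2x2(TwoByTwoTable(a, b, c, d))
    n = a + b + c + d
    closed = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
    assert stat == pytest.approx(float(closed), abs=1e-9)
    assert 0.0 <= p <= 1.0


@given(st.data())
@settings(max_examples=50, deadline=None)
def test_roc_auc_monotone_invariance_property(data):
    n = data.draw(st.integers(6, 30))
    # width=16 avoids subnormals that collapse into ties under the affine map
    scores = np.array(data.draw(st.lists(
        st.floats(-100, 100, allow_nan=False, width=16), min_size=n, max_size=n)))
    labels = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
    if labels.sum() in (0, n):
        labels[0], labels[1] = 0, 1
    r1 = roc_curve(scores, labels)
    r2 = roc_curve(3.0 * scores + 7.0, labels)
    assert r1.auc == pytest.approx(r2.auc, abs=1e-12)
    assert 0.0 <= r1.auc <= 1.0
    # sensitivity non-increasing as the threshold rises
    order = np.argsort(r1.thresholds)
    assert np.all(np.diff(r1.sensitivity[order]) <= 1e-12)
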