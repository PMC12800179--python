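"""Metric, curve, and test-statistic checks against brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from affetds._exceptions import ParameterError
from affetds.evaluation import (
    ConfusionCounts,
    calibration_curve,
    confusion_and_metrics,
    evaluate_scores,
    holm_adjust,
    metrics_from_counts,
    pr_curve,
    probability_summary,
    roc_auc,
    wilcoxon_signed_rank,
)

from oracles import auc_by_pair_counting, wilcoxon_exact_by_enumeration


def _counts_to_sequences(tn, tp, fp, fn):
    labels = ["real"] * (tn + fp) + ["manipulated"] * (tp + fn)
    preds = (
        ["real"] * tn + ["manipulated"] * fp + ["manipulated"] * tp + ["real"] * fn
    )
    return labels, preds


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "tn,tp,fp,fn,accuracy",
        [
            (107, 83, 9, 8, 190 / 207),  # strongest model on a 207-image test set
            (100, 79, 15, 13, 179 / 207),  # 28 errors -> 86.5%
            (103, 80, 13, 11, 183 / 207),  # 24 errors -> 88.4%
        ],
    )
    def test_accuracy_arithmetic(self, tn, tp, fp, fn, accuracy):
        labels, preds = _counts_to_sequences(tn, tp, fp, fn)
        counts, metrics = confusion_and_metrics(labels, preds)
        assert (counts.true_real, counts.true_manip) == (tn, tp)
        assert (counts.false_pos, counts.false_neg) == (fp, fn)
        assert metrics["accuracy"] == pytest.approx(accuracy)

    def test_perfect_predictions(self):
        labels, preds = _counts_to_sequences(5, 5, 0, 0)
        _, metrics = confusion_and_metrics(labels, preds)
        assert metrics["accuracy"] == 1.0
        assert metrics["f1"] == 1.0

    def test_undefined_rates_are_none_not_zero(self):
        # no positive predictions -> precision undefined
        counts = ConfusionCounts(true_real=5, true_manip=0, false_pos=0, false_neg=5)
        metrics = metrics_from_counts(counts)
        assert metrics["precision"] is None
        assert metrics["recall"] == 0.0
        assert metrics["f1"] is None

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            confusion_and_metrics([], [])

    def test_metrics_consistent_with_counts(self, rng):
        y = rng.integers(0, 2, 60)
        p = rng.integers(0, 2, 60)
        counts, metrics = confusion_and_metrics(y, p)
        assert counts.n == 60
        assert metrics["accuracy"] == pytest.approx(
            (counts.true_real + counts.true_manip) / 60
        )


class TestRocAuc:
    def test_perfect_separation(self):
        auc, pts = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0
        assert len(pts["fpr"]) == len(pts["tpr"])

    def test_hand_enumerated_pairs(self):
        # pairs: (0.9,0.8) ok, (0.9,0.2) ok, (0.4,0.8) wrong, (0.4,0.2) ok
        auc, _ = roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.2])
        assert auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        auc, _ = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_single_class_undefined(self):
        auc, pts = roc_auc([1, 1, 1], [0.1, 0.5, 0.9])
        assert auc is None and pts == {}

    def test_equals_pair_counting_oracle(self, rng):
        for trial in range(20):
            n = int(rng.integers(10, 200))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.random(n), 2)  # coarse grid to force ties
            auc, _ = roc_auc(y, s)
            assert auc == pytest.approx(auc_by_pair_counting(y, s), abs=1e-12)


class TestPrCurve:
    def test_perfect_scores(self):
        ap, _ = pr_curve([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert ap == 1.0

    def test_inverted_two_points(self):
        # threshold walk by hand: only the lower score is positive -> AP 0.5
        ap, _ = pr_curve([1, 0], [0.3, 0.7])
        assert ap == pytest.approx(0.5)

    def test_invariant_to_monotone_transform(self, rng):
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        s = rng.random(50)
        ap1, _ = pr_curve(y, s)
        ap2, _ = pr_curve(y, np.tanh(3 * s))  # strictly increasing map
        assert ap1 == pytest.approx(ap2)


class TestCalibration:
    def test_single_full_bin(self):
        bins = calibration_curve([1] * 7, [1.0] * 7)
        assert len(bins) == 1
        assert bins[0].mean_score == 1.0
        assert bins[0].fraction_positive == 1.0
        assert bins[0].count == 7

    def test_counts_sum_to_n(self, rng):
        s = rng.random(500)
        y = rng.integers(0, 2, 500)
        bins = calibration_curve(y, s)
        assert sum(b.count for b in bins) == 500

    def test_calibrated_predictor_lies_near_diagonal(self):
        # scores are true Bernoulli probabilities -> each bin's positive
        # fraction concentrates around its mean score (n=10000, ~1000/bin)
        gen = np.random.default_rng(99)
        s = gen.random(10_000)
        y = (gen.random(10_000) < s).astype(int)
        bins = calibration_curve(y, s, n_bins=10)
        worst = max(abs(b.fraction_positive - b.mean_score) for b in bins)
        assert worst <= 0.05

    def test_bad_bin_count_rejected(self):
        with pytest.raises(ParameterError):
            calibration_curve([0, 1], [0.2, 0.8], n_bins=0)


class TestProbabilitySummary:
    def test_odd_median(self):
        assert probability_summary([0.2, 0.4, 0.6])["median"] == pytest.approx(0.4)

    def test_constant_scores_zero_iqr(self):
        summary = probability_summary([0.3] * 9)
        assert summary["iqr_high"] - summary["iqr_low"] == 0.0

    def test_uniform_sample_median_near_half(self):
        gen = np.random.default_rng(5)
        summary = probability_summary(gen.random(10_001))
        assert abs(summary["median"] - 0.5) < 0.02


class TestWilcoxon:
    def test_identical_series_p_one(self):
        w, p = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert w is None and p == 1.0

    def test_all_positive_differences_n6(self):
        a = np.arange(1.0, 7.0)
        w, p = wilcoxon_signed_rank(a + 0.1, a)
        assert w == 0.0
        assert p == pytest.approx(2 / 64)

    def test_two_sided_symmetry(self, rng):
        a = rng.random(8)
        b = rng.random(8)
        _, p_ab = wilcoxon_signed_rank(a, b)
        _, p_ba = wilcoxon_signed_rank(b, a)
        assert p_ab == pytest.approx(p_ba)

    def test_matches_enumeration_oracle(self, rng):
        for trial in range(15):
            n = int(rng.integers(5, 11))
            a = np.round(rng.random(n), 1)  # coarse values force ties/zeros
            b = np.round(rng.random(n), 1)
            w, p = wilcoxon_signed_rank(a, b)
            w_ref, p_ref = wilcoxon_exact_by_enumeration(a, b)
            assert (w is None) == (w_ref is None)
            if w is not None:
                assert w == pytest.approx(w_ref)
            assert p == pytest.approx(p_ref)

    def test_matches_scipy_exact_when_tie_free(self, rng):
        a = rng.random(10)
        b = rng.random(10)
        w, p = wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, method="exact")
        assert w == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_large_n_normal_approximation_matches_scipy(self, rng):
        a = rng.random(40)
        b = rng.random(40)
        w, p = wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, method="approx", correction=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


def test_holm_adjustment_orders_and_caps():
    adjusted = holm_adjust([0.01, 0.04, 0.03])
    assert adjusted[0] == pytest.approx(0.03)
    assert all(a <= 1.0 for a in adjusted)
    assert adjusted[1] >= adjusted[2] - 1e-12


def test_evaluate_scores_report_is_internally_consistent(rng):
    y = rng.integers(0, 2, 120)
    y[:2] = [0, 1]
    s = np.clip(0.3 * y + 0.35 + 0.25 * rng.random(120), 0, 1)
    report = evaluate_scores(y, s, model="demo", threshold=0.5)
    counts = report.counts
    assert counts.n == 120
    recomputed = metrics_from_counts(counts)
    assert recomputed == report.metrics
    assert sum(b.count for b in report.calibration) == 120
    assert 0 <= report.auc <= 1
    payload = report.to_dict()
    assert payload["model"] == "demo"
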