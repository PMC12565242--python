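"""Metrics and paired comparison statistics against independent oracles."""

import itertools
import math

import numpy as np
import pytest

from ctslider.evalstats import (PredictionSet, auprc, auprc_permutation_test,
                                auroc, compare_models, delong_test,
                                paired_bootstrap_diff_ci, threshold_metrics)


def _brute_auroc(y, s):
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def _brute_auprc(y, s):
    # step-wise average precision: precision at each descending unique score
    # threshold weighted by the recall increment it contributes
    ap, prev_recall = 0.0, 0.0
    for t in np.unique(s)[::-1]:
        pred = s >= t
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        recall = tp / y.sum()
        ap += (recall - prev_recall) * (tp / (tp + fp))
        prev_recall = recall
    return ap


class TestThresholdMetrics:
    def test_worked_confusion_example(self):
        # TP=2 TN=2 FP=1 FN=1
        y = np.array([1, 1, 1, 0, 0, 0])
        s = np.array([0.9, 0.8, 0.1, 0.7, 0.2, 0.3])
        m = threshold_metrics(y, s)
        assert (m.tp, m.tn, m.fp, m.fn) == (2, 2, 1, 1)
        for v in (m.accuracy, m.recall, m.precision, m.specificity, m.f1):
            assert round(v, 3) == 0.667

    def test_perfect_predictions(self):
        m = threshold_metrics([1, 0, 1], [0.9, 0.1, 0.8])
        assert m.accuracy == m.recall == m.precision == m.f1 == 1.0
        assert m.auroc == 1.0

    def test_zero_denominators_reported_as_nan_not_zero(self):
        m = threshold_metrics([1, 1, 0], [0.1, 0.2, 0.3])  # nothing predicted +
        assert math.isnan(m.precision)
        assert m.recall == 0.0

    def test_threshold_boundary_is_positive(self):
        m = threshold_metrics([1], [0.5])
        assert m.tp == 1

    def test_prediction_set_interface(self):
        p = PredictionSet(["a", "b"], [1, 0], [0.9, 0.1])
        assert threshold_metrics(p).accuracy == 1.0

    def test_f1_identities_agree(self, rng):
        for _ in range(50):
            y = rng.integers(0, 2, 30)
            s = rng.random(30)
            m = threshold_metrics(y, s)
            if m.tp == 0:
                continue
            harmonic = 2 * m.precision * m.recall / (m.precision + m.recall)
            assert m.f1 == pytest.approx(harmonic)
            assert m.f1 == pytest.approx(2 * m.tp / (2 * m.tp + m.fp + m.fn))


class TestRankMetrics:
    def test_separated_scores_give_unit_auroc(self):
        assert auroc([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2]) == 1.0

    def test_constant_scores_give_half(self):
        assert auroc([1, 0, 1, 0], [0.3, 0.3, 0.3, 0.3]) == 0.5

    def test_auroc_matches_pair_counting(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 25))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], n)  # ties likely
            assert auroc(y, s) == pytest.approx(_brute_auroc(y, s))

    def test_auroc_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.random(40)
        assert auroc(y, s) == pytest.approx(auroc(y, np.exp(3 * s - 1)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1, 1], [0.5, 0.6])

    def test_auprc_single_positive_ranked_last(self):
        assert auprc([0, 0, 0, 1], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(0.25)

    def test_auprc_perfect_separation(self):
        assert auprc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_auprc_matches_threshold_sweep(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 25))
            y = rng.integers(0, 2, n)
            if y.sum() == 0:
                continue
            s = rng.random(n)
            assert auprc(y, s) == pytest.approx(_brute_auprc(y, s))

    def test_auprc_without_positives_rejected(self):
        with pytest.raises(ValueError):
            auprc([0, 0], [0.2, 0.4])


class TestPairedBootstrap:
    Y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0])
    A = np.array([0.9, 0.8, 0.4, 0.7, 0.2, 0.3, 0.1, 0.4, 0.25])
    B = np.array([0.7, 0.9, 0.3, 0.5, 0.4, 0.2, 0.15, 0.5, 0.3])

    def test_identical_models_give_degenerate_interval(self):
        e = paired_bootstrap_diff_ci(self.A, self.A, self.Y, B=200, seed=0)
        assert e.delta == 0.0 and e.ci_low == 0.0 and e.ci_high == 0.0

    def test_same_seed_reproduces_interval(self):
        e1 = paired_bootstrap_diff_ci(self.A, self.B, self.Y, B=300, seed=7)
        e2 = paired_bootstrap_diff_ci(self.A, self.B, self.Y, B=300, seed=7)
        assert (e1.ci_low, e1.ci_high) == (e2.ci_low, e2.ci_high)

    def test_interval_nesting_across_confidence_levels(self):
        wide = paired_bootstrap_diff_ci(self.A, self.B, self.Y, B=500,
                                        alpha=0.05, seed=3)
        narrow = paired_bootstrap_diff_ci(self.A, self.B, self.Y, B=500,
                                          alpha=0.30, seed=3)
        assert wide.ci_low <= narrow.ci_low <= narrow.ci_high <= wide.ci_high

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            paired_bootstrap_diff_ci([0.1, 0.2], [0.3, 0.4], [1, 1], B=10)


class TestDeLong:
    Y = np.array([1, 1, 1, 0, 0, 0])
    A = np.array([0.9, 0.6, 0.8, 0.3, 0.5, 0.2])
    B = np.array([0.8, 0.5, 0.4, 0.6, 0.3, 0.1])

    @staticmethod
    def _brute_delong(sa, sb, y):
        pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
        n1, n0 = len(pos), len(neg)
        v10 = np.zeros((2, n1))
        v01 = np.zeros((2, n0))
        for k, s in enumerate((sa, sb)):
            for i, ip in enumerate(pos):
                v10[k, i] = np.mean([1.0 if s[ip] > s[jn] else
                                     0.5 if s[ip] == s[jn] else 0.0 for jn in neg])
            for j, jn in enumerate(neg):
                v01[k, j] = np.mean([1.0 if s[ip] > s[jn] else
                                     0.5 if s[ip] == s[jn] else 0.0 for ip in pos])
        auc = v10.mean(axis=1)

        def cov(m):
            centred = m - m.mean(axis=1, keepdims=True)
            return centred @ centred.T / (m.shape[1] - 1)

        s10, s01 = cov(v10), cov(v01)
        var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1
               + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0)
        return (auc[0] - auc[1]) / math.sqrt(var)

    def test_matches_placement_value_oracle_on_six_cases(self):
        z, p = delong_test(self.A, self.B, self.Y)
        z_ref = self._brute_delong(self.A, self.B, self.Y)
        assert z == pytest.approx(z_ref)
        from scipy.stats import norm
        assert p == pytest.approx(2 * norm.sf(abs(z_ref)))

    def test_antisymmetry(self):
        z_ab, p_ab = delong_test(self.A, self.B, self.Y)
        z_ba, p_ba = delong_test(self.B, self.A, self.Y)
        assert z_ab == pytest.approx(-z_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_identical_scores_flagged_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            z, p = delong_test(self.A, self.A, self.Y)
        assert (z, p) == (0.0, 1.0)


class TestPermutationTest:
    Y = np.array([1, 1, 0, 0, 1, 0])
    A = np.array([0.9, 0.6, 0.5, 0.2, 0.7, 0.35])
    B = np.array([0.6, 0.5, 0.45, 0.4, 0.8, 0.3])

    @staticmethod
    def _exhaustive(sa, sb, y):
        observed = abs(auprc(y, sa) - auprc(y, sb))
        n = len(y)
        count = 0
        for pattern in itertools.product([False, True], repeat=n):
            swap = np.array(pattern)
            a = np.where(swap, sb, sa)
            b = np.where(swap, sa, sb)
            if abs(auprc(y, a) - auprc(y, b)) >= observed - 1e-12:
                count += 1
        return count / 2 ** n

    def test_exact_mode_matches_exhaustive_enumeration(self):
        p = auprc_permutation_test(self.A, self.B, self.Y, method="exact")
        assert p == pytest.approx(self._exhaustive(self.A, self.B, self.Y))

    def test_identical_models_give_p_one(self):
        assert auprc_permutation_test(self.A, self.A, self.Y, n_perm=50,
                                      seed=0) == 1.0

    def test_symmetric_under_model_relabeling(self):
        p_ab = auprc_permutation_test(self.A, self.B, self.Y, n_perm=200, seed=5)
        p_ba = auprc_permutation_test(self.B, self.A, self.Y, n_perm=200, seed=5)
        assert p_ab == p_ba

    def test_sampled_p_uses_add_one_estimator(self):
        p = auprc_permutation_test(self.A, self.B, self.Y, n_perm=19, seed=2)
        assert (p * 20) == pytest.approx(round(p * 20))
        assert 1 / 20 <= p <= 1.0

    def test_null_p_values_are_super_uniform(self, rng):
        # paired scores drawn from one exchangeable distribution: rejection
        # rate at alpha=0.05 must not exceed alpha within Monte-Carlo error
        reps, alpha = 400, 0.05
        rejections = 0
        for _ in range(reps):
            y = np.array([1, 1, 1, 0, 0, 0, 1, 0, 0, 1, 0, 1])
            a = rng.random(12)
            b = rng.random(12)
            p = auprc_permutation_test(a, b, y, n_perm=79, seed=int(rng.integers(2**31)))
            rejections += p <= alpha
        rate = rejections / reps
        assert rate <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / reps)

    def test_invalid_n_perm_rejected(self):
        with pytest.raises(ValueError):
            auprc_permutation_test(self.A, self.B, self.Y, n_perm=0)


def test_compare_models_report_shape():
    y = np.array([1, 1, 1, 0, 0, 0, 1, 0])
    rng = np.random.default_rng(3)
    a, b = rng.random(8), rng.random(8)
    report = compare_models(y, a, b, B=50, n_perm=50, seed=0)
    assert set(report.entries) == {"auroc", "auprc", "accuracy", "recall",
                                   "precision", "specificity", "f1"}
    assert report.entries["auroc"].test == "delong"
    assert report.entries["auprc"].p_value is not None
    d = report.as_dict()
    assert d["auroc"]["delta"] == pytest.approx(
        auroc(y, a) - auroc(y, b))
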