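"""Classification metrics and paired model-comparison statistics.

Threshold metrics (accuracy, recall, precision, specificity, F1) come from
the confusion matrix at a fixed operating point (score >= 0.5 is positive by
default); ratios with zero denominators are reported as NaN, not zero.
AUROC is the probability that a positive case outranks a negative one (ties
counted 1/2) and AUPRC is step-wise average precision; both are delegated to
scikit-learn, whose estimators implement exactly these definitions.

Model comparison on a shared test set uses three paired procedures:

* a class-stratified paired bootstrap of the metric difference
  (Delta = metric_A - metric_B), resampling cases with replacement within
  each label stratum and applying identical indices to both models, with a
  percentile 95% CI;
* DeLong's test for the difference of two correlated AUROCs, via the
  placement-value covariance estimator;
* a within-case score-swapping permutation test for the AUPRC difference:
  under the null the (A, B) scores of each case are exchangeable, so each
  case's pair is swapped independently with probability 1/2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "PredictionSet",
    "MetricsReport",
    "ComparisonEntry",
    "ComparisonReport",
    "threshold_metrics",
    "auroc",
    "auprc",
    "paired_bootstrap_diff_ci",
    "delong_test",
    "auprc_permutation_test",
    "compare_models",
]


@dataclass
class PredictionSet:
    """Per-case scores and binary labels (1 = PF-ILD positive)."""

    case_ids: list[str]
    labels: np.ndarray
    scores: np.ndarray
    threshold: float = 0.5

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if not (len(self.case_ids) == len(self.labels) == len(self.scores)):
            raise ValueError("case_ids, labels and scores must have equal length")


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    recall: float
    precision: float
    specificity: float
    f1: float
    auroc: float
    auprc: float

    def as_dict(self) -> dict[str, float]:
        return dict(vars(self))


def _check_labels_scores(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.size == 0:
        raise ValueError("labels and scores must be equal-length and non-empty")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return labels, scores


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def threshold_metrics(labels, scores=None, threshold: float = 0.5) -> MetricsReport:
    """Confusion-matrix metrics at a fixed threshold (score >= t is positive)."""
    if isinstance(labels, PredictionSet):
        p = labels
        labels, scores, threshold = p.labels, p.scores, p.threshold
    labels, scores = _check_labels_scores(labels, scores)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    both = len(np.unique(labels)) == 2
    has_pos = labels.sum() > 0
    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=_ratio(tp + tn, tp + tn + fp + fn),
        recall=_ratio(tp, tp + fn),
        precision=_ratio(tp, tp + fp),
        specificity=_ratio(tn, tn + fp),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
        auroc=auroc(labels, scores) if both else float("nan"),
        auprc=auprc(labels, scores) if has_pos else float("nan"),
    )


def auroc(labels, scores) -> float:
    """Pairwise probability that a positive outranks a negative (ties 1/2)."""
    labels, scores = _check_labels_scores(labels, scores)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC requires both classes present")
    return float(roc_auc_score(labels, scores))


def auprc(labels, scores) -> float:
    """Step-wise average precision over descending score thresholds."""
    labels, scores = _check_labels_scores(labels, scores)
    if labels.sum() == 0:
        raise ValueError("AUPRC requires at least one positive case")
    return float(average_precision_score(labels, scores))


_METRIC_FNS = {
    "auroc": auroc,
    "auprc": auprc,
    "accuracy": lambda y, s: threshold_metrics(y, s).accuracy,
    "recall": lambda y, s: threshold_metrics(y, s).recall,
    "precision": lambda y, s: threshold_metrics(y, s).precision,
    "specificity": lambda y, s: threshold_metrics(y, s).specificity,
    "f1": lambda y, s: threshold_metrics(y, s).f1,
}


@dataclass
class ComparisonEntry:
    metric: str
    value_a: float
    value_b: float
    delta: float
    ci_low: float
    ci_high: float
    n_resamples: int
    alpha: float
    p_value: float | None = None
    test: str | None = None


@dataclass
class ComparisonReport:
    entries: dict[str, ComparisonEntry] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {k: dict(vars(v)) for k, v in self.entries.items()}


def paired_bootstrap_diff_ci(scores_a, scores_b, labels, metric="auroc",
                             B: int = 5000, alpha: float = 0.05,
                             seed: int = 0) -> ComparisonEntry:
    """Class-stratified paired bootstrap CI for Delta = metric_A - metric_B.

    Cases are resampled with replacement within each label stratum and the
    same resampled indices are applied to both models, preserving pairing.
    """
    labels, scores_a = _check_labels_scores(labels, scores_a)
    _, scores_b = _check_labels_scores(labels, scores_b)
    if B < 1:
        raise ValueError("B must be >= 1")
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both label strata must be non-empty")
    name = metric if isinstance(metric, str) else getattr(metric, "__name__", "metric")
    fn = _METRIC_FNS[metric] if isinstance(metric, str) else metric

    rng = np.random.default_rng(seed)
    deltas = np.empty(B)
    for b in range(B):
        idx = np.concatenate([rng.choice(pos, size=len(pos), replace=True),
                              rng.choice(neg, size=len(neg), replace=True)])
        deltas[b] = fn(labels[idx], scores_a[idx]) - fn(labels[idx], scores_b[idx])
    lo, hi = np.percentile(deltas, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    va, vb = fn(labels, scores_a), fn(labels, scores_b)
    return ComparisonEntry(metric=name, value_a=va, value_b=vb, delta=va - vb,
                           ci_low=float(lo), ci_high=float(hi),
                           n_resamples=B, alpha=alpha)


def _placements(pos_scores: np.ndarray, neg_scores: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    gt = (pos_scores[:, None] > neg_scores[None, :]).astype(float)
    eq = (pos_scores[:, None] == neg_scores[None, :]).astype(float)
    psi = gt + 0.5 * eq
    return psi.mean(axis=1), psi.mean(axis=0)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired DeLong test for the AUROC difference; returns (z, two-sided p).

    Degenerate (zero-variance) comparisons — e.g. identical score vectors —
    are flagged with a warning and reported as z = 0, p = 1 by convention.
    """
    labels, scores_a = _check_labels_scores(labels, scores_a)
    _, scores_b = _check_labels_scores(labels, scores_b)
    pos, neg = labels == 1, labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("both classes must be present")
    v10 = np.empty((2, pos.sum()))
    v01 = np.empty((2, neg.sum()))
    for k, s in enumerate((scores_a, scores_b)):
        v10[k], v01[k] = _placements(s[pos], s[neg])
    aucs = v10.mean(axis=1)
    n1, n0 = pos.sum(), neg.sum()
    s10 = np.cov(v10) if n1 > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n0 > 1 else np.zeros((2, 2))
    var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1
           + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0)
    delta = aucs[0] - aucs[1]
    if var <= 0 or not math.isfinite(var):
        warnings.warn("degenerate DeLong variance; returning p = 1", stacklevel=2)
        return 0.0, 1.0
    z = float(delta / math.sqrt(var))
    return z, float(2.0 * norm.sf(abs(z)))


def auprc_permutation_test(scores_a, scores_b, labels, n_perm: int = 5000,
                           seed: int = 0, method: str = "sampled") -> float:
    """Within-case score-swapping permutation p for the AUPRC difference.

    ``method='sampled'`` draws ``n_perm`` random swap patterns and uses the
    add-one estimator p = (1 + #{|D*| >= |D|}) / (1 + n_perm);
    ``method='exact'`` enumerates all 2^N swap patterns and reports the
    exact tail fraction (feasible for small N).
    """
    labels, scores_a = _check_labels_scores(labels, scores_a)
    _, scores_b = _check_labels_scores(labels, scores_b)
    observed = abs(auprc(labels, scores_a) - auprc(labels, scores_b))
    n = len(labels)
    eps = 1e-12

    def perm_delta(swap: np.ndarray) -> float:
        a = np.where(swap, scores_b, scores_a)
        b = np.where(swap, scores_a, scores_b)
        return abs(auprc(labels, a) - auprc(labels, b))

    if method == "exact":
        if n > 20:
            raise ValueError("exact enumeration is limited to N <= 20 cases")
        count = 0
        for bits in range(2 ** n):
            swap = (bits >> np.arange(n)) & 1
            if perm_delta(swap.astype(bool)) >= observed - eps:
                count += 1
        return count / 2 ** n
    if method != "sampled":
        raise ValueError(f"unknown method {method!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    count = sum(perm_delta(rng.random(n) < 0.5) >= observed - eps
                for _ in range(n_perm))
    return (1 + count) / (1 + n_perm)


def compare_models(labels, scores_a, scores_b,
                   metrics: tuple[str, ...] = ("auroc", "auprc", "accuracy",
                                               "recall", "precision",
                                               "specificity", "f1"),
                   B: int = 5000, n_perm: int = 5000, alpha: float = 0.05,
                   seed: int = 0) -> ComparisonReport:
    """Full paired comparison: bootstrap CIs for every metric difference plus
    DeLong p for the AUROC and the swap-permutation p for the AUPRC."""
    report = ComparisonReport()
    for i, m in enumerate(metrics):
        entry = paired_bootstrap_diff_ci(scores_a, scores_b, labels, metric=m,
                                         B=B, alpha=alpha, seed=seed + i)
        if m == "auroc":
            entry.test = "delong"
            _, entry.p_value = delong_test(scores_a, scores_b, labels)
        elif m == "auprc":
            entry.test = "swap_permutation"
            entry.p_value = auprc_permutation_test(scores_a, scores_b, labels,
                                                   n_perm=n_perm, seed=seed)
        report.entries[m] = entry
    return report
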