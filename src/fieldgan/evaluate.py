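"""Binary-classification performance metrics and multi-run confidence intervals.

Curves follow the sensitivity–specificity (SS) and precision–recall (PR)
conventions; the SS area is the usual ROC AUC (trapezoidal over
1 − specificity), the PR area the non-interpolated step-wise sum.  Point
metrics at a fixed threshold include accuracy, sensitivity, specificity,
F1 and the Matthews correlation coefficient (MCC, set to 0 by convention
when a confusion-matrix marginal is zero).  Repeated-training uncertainty is
summarized by t-based 95% confidence intervals across runs, including
paired differences between two model variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import ValidationError


def _check_classes(labels: np.ndarray) -> None:
    u = np.unique(labels)
    if not (0 in u and 1 in u):
        raise ValidationError(
            f"both classes must be present, got labels {sorted(u.tolist())}"
        )


def roc_points(scores, labels) -> np.ndarray:
    """(sensitivity, specificity) at every distinct threshold.

    Thresholds sweep the distinct score values from high to low (ties
    grouped), bracketed by the (0, 1) and (1, 0) endpoints.  Returns an
    array of shape (n_points, 2).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    _check_classes(labels)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # keep only the last index of each tied score group
    distinct = np.r_[s[1:] != s[:-1], True]
    sens = tp[distinct] / n_pos
    spec = 1.0 - fp[distinct] / n_neg
    pts = np.vstack([[0.0, 1.0], np.column_stack([sens, spec])])
    return pts


def pr_points(scores, labels) -> np.ndarray:
    """(recall, precision) at every distinct threshold, high to low."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_classes(labels)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    n_pos = int(y.sum())
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    distinct = np.r_[s[1:] != s[:-1], True]
    recall = tp[distinct] / n_pos
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    return np.column_stack([recall, precision])


def auc_ss(curve: np.ndarray) -> float:
    """Trapezoidal area under the sensitivity vs (1 - specificity) curve."""
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[0] < 2 or curve.shape[1] != 2:
        raise ValidationError(f"malformed curve of shape {curve.shape}")
    sens = curve[:, 0]
    fpr = 1.0 - curve[:, 1]
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(sens[order], fpr[order]))


def auc_pr(curve: np.ndarray) -> float:
    """Non-interpolated step-wise area under the precision-recall curve."""
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[0] < 1 or curve.shape[1] != 2:
        raise ValidationError(f"malformed curve of shape {curve.shape}")
    recall = np.r_[0.0, curve[:, 0]]
    precision = curve[:, 1]
    return float(np.sum(np.diff(recall) * precision))


@dataclass
class ClassificationReport:
    auc_ss: float
    auc_pr: float
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    threshold: float
    n_pos: int
    n_neg: int


def confusion_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """Threshold metrics from the confusion matrix (predict positive at >= t)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_classes(labels)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    return {
        "accuracy": (tp + tn) / labels.size,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "f1": 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0,
        "mcc": float(mcc),
        "threshold": threshold,
        "n_pos": tp + fn,
        "n_neg": tn + fp,
    }


def classification_report(scores, labels, threshold: float = 0.5) -> ClassificationReport:
    cm = confusion_metrics(scores, labels, threshold)
    return ClassificationReport(
        auc_ss=auc_ss(roc_points(scores, labels)),
        auc_pr=auc_pr(pr_points(scores, labels)),
        **cm,
    )


def multi_run_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """t-based confidence interval over repeated runs.

    Returns ``(low, high, mean)``; interval is mean ± t_{1-(1-level)/2, n-1}
    * s / sqrt(n) with the sample (n-1) SD.  Identical values give a
    zero-width interval.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError(f"need >= 2 runs for a confidence interval, got {v.size}")
    mean = float(v.mean())
    s = float(v.std(ddof=1))
    half = float(stats.t.ppf(0.5 + level / 2.0, v.size - 1)) * s / np.sqrt(v.size)
    return mean - half, mean + half, mean


def paired_difference_ci(values_a, values_b, level: float = 0.95):
    """CI of the per-run difference a - b between two model variants."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired run sets must have equal length")
    return multi_run_ci(a - b, level)
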