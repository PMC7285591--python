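"""Binary-classification evaluation: confusion-matrix metrics, ROC/AUC and
DeLong's paired AUC comparison.

Threshold metrics follow the standard definitions

    Sn  = TP / (TP + FN)                      (sensitivity / recall)
    Sp  = TN / (TN + FP)                      (specificity)
    Acc = (TP + TN) / total
    P   = TP / (TP + FP)                      (precision)
    F1  = 2 P R / (P + R)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with the zero-denominator conventions MCC -> 0, P -> 0, F1 -> 0.  AUC uses
the rank (Mann-Whitney) identity, which handles ties exactly and equals
the trapezoid area under the ROC curve swept over all distinct scores.
DeLong's test compares two correlated AUCs on the same labels via
placement-value covariance and a two-sided normal p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("empty confusion matrix")


@dataclass(frozen=True)
class EvaluationReport:
    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    precision: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Sn": self.sn, "Sp": self.sp, "Acc": self.acc,
            "Precision": self.precision, "F1": self.f1, "MCC": self.mcc,
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def metrics_from_counts(counts: ConfusionCounts) -> EvaluationReport:
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sn = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    acc = (tp + tn) / (tp + fp + tn + fn)
    prec = _ratio(tp, tp + fp)
    f1 = _ratio(2 * prec * sn, prec + sn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return EvaluationReport(counts, sn, sp, acc, prec, f1, float(mcc))


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary {0,1}")
    if labels.min() == labels.max():
        raise ValueError("labels contain a single class")
    return labels


def confusion_metrics(labels, predictions) -> EvaluationReport:
    """Threshold metrics from binary labels and binary predictions."""
    labels = _check_labels(labels)
    predictions = np.asarray(predictions, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("labels and predictions lengths differ")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    return metrics_from_counts(ConfusionCounts(tp, fp, tn, fn))


def auc_score(labels, scores) -> float:
    """AUC by the Mann-Whitney rank identity (ties count one half)."""
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = sps.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc(labels, scores) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC points and AUC.

    Returns (fpr, tpr, thresholds, auc): the ROC curve evaluated at every
    distinct score (plus the endpoint), with tpr = Sn and fpr = 1 - Sp,
    and the exact tie-aware AUC.
    """
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return fpr, tpr, thr, auc_score(labels, scores)


def _placements(pos_scores: np.ndarray, neg_scores: np.ndarray):
    """Midrank placement values V10 (per positive) and V01 (per negative)."""
    m, n = len(pos_scores), len(neg_scores)
    allscores = np.concatenate([pos_scores, neg_scores])
    mid = sps.rankdata(allscores)
    mid_pos = sps.rankdata(pos_scores)
    mid_neg = sps.rankdata(neg_scores)
    v10 = (mid[:m] - mid_pos) / n
    v01 = 1.0 - (mid[m:] - mid_neg) / m
    return v10, v01


def delong_test(labels, scores_a, scores_b) -> tuple[float, float, float]:
    """DeLong's paired test for the difference of two correlated AUCs.

    Returns (AUC_a, AUC_b, two-sided p-value).  Identical score vectors
    (zero-variance difference) give p = 1 by convention.
    """
    labels = _check_labels(labels)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != labels.shape or scores_b.shape != labels.shape:
        raise ValueError("labels and score vectors must have the same length")
    pos = labels == 1
    auc_a = auc_score(labels, scores_a)
    auc_b = auc_score(labels, scores_b)

    v10_a, v01_a = _placements(scores_a[pos], scores_a[~pos])
    v10_b, v01_b = _placements(scores_b[pos], scores_b[~pos])
    m, n = int(pos.sum()), int((~pos).sum())

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (
        (s10[0, 0] - 2 * s10[0, 1] + s10[1, 1]) / m
        + (s01[0, 0] - 2 * s01[0, 1] + s01[1, 1]) / n
    )
    if var <= 0:
        return auc_a, auc_b, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return auc_a, auc_b, float(p)


def evaluate_scores(labels, scores, threshold: float) -> dict[str, float]:
    """Full report at a decision threshold, plus AUC."""
    from aptapred.ensemble import classify

    report = confusion_metrics(labels, classify(scores, threshold))
    out = report.as_dict()
    out["AUC"] = auc_score(labels, scores)
    return out


def stratified_split(labels, test_fraction: float = 0.2, seed: int = 0):
    """Simple stratified train/test index split."""
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        cut = max(1, int(round(test_fraction * len(idx))))
        test_idx.extend(idx[:cut])
        train_idx.extend(idx[cut:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))
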