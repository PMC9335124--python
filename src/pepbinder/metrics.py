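"""Binary-classifier evaluation metrics.

Scalar metrics from the 2x2 confusion table (sensitivity, specificity,
precision, F1, accuracy, Matthews correlation coefficient) plus the
threshold-free AUROC (Mann–Whitney rank form) and AUPRC (average
precision, step-wise).  Zero-denominator ratios are reported as 0 with a
warning flag so fold averaging never propagates NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

METRIC_NAMES = ("Sn", "Sp", "Pr", "F1", "Acc", "MCC", "AUROC", "AUPRC")


@dataclass(frozen=True)
class Confusion:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.TP + self.FP + self.TN + self.FN < 1:
            raise ValueError("empty confusion table")


def confusion(y_true, y_pred) -> Confusion:
    """Standard 2x2 counts from binary label vectors."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("empty input")
    return Confusion(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def scalar_metrics(c: Confusion) -> dict[str, float]:
    """Sn, Sp, Pr, F1, Acc, MCC from a confusion table.

    Sn = TP/(TP+FN);  Sp = TN/(TN+FP);  Pr = TP/(TP+FP);
    F1 = 2TP/(2TP+FP+FN);  Acc = (TP+TN)/N;
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    TP, FP, TN, FN = c.TP, c.FP, c.TN, c.FN
    mcc_den = np.sqrt(float(TP + FP) * (TP + FN) * (TN + FP) * (TN + FN))
    return {
        "Sn": _safe_div(TP, TP + FN, "Sn"),
        "Sp": _safe_div(TN, TN + FP, "Sp"),
        "Pr": _safe_div(TP, TP + FP, "Pr"),
        "F1": _safe_div(2 * TP, 2 * TP + FP + FN, "F1"),
        "Acc": (TP + TN) / (TP + FP + TN + FN),
        "MCC": _safe_div(TP * TN - FP * FN, mcc_den, "MCC"),
    }


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the Mann–Whitney rank statistic.

    Equals P(score+ > score-) + 0.5 P(tie); ties handled by average ranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Area under the precision–recall curve as average precision.

    AP = sum_k (R_k - R_{k-1}) P_k over descending unique-score thresholds
    (step-wise, no interpolation).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AUPRC needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    pred = np.arange(1, y.size + 1)
    # evaluate only at the last index of each tied-score group
    last = np.r_[s[1:] != s[:-1], True]
    precision = tp[last] / pred[last]
    recall = tp[last] / n_pos
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def metric_report(y_true, prob, tp: float = 0.5) -> dict[str, float]:
    """Full eight-metric report from true labels and positive-class
    probabilities thresholded at ``tp`` (binder iff prob >= tp)."""
    y_true = np.asarray(y_true).astype(int)
    prob = np.asarray(prob, dtype=float)
    rep = scalar_metrics(confusion(y_true, (prob >= tp).astype(int)))
    rep["AUROC"] = auroc(prob, y_true)
    rep["AUPRC"] = auprc(prob, y_true)
    return rep


def mean_report(reports: list[dict]) -> dict[str, float]:
    """Arithmetic mean of per-fold metric reports (matching mean +/- SD
    fold summaries); keys restricted to the shared metric names."""
    keys = [k for k in METRIC_NAMES if all(k in r for r in reports)]
    return {k: float(np.mean([r[k] for r in reports])) for k in keys}
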