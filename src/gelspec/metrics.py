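"""Two-class evaluation: confusion matrix, accuracy, precision,
sensitivity, Cohen's kappa and ROC AUC.

"gelled" is the positive class throughout.  Kappa corrects the observed
agreement p0 for the chance agreement pc expected from the marginal
label frequencies:

    kappa = (p0 - pc) / (1 - pc),
    p0 = (TP + TN) / N,
    pc = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / N^2.

AUC uses the rank (Mann-Whitney) formulation — the probability that a
random gelled egg receives a higher score than a random non-gelled egg,
ties counted half — which equals trapezoidal integration of the ROC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .spectra import GELLED, NON_GELLED


class MetricError(ValueError):
    """Raised when a metric is undefined for the given table."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts for gelled (positive) vs non-gelled (negative) predictions."""

    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FN", "FP", "TN"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise MetricError(f"{name} must be a non-negative integer")
        if self.total == 0:
            raise MetricError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.FP + self.TN


def confusion(true_labels: Sequence[str],
              predicted_labels: Sequence[str]) -> ConfusionMatrix:
    """Tabulate predictions against truth ("gelled" positive)."""
    if len(true_labels) != len(predicted_labels):
        raise MetricError("label vectors differ in length")
    tp = fn = fp = tn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t not in (GELLED, NON_GELLED) or p not in (GELLED, NON_GELLED):
            raise MetricError(f"labels must be gelled/non_gelled, got ({t!r}, {p!r})")
        if t == GELLED:
            if p == GELLED:
                tp += 1
            else:
                fn += 1
        else:
            if p == GELLED:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, fn, fp, tn)


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / N."""
    return (cm.TP + cm.TN) / cm.total


def precision(cm: ConfusionMatrix) -> float:
    """TP / (TP + FP); undefined when nothing is predicted gelled."""
    if cm.TP + cm.FP == 0:
        raise MetricError("precision undefined: no positive predictions")
    return cm.TP / (cm.TP + cm.FP)


def sensitivity(cm: ConfusionMatrix) -> float:
    """TP / (TP + FN); undefined when no gelled eggs are present."""
    if cm.TP + cm.FN == 0:
        raise MetricError("sensitivity undefined: no positive examples")
    return cm.TP / (cm.TP + cm.FN)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's chance-corrected agreement."""
    n = cm.total
    p0 = (cm.TP + cm.TN) / n
    pc = ((cm.TP + cm.FP) * (cm.TP + cm.FN)
          + (cm.FN + cm.TN) * (cm.FP + cm.TN)) / n**2
    if pc == 1:
        raise MetricError("kappa undefined: degenerate single-class table")
    return (p0 - pc) / (1 - pc)


def roc_auc(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Rank-based AUC of gelled-posterior scores against true labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == GELLED
    neg = labels == NON_GELLED
    if not (pos.any() and neg.any()):
        raise MetricError("AUC needs both classes present")
    if pos.sum() + neg.sum() != len(labels):
        raise MetricError("labels must be gelled/non_gelled")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def evaluation_report(true_labels: Sequence[str],
                      predicted_labels: Sequence[str],
                      scores: Sequence[float] | None = None) -> dict:
    """Confusion matrix plus all metrics, as a JSON-ready dict.

    Percentages mirror the field's reporting convention (1 decimal);
    kappa and AUC are given to 2 decimals alongside raw values.
    """
    cm = confusion(true_labels, predicted_labels)
    report = {
        "confusion_matrix": {"TP": cm.TP, "FN": cm.FN, "FP": cm.FP, "TN": cm.TN},
        "accuracy": accuracy(cm),
        "precision": precision(cm),
        "sensitivity": sensitivity(cm),
        "kappa": kappa(cm),
        "accuracy_pct": round(100 * accuracy(cm), 1),
        "precision_pct": round(100 * precision(cm), 1),
        "sensitivity_pct": round(100 * sensitivity(cm), 1),
        "kappa_2dp": round(kappa(cm), 2),
    }
    if scores is not None:
        report["auc"] = roc_auc(scores, true_labels)
        report["auc_2dp"] = round(report["auc"], 2)
    return report
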