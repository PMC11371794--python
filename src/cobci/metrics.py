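"""Classification metrics: tie-corrected ROC AUC, TPR and FPR."""

from __future__ import annotations

import numpy as np
import scipy.stats

__all__ = ["UndefinedMetricError", "auc", "binary_metrics"]


class UndefinedMetricError(ValueError):
    """A metric is undefined for the given label composition."""


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney formulation with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUC needs both classes present")
    ranks = scipy.stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def binary_metrics(labels: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """(TPR, FPR) from hard decisions: TP/(TP+FN) and FP/(FP+TN)."""
    labels = np.asarray(labels)
    predicted = np.asarray(predicted)
    if labels.shape != predicted.shape:
        raise ValueError("labels and predicted must have the same length")
    pos = labels == 1
    neg = labels == 0
    if not pos.any():
        raise UndefinedMetricError("TPR undefined: no positive labels")
    if not neg.any():
        raise UndefinedMetricError("FPR undefined: no negative labels")
    tpr = float((predicted[pos] == 1).sum() / pos.sum())
    fpr = float((predicted[neg] == 1).sum() / neg.sum())
    return tpr, fpr
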