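"""ROC and precision-recall machinery: curves plus AUROC / AUPRC.

AUROC integrates the ROC curve with the trapezoidal rule (equal scores
grouped into one threshold, ties contributing half).  AUPRC uses the
step-wise, right-continuous rule (the average-precision estimator), which
avoids the optimistic bias of trapezoidal interpolation in PR space.
Curve construction is delegated to scikit-learn's threshold sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve


@dataclass
class CurveResult:
    """An ordered curve (x, y points) and the area under it."""

    points: np.ndarray  # shape (k, 2)
    auc: float

    def summary(self, labels: np.ndarray) -> dict:
        labels = np.asarray(labels)
        return {
            "auc": self.auc,
            "n_pos": int((labels == 1).sum()),
            "n_neg": int((labels == 0).sum()),
        }


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1}:
        raise ValueError("labels must be 0/1")
    return scores, labels.astype(int)


def roc_auc(scores, labels) -> CurveResult:
    """ROC curve (FPR, TPR) and trapezoidal AUROC.

    Requires both classes present.  Equivalent to the Mann-Whitney
    statistic: the probability a random positive outscores a random
    negative, ties counting one half.
    """
    scores, labels = _validate(scores, labels)
    if labels.min() == labels.max():
        raise ValueError("AUROC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return CurveResult(points=np.column_stack([fpr, tpr]), auc=auc)


def pr_auc(scores, labels) -> CurveResult:
    """Precision-recall curve and step-wise AUPRC.

    Area = sum over descending-score thresholds of (R_i - R_{i-1}) * P_i,
    i.e. the average-precision estimator; a score-independent classifier
    scores the positive prevalence.
    """
    scores, labels = _validate(scores, labels)
    if labels.sum() == 0:
        raise ValueError("AUPRC needs at least one positive")
    precision, recall, _ = precision_recall_curve(labels, scores)
    # sklearn returns points from high threshold to low, recall increasing
    # when read right-to-left; the step rule sums P * delta-R.
    auc = float(-np.sum(np.diff(recall) * precision[:-1]))
    return CurveResult(points=np.column_stack([recall, precision]), auc=auc)


def scored_summary(scores, labels) -> dict:
    """Both areas in one record: {auroc, auprc, n_pos, n_neg}."""
    scores, labels = _validate(scores, labels)
    return {
        "auroc": roc_auc(scores, labels).auc,
        "auprc": pr_auc(scores, labels).auc,
        "n_pos": int(labels.sum()),
        "n_neg": int((1 - labels).sum()),
    }
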