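"""Classification metrics: Mann-Whitney AUC and confusion-table rates.

Conventions fixed across the package: label 1 (functionally limited) is the
positive class; sensitivity is the correct-identification rate of label 1,
specificity of label 0; accuracy/sensitivity/specificity are reported in
percent, AUC on [0, 1]; tied decision scores contribute one half to the AUC
(the Mann-Whitney convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["MetricSet", "UndefinedMetricError", "auc", "compute_metrics"]


class UndefinedMetricError(ValueError):
    """A metric is undefined on this input (e.g. AUC with one class)."""


@dataclass(frozen=True)
class MetricSet:
    """Performance of one train/test evaluation."""

    auc: float          # [0, 1]
    accuracy: float     # percent
    sensitivity: float  # percent, correct label-1 identification
    specificity: float  # percent, correct label-0 identification

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"auc out of [0, 1]: {self.auc}")
        for name in ("accuracy", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} out of [0, 100]: {v}")

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def auc(scores, labels) -> float:
    """Probability that a random positive outscores a random negative.

    Computed from average ranks (equivalent to the Mann-Whitney U statistic
    normalized by ``n1 * n0``), so tied scores count one half.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = labels.shape[0] - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # average ranks on ties
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def compute_metrics(model, X_test, y_test) -> MetricSet:
    """Evaluate a trained classifier on a test set containing both labels.

    ``model`` must expose ``predict`` (hard 0/1 labels) and
    ``decision_function`` (continuous confidence in label 1).
    """
    y_test = np.asarray(y_test)
    if (y_test == 1).sum() == 0 or (y_test == 0).sum() == 0:
        raise UndefinedMetricError("test set must contain both labels")
    y_pred = np.asarray(model.predict(X_test))
    scores = np.asarray(model.decision_function(X_test), dtype=np.float64)

    tp = int(((y_pred == 1) & (y_test == 1)).sum())
    fn = int(((y_pred == 0) & (y_test == 1)).sum())
    tn = int(((y_pred == 0) & (y_test == 0)).sum())
    fp = int(((y_pred == 1) & (y_test == 0)).sum())
    return MetricSet(
        auc=auc(scores, y_test),
        accuracy=100.0 * (tp + tn) / (tp + tn + fp + fn),
        sensitivity=100.0 * tp / (tp + fn),
        specificity=100.0 * tn / (tn + fp),
    )
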