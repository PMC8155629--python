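"""SVM classifier configuration and training.

The classifier throughout the pipeline is a soft-margin SVM.  The published
analyses of this kind rarely state kernel or regularization choices; the
defaults here (linear kernel, C = 1, no class weighting) are documented in
the methods note and are fully configurable.  Training goes through
scikit-learn's ``SVC``; the compiled solver in :mod:`beamselect._smo` is
used only inside the subset-scoring hot loop and is tested against ``SVC``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

__all__ = ["ClassifierConfig", "train_classifier", "make_svc"]


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameters of the severity classifier.

    Parameters
    ----------
    kernel : {"linear", "rbf"}
        Kernel of the SVM; linear by default (41 subjects, up to 68
        features — a regime where linear decision functions are standard).
    regularization_strength : float
        The SVM cost parameter C (> 0).
    class_weighting : None or "balanced"
        Optional inverse-frequency class weights; off by default.
    seed : int
        Seed forwarded to the estimator (only consumed by stochastic
        sub-procedures; SVC training itself is deterministic).
    """

    kernel: str = "linear"
    regularization_strength: float = 1.0
    class_weighting: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"kernel must be 'linear' or 'rbf', got {self.kernel!r}")
        if not self.regularization_strength > 0:
            raise ValueError(
                f"regularization_strength must be > 0, got {self.regularization_strength}"
            )
        if self.class_weighting not in (None, "balanced"):
            raise ValueError(
                f"class_weighting must be None or 'balanced', got {self.class_weighting!r}"
            )


def make_svc(config: ClassifierConfig) -> SVC:
    """Unfitted sklearn estimator matching ``config``."""
    return SVC(
        kernel=config.kernel,
        C=config.regularization_strength,
        class_weight=config.class_weighting,
        random_state=config.seed,
    )


def train_classifier(X, y, config: ClassifierConfig = ClassifierConfig()) -> SVC:
    """Fit the configured SVM on (normalized) features.

    The returned model exposes ``predict`` (hard labels) and
    ``decision_function`` (continuous score, larger = more confident in
    label 1).  Raises ``ValueError`` on fewer than two rows or a
    single-label training set (the signal of a degenerate resample).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("training set must be 2-D with at least 2 rows")
    if np.unique(y).size < 2:
        raise ValueError("degenerate training set: only one label present")
    return make_svc(config).fit(X, y)
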