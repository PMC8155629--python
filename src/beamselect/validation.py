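"""Resampling validation engines for the severity classifier.

Two schemes, matching how small imaging cohorts are usually validated:

* **bootstrap out-of-bag** — each repetition draws n subjects with
  replacement as the training multiset (n = cohort size) and tests on the
  subjects never drawn (on average ``(1 - 1/n)^n`` of the cohort, ~36%);
* **repeated stratified k-fold cross-validation** — class-proportional
  folds, every subject tested exactly once per repeat, the whole procedure
  repeated with reshuffled folds.

Both engines normalize features with the zero-mean scaler under a
configurable leakage policy: ``"train"`` (default) fits the scaler on the
training rows of each resample; ``"all"`` fits it once on the full cohort,
mimicking published pipelines that normalize before splitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort import FeatureTable
from .metrics import MetricSet, compute_metrics
from .svm import ClassifierConfig, train_classifier

__all__ = [
    "MetricSummary",
    "DegenerateResampleError",
    "draw_bootstrap_indices",
    "bootstrap_validate",
    "stratified_cv",
]

logger = logging.getLogger(__name__)

_METRIC_COLS = ["auc", "accuracy", "sensitivity", "specificity"]


class DegenerateResampleError(RuntimeError):
    """Raised when valid bootstrap resamples cannot be drawn."""


@dataclass
class MetricSummary:
    """Mean and deviation of AUC/accuracy/sensitivity/specificity.

    ``per_repetition`` holds one row per bootstrap repetition or CV fold;
    CV rows additionally carry ``repeat`` and ``fold`` columns.  The
    deviation convention is ``sd_mode``: ``"per_fold"`` takes the SD across
    all individual repetitions/folds, ``"per_repeat_mean"`` first averages
    folds within each CV repeat.
    """

    scheme: str  # "bootstrap" | "stratified_cv"
    per_repetition: pd.DataFrame
    n_redraws: int = 0
    sd_mode: str = "per_fold"
    details: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.scheme not in ("bootstrap", "stratified_cv"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.sd_mode not in ("per_fold", "per_repeat_mean"):
            raise ValueError(f"unknown sd_mode {self.sd_mode!r}")
        if len(self.per_repetition) < 1:
            raise ValueError("at least one repetition required")

    @property
    def n_repetitions(self) -> int:
        return len(self.per_repetition)

    def mean(self) -> dict[str, float]:
        return {c: float(self.per_repetition[c].mean()) for c in _METRIC_COLS}

    def sd(self) -> dict[str, float]:
        df = self.per_repetition
        if self.sd_mode == "per_repeat_mean" and "repeat" in df.columns:
            df = df.groupby("repeat")[_METRIC_COLS].mean()
        if len(df) < 2:
            return {c: 0.0 for c in _METRIC_COLS}
        return {c: float(df[c].std(ddof=1)) for c in _METRIC_COLS}

    def summary(self) -> dict[str, float]:
        out = {}
        m, s = self.mean(), self.sd()
        for c in _METRIC_COLS:
            out[f"{c}_mean"] = m[c]
            out[f"{c}_sd"] = s[c]
        return out


def draw_bootstrap_indices(labels, n_draws, rng, max_rounds=1000):
    """Draw valid with-replacement resamples of ``len(labels)`` rows each.

    A draw is valid when the training multiset contains both classes and
    the out-of-bag complement is non-empty with both classes present
    (otherwise AUC and specificity/sensitivity are undefined).  Invalid
    draws are redrawn; the redraw count is returned for logging.

    Returns ``(boot_idx, oob_mask, n_redraws)`` with shapes (B, n), (B, n).
    """
    y = np.asarray(labels)
    n = y.shape[0]
    pos = y == 1
    boot = rng.integers(0, n, size=(n_draws, n), dtype=np.int64)
    rows = np.arange(n_draws)[:, None]
    n_redraws = 0
    for _ in range(max_rounds):
        oob = np.ones((n_draws, n), dtype=bool)
        oob[rows, boot] = False
        valid = (
            pos[boot].any(axis=1)
            & (~pos)[boot].any(axis=1)
            & (oob & pos).any(axis=1)
            & (oob & ~pos).any(axis=1)
        )
        bad = np.flatnonzero(~valid)
        if bad.size == 0:
            return boot, oob, n_redraws
        n_redraws += bad.size
        boot[bad] = rng.integers(0, n, size=(bad.size, n), dtype=np.int64)
    raise DegenerateResampleError(
        f"could not draw {n_draws} valid bootstrap resamples in {max_rounds} rounds"
    )


def _scale_split(X_train, X_apply, use_sample_sd):
    """Z-score both matrices with train statistics; zero-SD columns pass
    through centred (they carry no information on this resample)."""
    ddof = 1 if use_sample_sd else 0
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=ddof)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (X_train - mu) / sd, (X_apply - mu) / sd


def _pca_project(X_train, X_test, variance_threshold):
    from .selection import pca_reduce  # local import: avoid cycle

    tr, te, _ = pca_reduce(X_train, X_test, variance_threshold)
    return tr, te


def _evaluate_split(
    X, y, train_rows, test_rows, config, leakage, use_sample_sd,
    feature_subset, pca_variance, selector_factory, global_scaled,
) -> MetricSet:
    if selector_factory is not None:
        feature_subset = selector_factory(X[train_rows], y[train_rows])
    if feature_subset is not None:
        cols = np.asarray(sorted(feature_subset), dtype=np.intp)
        Xs = X[:, cols]
        Gs = global_scaled[:, cols] if global_scaled is not None else None
    else:
        Xs, Gs = X, global_scaled
    if leakage == "all":
        Xtr, Xte = Gs[train_rows], Gs[test_rows]
    else:
        Xtr, Xte = _scale_split(Xs[train_rows], Xs[test_rows], use_sample_sd)
    if pca_variance is not None:
        Xtr, Xte = _pca_project(Xtr, Xte, pca_variance)
    model = train_classifier(Xtr, y[train_rows], config)
    return compute_metrics(model, Xte, y[test_rows])


def _global_scaled(X, leakage, use_sample_sd):
    if leakage != "all":
        return None
    scaled, _ = _scale_split(X, X[:0], use_sample_sd)
    return scaled


def bootstrap_validate(
    table: FeatureTable,
    feature_subset=None,
    config: ClassifierConfig = ClassifierConfig(),
    n_repetitions: int = 1000,
    seed: int = 0,
    leakage: str = "train",
    use_sample_sd: bool = False,
    pca_variance: float | None = None,
    selector_factory=None,
    return_details: bool = False,
) -> MetricSummary:
    """Bootstrap out-of-bag validation of an SVM on selected features.

    Each of ``n_repetitions`` valid resamples trains on n-with-replacement
    rows and evaluates the full metric set on the out-of-bag rows.
    Degenerate draws are redrawn (count logged).  Fully reproducible from
    ``seed``.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    if leakage not in ("train", "all"):
        raise ValueError(f"leakage must be 'train' or 'all', got {leakage!r}")
    X, y = table.values, table.labels
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 0xB007)))
    boot, oob, n_redraws = draw_bootstrap_indices(y, n_repetitions, rng)
    if n_redraws:
        logger.info("bootstrap_validate: %d degenerate resamples redrawn", n_redraws)
    gscaled = _global_scaled(X, leakage, use_sample_sd)

    rows = []
    details = []
    for r in range(n_repetitions):
        train_rows = boot[r]
        test_rows = np.flatnonzero(oob[r])
        ms = _evaluate_split(
            X, y, train_rows, test_rows, config, leakage, use_sample_sd,
            feature_subset, pca_variance, selector_factory, gscaled,
        )
        rows.append(ms.as_dict())
        if return_details:
            details.append((train_rows.copy(), test_rows))
    return MetricSummary(
        scheme="bootstrap",
        per_repetition=pd.DataFrame(rows),
        n_redraws=n_redraws,
        details=details,
    )


def stratified_cv(
    table: FeatureTable,
    feature_subset=None,
    config: ClassifierConfig = ClassifierConfig(),
    k: int = 5,
    n_repeats: int = 10,
    seed: int = 0,
    leakage: str = "train",
    use_sample_sd: bool = False,
    pca_variance: float | None = None,
    selector_factory=None,
    sd_mode: str = "per_fold",
    return_details: bool = False,
) -> MetricSummary:
    """Repeated stratified k-fold cross-validation.

    Folds preserve class proportions as closely as integer counts allow and
    partition the cohort within each repeat.  The summary aggregates all
    ``k x n_repeats`` fold-level metric sets; the deviation convention is
    ``sd_mode``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if leakage not in ("train", "all"):
        raise ValueError(f"leakage must be 'train' or 'all', got {leakage!r}")
    X, y = table.values, table.labels
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members < k={k}; use a smaller k"
        )
    ss = np.random.SeedSequence(entropy=(int(seed), 0x5CF0))
    fold_seeds = ss.generate_state(n_repeats) % (2**31)
    gscaled = _global_scaled(X, leakage, use_sample_sd)

    rows = []
    details = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(fold_seeds[rep]))
        for fold, (train_rows, test_rows) in enumerate(skf.split(X, y)):
            ms = _evaluate_split(
                X, y, train_rows, test_rows, config, leakage, use_sample_sd,
                feature_subset, pca_variance, selector_factory, gscaled,
            )
            d = ms.as_dict()
            d["repeat"] = rep
            d["fold"] = fold
            rows.append(d)
            if return_details:
                details.append((rep, fold, train_rows, test_rows))
    return MetricSummary(
        scheme="stratified_cv",
        per_repetition=pd.DataFrame(rows),
        sd_mode=sd_mode,
        details=details,
    )
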