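"""Zero-mean normalization (z-scoring) of region features.

Each feature j is transformed as ``(x_ij - mu_j) / sigma_j`` with mu/sigma
estimated from a designated set of fit rows.  The population standard
deviation (divide by n) is the default convention; the sample convention
(n - 1) is available via ``use_sample_sd``.

Two leakage policies are supported downstream: fitting the scaler on the
training rows of each resample (statistically sound, the default) or once on
all subjects (procedural mimicry of published small-cohort pipelines).  The
policy lives in the validation engines; this module only ever normalizes
with respect to the rows it is told to use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .cohort import FeatureTable

__all__ = ["ScalerParams", "ZeroMeanScaler", "fit_scaler", "apply_scaler"]


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature location/scale of a fitted zero-mean normalizer."""

    means: np.ndarray
    sds: np.ndarray
    fit_row_indices: tuple[int, ...]

    def __post_init__(self):
        means = np.asarray(self.means, dtype=np.float64)
        sds = np.asarray(self.sds, dtype=np.float64)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        if means.shape != sds.shape or means.ndim != 1:
            raise ValueError("means and sds must be 1-D arrays of equal length")
        if not (sds > 0).all():
            raise ValueError("all sds must be strictly positive")

    @property
    def n_features(self) -> int:
        return self.means.shape[0]


class ZeroMeanScaler(TransformerMixin, BaseEstimator):
    """Z-score features using statistics of the rows passed to :meth:`fit`.

    Parameters
    ----------
    use_sample_sd : bool, default False
        Divide by the sample SD (n - 1) instead of the population SD (n).

    Attributes
    ----------
    means_ : ndarray of shape (n_features,)
    sds_ : ndarray of shape (n_features,)
    n_features_in_ : int
    """

    def __init__(self, use_sample_sd: bool = False):
        self.use_sample_sd = use_sample_sd

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64)
        ddof = 1 if self.use_sample_sd else 0
        if self.use_sample_sd and X.shape[0] < 2:
            raise ValueError("sample SD needs at least 2 fit rows")
        self.means_ = X.mean(axis=0)
        self.sds_ = X.std(axis=0, ddof=ddof)
        zero = np.flatnonzero(self.sds_ == 0.0)
        if zero.size:
            raise ValueError(f"zero-variance feature(s) at column index {zero.tolist()}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "means_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"X has {X.shape[1]} features, scaler fitted on {self.n_features_in_}")
        return (X - self.means_) / self.sds_


def fit_scaler(
    table: FeatureTable, rows=None, use_sample_sd: bool = False
) -> ScalerParams:
    """Fit normalization statistics over ``rows`` (all rows if ``None``).

    Raises ``ValueError`` naming any zero-variance feature over the fit rows.
    """
    if rows is None:
        rows = np.arange(table.n_subjects)
    rows = np.asarray(rows, dtype=np.intp)
    if rows.size == 0:
        raise ValueError("rows must be non-empty")
    X = table.values[rows]
    ddof = 1 if use_sample_sd else 0
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=ddof) if X.shape[0] > ddof else np.zeros(X.shape[1])
    zero = np.flatnonzero(sds == 0.0)
    if zero.size:
        names = [table.feature_names[j] for j in zero.tolist()]
        raise ValueError(f"zero-variance feature(s) over fit rows: {names}")
    return ScalerParams(means=means, sds=sds, fit_row_indices=tuple(int(r) for r in rows))


def apply_scaler(table: FeatureTable, params: ScalerParams) -> FeatureTable:
    """Return a normalized copy of ``table``; labels and ordering unchanged."""
    if params.n_features != table.n_features:
        raise ValueError(
            f"scaler has {params.n_features} features, table has {table.n_features}"
        )
    return FeatureTable(
        subject_ids=list(table.subject_ids),
        labels=table.labels.copy(),
        values=(table.values - params.means) / params.sds,
        feature_names=list(table.feature_names),
        metric_name=table.metric_name,
    )
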