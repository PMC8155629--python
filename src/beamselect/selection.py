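"""Feature selection: beam-search wrapper, ReliefF weighting, PCA reduction.

The central selector is a breadth-limited combinatorial search over feature
subsets ("beam search" with a priority queue):

1. *Initialization* — every 3-combination of the p features is scored by
   the mean out-of-bag AUC of a bootstrap-validated SVM (for p = 68 that is
   C(68,3) = 50,116 subsets); the ``beam_width`` best form the priority
   queue.
2. *Expansion* — each queued subset is extended by every absent feature;
   the deduplicated candidates are scored and the best ``beam_width`` form
   the next queue.
3. *Stopping* — the loop ends when the best candidate improves on the
   previous loop's best mean AUC by less than ``stop_delta`` (default
   0.002), or when subsets reach the full feature count.

The frequency of each feature across the final queue is a stability
measure: features present in most top subsets are the reproducible signal.

ReliefF (nearest-hit/miss feature weighting) and PCA (variance-threshold
projection) are provided as the customary fast baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import FeatureTable
from .scoring import bootstrap_subset_auc
from .svm import ClassifierConfig

__all__ = [
    "SubsetScore",
    "SelectionResult",
    "enumerate_initial_queue",
    "feature_frequency",
    "beam_search",
    "BeamSearchSelector",
    "relieff_weights",
    "select_top_relieff",
    "ReliefFSelector",
    "pca_reduce",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubsetScore:
    """A feature subset with its bootstrap-AUC evaluation."""

    features: tuple[int, ...]
    mean_auc: float
    sd_auc: float
    n_bootstrap: int

    def __post_init__(self):
        feats = tuple(sorted(int(f) for f in self.features))
        object.__setattr__(self, "features", feats)
        if len(feats) == 0 or len(set(feats)) != len(feats):
            raise ValueError("features must be a non-empty duplicate-free set")


@dataclass
class SelectionResult:
    """Outcome of a beam-search run."""

    optimal_subset: tuple[int, ...]
    final_queue: list[SubsetScore]
    frequencies: dict[int, float]
    auc_trace: list[float]
    stopped_by: str = "stop_delta"  # or "exhausted"
    n_scored: int = 0
    queue_history: list = field(default_factory=list, repr=False)


def enumerate_initial_queue(n_features: int, k_init: int = 3) -> list[tuple[int, ...]]:
    """All unordered ``k_init``-subsets of ``range(n_features)``, sorted."""
    if not 1 <= k_init <= n_features:
        raise ValueError(f"k_init must lie in [1, {n_features}], got {k_init}")
    return list(combinations(range(n_features), k_init))


def feature_frequency(queue: list[SubsetScore]) -> dict[int, float]:
    """Fraction of queue subsets containing each feature."""
    if len(queue) == 0:
        raise ValueError("queue must be non-empty")
    counts: dict[int, int] = {}
    for sc in queue:
        for f in sc.features:
            counts[f] = counts.get(f, 0) + 1
    return {f: c / len(queue) for f, c in sorted(counts.items())}


def _rank_key(sc: SubsetScore):
    # deterministic: AUC descending, then smaller subsets, then lexicographic
    return (-sc.mean_auc, len(sc.features), sc.features)


def _as_xy(table, y):
    if isinstance(table, FeatureTable):
        return table.values, table.labels
    X = np.asarray(table, dtype=np.float64)
    if y is None:
        raise ValueError("labels required when passing a raw matrix")
    return X, np.asarray(y)


def beam_search(
    table,
    y=None,
    config: ClassifierConfig = ClassifierConfig(),
    beam_width: int = 100,
    stop_delta: float = 0.002,
    k_init: int = 3,
    n_bootstrap: int = 50,
    seed: int = 0,
    leakage: str = "train",
    return_previous_on_stop: bool = False,
    max_loops: int | None = None,
) -> SelectionResult:
    """Wrapper feature selection by beam search over bootstrap-AUC scores.

    ``table`` may be a :class:`FeatureTable` or a raw matrix with ``y``.
    Deterministic given ``seed``: each subset's bootstrap resampling seed
    derives from ``(seed, subset)``, so identical subsets score identically
    across loops and runs; scores are cached.

    When the search stops because the improvement fell below
    ``stop_delta``, the queue of the terminating loop is returned (set
    ``return_previous_on_stop`` to keep the previous loop instead).  When
    it runs out of features to add, the queue of the best-scoring loop is
    returned.
    """
    X, yv = _as_xy(table, y)
    p = X.shape[1]
    if beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    cache: dict[tuple[int, ...], SubsetScore] = {}

    def score_all(subsets):
        out = []
        for s in subsets:
            sc = cache.get(s)
            if sc is None:
                mean, sd = bootstrap_subset_auc(
                    X, yv, s, config=config, n_bootstrap=n_bootstrap,
                    master_seed=seed, leakage=leakage,
                )
                sc = SubsetScore(s, mean, sd, n_bootstrap)
                cache[s] = sc
            out.append(sc)
        return out

    initial = enumerate_initial_queue(p, k_init)
    scored = sorted(score_all(initial), key=_rank_key)
    queue = scored[:beam_width]
    history = [queue[0].mean_auc]
    queue_history = [queue]
    logger.info(
        "beam loop 0: scored %d initial subsets, best AUC %.4f",
        len(initial), history[0],
    )

    stopped_by = "exhausted"
    loop = 0
    while True:
        if max_loops is not None and loop >= max_loops:
            stopped_by = "max_loops"
            break
        if len(queue[0].features) >= p:
            break
        candidates = sorted(
            {
                tuple(sorted(sc.features + (f,)))
                for sc in queue
                for f in range(p)
                if f not in sc.features
            }
        )
        if not candidates:
            break
        loop += 1
        new_queue = sorted(score_all(candidates), key=_rank_key)[:beam_width]
        best_new = new_queue[0].mean_auc
        improvement = best_new - history[-1]
        history.append(best_new)
        queue_history.append(new_queue)
        logger.info(
            "beam loop %d: %d candidates, best AUC %.4f (delta %+.4f)",
            loop, len(candidates), best_new, improvement,
        )
        if improvement < stop_delta:
            stopped_by = "stop_delta"
            queue = queue_history[-2] if return_previous_on_stop else new_queue
            break
        queue = new_queue

    if stopped_by in ("exhausted", "max_loops"):
        queue = queue_history[int(np.argmax(history))]

    return SelectionResult(
        optimal_subset=queue[0].features,
        final_queue=queue,
        frequencies=feature_frequency(queue),
        auc_trace=history,
        stopped_by=stopped_by,
        n_scored=len(cache),
        queue_history=queue_history,
    )


class BeamSearchSelector(SelectorMixin, BaseEstimator):
    """sklearn-style transformer exposing the beam-search wrapper selector.

    Attributes after :meth:`fit`: ``optimal_subset_``, ``final_queue_``,
    ``frequencies_``, ``auc_trace_``, ``result_``, ``support_``.
    """

    def __init__(
        self,
        beam_width: int = 100,
        stop_delta: float = 0.002,
        k_init: int = 3,
        n_bootstrap: int = 50,
        C: float = 1.0,
        kernel: str = "linear",
        class_weighting: str | None = None,
        leakage: str = "train",
        return_previous_on_stop: bool = False,
        random_state: int = 0,
    ):
        self.beam_width = beam_width
        self.stop_delta = stop_delta
        self.k_init = k_init
        self.n_bootstrap = n_bootstrap
        self.C = C
        self.kernel = kernel
        self.class_weighting = class_weighting
        self.leakage = leakage
        self.return_previous_on_stop = return_previous_on_stop
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        config = ClassifierConfig(
            kernel=self.kernel,
            regularization_strength=self.C,
            class_weighting=self.class_weighting,
            seed=self.random_state,
        )
        self.result_ = beam_search(
            X, y, config=config, beam_width=self.beam_width,
            stop_delta=self.stop_delta, k_init=self.k_init,
            n_bootstrap=self.n_bootstrap, seed=self.random_state,
            leakage=self.leakage,
            return_previous_on_stop=self.return_previous_on_stop,
        )
        self.optimal_subset_ = self.result_.optimal_subset
        self.final_queue_ = self.result_.final_queue
        self.frequencies_ = self.result_.frequencies
        self.auc_trace_ = self.result_.auc_trace
        self.n_features_in_ = X.shape[1]
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[list(self.optimal_subset_)] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def relieff_weights(X, y, k_neighbors: int = 10, n_sampling: int | None = None) -> np.ndarray:
    """ReliefF feature weights for a binary-labelled matrix.

    For each sampled instance the ``k_neighbors`` nearest same-class hits
    and nearest other-class misses (Manhattan distance on range-scaled
    features, ties broken by row order) update each feature's weight by
    ``-diff/(m k)`` for hits and ``P(miss)/(1 - P(own)) * diff/(m k)`` for
    misses, with ``diff`` normalized by the feature's range (zero-range
    features contribute zero).  Deterministic: instances are visited in row
    order (all of them unless ``n_sampling`` truncates).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n, p = X.shape
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present")
    if not 1 <= k_neighbors < counts.min():
        raise ValueError(
            f"k_neighbors must lie in [1, {counts.min() - 1}] "
            f"(smaller class has {counts.min()} members), got {k_neighbors}"
        )
    rng_span = X.max(axis=0) - X.min(axis=0)
    nz = rng_span > 0
    Xs = np.zeros_like(X)
    Xs[:, nz] = X[:, nz] / rng_span[nz]

    dist = cdist(Xs, Xs, metric="cityblock")
    prior = counts / n
    instances = range(n if n_sampling is None else min(int(n_sampling), n))
    m = len(instances)
    if m == 0:
        raise ValueError("n_sampling must allow at least one instance")

    W = np.zeros(p)
    order_all = np.argsort(dist, axis=1, kind="stable")
    for i in instances:
        ci = y[i]
        order = order_all[i]
        hits = [t for t in order if t != i and y[t] == ci][:k_neighbors]
        misses = [t for t in order if y[t] != ci][:k_neighbors]
        diff_hit = np.abs(Xs[hits] - Xs[i]).sum(axis=0)
        diff_miss = np.abs(Xs[misses] - Xs[i]).sum(axis=0)
        w_miss = prior[1 - ci] / (1.0 - prior[ci])
        W += (-diff_hit + w_miss * diff_miss) / (m * k_neighbors)
    return W


def select_top_relieff(weights, m: int) -> tuple[int, ...]:
    """Indices of the ``m`` largest weights; ties broken by smaller index."""
    weights = np.asarray(weights, dtype=np.float64)
    if not 1 <= m <= weights.shape[0]:
        raise ValueError(f"m must lie in [1, {weights.shape[0]}], got {m}")
    order = np.argsort(-weights, kind="stable")
    return tuple(sorted(int(i) for i in order[:m]))


class ReliefFSelector(SelectorMixin, BaseEstimator):
    """Filter selector keeping the top-weighted ReliefF features.

    ``n_neighbors`` is capped at (smaller class size - 1) during fit.
    Attributes: ``weights_``, ``selected_``, ``support_``.
    """

    def __init__(self, n_features_to_select: int = 10, n_neighbors: int = 10):
        self.n_features_to_select = n_features_to_select
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        k = min(self.n_neighbors, int(np.bincount(y, minlength=2).min()) - 1)
        if k < 1:
            raise ValueError("smaller class too small for ReliefF neighbours")
        self.weights_ = relieff_weights(X, y, k_neighbors=k)
        m = min(self.n_features_to_select, X.shape[1])
        self.selected_ = select_top_relieff(self.weights_, m)
        self.n_features_in_ = X.shape[1]
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[list(self.selected_)] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def pca_reduce(X_train, X_test, variance_threshold: float = 0.95):
    """Project train/test onto the leading principal components of train.

    Keeps the smallest component count whose cumulative explained-variance
    ratio reaches ``variance_threshold`` (all non-degenerate components
    when the threshold is 1).  Returns ``(train_proj, test_proj, n_components)``.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    X_test = np.asarray(X_test, dtype=np.float64)
    if X_train.ndim != 2 or X_train.shape[0] < 2:
        raise ValueError("X_train must be 2-D with at least 2 rows")
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError(f"variance_threshold must lie in (0, 1], got {variance_threshold}")
    if not (X_train.var(axis=0) > 0).any():
        raise ValueError("degenerate training matrix: zero variance everywhere")
    if variance_threshold < 1.0:
        pca = PCA(n_components=variance_threshold, svd_solver="full").fit(X_train)
    else:
        pca = PCA(svd_solver="full").fit(X_train)
        keep = int((pca.explained_variance_ > 1e-12).sum())
        pca = PCA(n_components=max(keep, 1), svd_solver="full").fit(X_train)
    return pca.transform(X_train), pca.transform(X_test), int(pca.n_components_)
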