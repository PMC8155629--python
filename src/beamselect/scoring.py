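"""Bootstrap-AUC scoring of candidate feature subsets.

Each subset's score is the mean out-of-bag AUC of the configured SVM over
``n_bootstrap`` bootstrap resamples.  The resampling seed derives
deterministically from ``(master_seed, subset)``, so a given subset scores
identically wherever it is encountered — across beam-search loops, across
cache hits, and in exhaustive-enumeration cross-checks.

Linear-kernel scoring runs through the compiled kernel in
:mod:`beamselect._smo`; other kernels fall back to sklearn's ``SVC``.
"""

from __future__ import annotations

import numpy as np

from ._smo import bootstrap_aucs_linear
from .metrics import auc as _auc
from .svm import ClassifierConfig, make_svc
from .validation import draw_bootstrap_indices

__all__ = ["subset_rng", "bootstrap_subset_auc"]


def subset_rng(master_seed: int, subset) -> np.random.Generator:
    """Deterministic generator for scoring one subset."""
    entropy = (int(master_seed), 0xBEA2, *sorted(int(f) for f in subset))
    return np.random.default_rng(np.random.SeedSequence(entropy=entropy))


def _slow_aucs(Xsub, y, boot, oob, config, scale_per_draw, global_scaled):
    out = np.empty(boot.shape[0])
    for r in range(boot.shape[0]):
        tr = boot[r]
        te = np.flatnonzero(oob[r])
        if scale_per_draw:
            Xtr = Xsub[tr]
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd = np.where(sd < 1e-12, 1.0, sd)
            Xtr = (Xtr - mu) / sd
            Xte = (Xsub[te] - mu) / sd
        else:
            Xtr, Xte = global_scaled[tr], global_scaled[te]
        model = make_svc(config).fit(Xtr, y[tr])
        out[r] = _auc(model.decision_function(Xte), y[te])
    return out


def bootstrap_subset_auc(
    X,
    y,
    subset,
    config: ClassifierConfig = ClassifierConfig(),
    n_bootstrap: int = 50,
    master_seed: int = 0,
    leakage: str = "train",
    return_aucs: bool = False,
):
    """Mean and SD of out-of-bag AUC for one feature subset.

    ``leakage`` controls normalization: ``"train"`` z-scores with the
    statistics of each bootstrap training multiset (population SD);
    ``"all"`` z-scores once over all rows before resampling.

    Returns ``(mean_auc, sd_auc)`` (SD with ddof=1; 0 when B=1), or the
    full per-repetition AUC vector when ``return_aucs`` is set.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    if leakage not in ("train", "all"):
        raise ValueError(f"leakage must be 'train' or 'all', got {leakage!r}")
    subset = tuple(sorted(int(f) for f in subset))
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    X = np.asarray(X, dtype=np.float64)
    if len(set(subset)) != len(subset) or subset[0] < 0 or subset[-1] >= X.shape[1]:
        raise ValueError(f"invalid feature subset {subset} for {X.shape[1]} features")
    y = np.asarray(y)

    rng = subset_rng(master_seed, subset)
    boot, oob, _ = draw_bootstrap_indices(y, n_bootstrap, rng)
    Xsub = np.ascontiguousarray(X[:, list(subset)])
    scale_per_draw = leakage == "train"
    if not scale_per_draw:
        mu = Xsub.mean(axis=0)
        sd = Xsub.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        Xglob = (Xsub - mu) / sd
    else:
        Xglob = None

    if config.kernel == "linear":
        aucs = bootstrap_aucs_linear(
            Xglob if not scale_per_draw else Xsub,
            y.astype(np.int8),
            boot,
            oob,
            C=config.regularization_strength,
            class_weight=config.class_weighting,
            scale_per_draw=scale_per_draw,
        )
    else:
        aucs = _slow_aucs(Xsub, y, boot, oob, config, scale_per_draw, Xglob)

    if return_aucs:
        return aucs
    sd_auc = float(np.std(aucs, ddof=1)) if n_bootstrap > 1 else 0.0
    return float(np.mean(aucs)), sd_auc
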