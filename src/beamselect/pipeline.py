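"""Experiment orchestration: cohort -> normalization -> selection ->
classification -> resampling validation -> report table.

`run_experiment` executes a configurable grid of feature selectors
(none / PCA / ReliefF / beam search) crossed with validation schemes
(bootstrap out-of-bag / repeated stratified 5-fold CV) on one cohort, and
returns a report with mean +/- SD of AUC, accuracy, sensitivity and
specificity per combination — the standard summary grid of this kind of
study.

Selection leakage: in the default ``"as_published"`` mode, features are
selected once on the full cohort and the same subset is then
cross-validated on the same subjects (the procedure small-cohort papers
typically report, optimistically biased).  The ``"nested"`` mode repeats
selection inside every training resample; it is slower and gives the
honest generalization estimate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortSpec, FeatureTable, generate_cohort, read_cohort
from .preprocessing import apply_scaler, fit_scaler
from .selection import (
    SelectionResult,
    ReliefFSelector,
    beam_search,
    relieff_weights,
    select_top_relieff,
)
from .svm import ClassifierConfig
from .validation import MetricSummary, bootstrap_validate, stratified_cv

__all__ = ["ExperimentConfig", "ReportTable", "run_experiment", "write_report", "read_report"]

logger = logging.getLogger(__name__)

SELECTORS = ("none", "pca", "relieff", "bs")
VALIDATIONS = ("bootstrap", "stratified_cv")

REPORT_COLUMNS = [
    "feature", "validation", "selector",
    "auc_mean", "auc_sd", "acc_mean", "acc_sd",
    "sens_mean", "sens_sd", "spec_mean", "spec_sd",
]

_SHORT = {"auc": "auc", "accuracy": "acc", "sensitivity": "sens", "specificity": "spec"}


@dataclass
class ExperimentConfig:
    """Everything a full experiment run depends on; one seed drives it all."""

    # exactly one input source
    input_path: str | None = None
    cohort: CohortSpec | None = None

    selectors: tuple[str, ...] = ("none", "pca", "relieff", "bs")
    validation: str = "both"  # "bootstrap" | "stratified_cv" | "both"
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    # beam-search selector
    beam_width: int = 100
    stop_delta: float = 0.002
    k_init: int = 3
    n_bootstrap: int = 50
    return_previous_on_stop: bool = False
    # ReliefF selector
    relieff_k_neighbors: int = 10
    relieff_m: int = 10
    # PCA selector
    pca_variance: float = 0.95
    # validation engines
    bootstrap_repetitions: int = 1000
    cv_k: int = 5
    cv_repeats: int = 10
    cv_sd_mode: str = "per_fold"  # or "per_repeat_mean"
    # normalization / leakage policy
    leakage: str = "train"  # or "all"
    use_sample_sd: bool = False
    selection_mode: str = "as_published"  # or "nested"

    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        self.selectors = tuple(self.selectors)
        self.validate()

    def validate(self) -> None:
        if (self.input_path is None) == (self.cohort is None):
            raise ValueError("exactly one input source required: input_path or cohort")
        bad = [s for s in self.selectors if s not in SELECTORS]
        if bad:
            raise ValueError(f"unknown selector(s) {bad}; choose from {SELECTORS}")
        if not self.selectors:
            raise ValueError("at least one selector required")
        if self.validation not in ("bootstrap", "stratified_cv", "both"):
            raise ValueError(f"unknown validation {self.validation!r}")
        for name in ("beam_width", "k_init", "n_bootstrap", "relieff_k_neighbors",
                     "relieff_m", "bootstrap_repetitions", "cv_k", "cv_repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if not 0.0 < self.pca_variance <= 1.0:
            raise ValueError("pca_variance must lie in (0, 1]")
        if self.leakage not in ("train", "all"):
            raise ValueError("leakage must be 'train' or 'all'")
        if self.selection_mode not in ("as_published", "nested"):
            raise ValueError("selection_mode must be 'as_published' or 'nested'")
        if self.cv_sd_mode not in ("per_fold", "per_repeat_mean"):
            raise ValueError("cv_sd_mode must be 'per_fold' or 'per_repeat_mean'")
        float(self.stop_delta)  # any real is allowed (negative disables stopping)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["classifier"] = asdict(self.classifier)
        if self.cohort is not None:
            d["cohort"] = asdict(self.cohort)
        d["selectors"] = list(self.selectors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if d.get("cohort") is not None:
            c = dict(d["cohort"])
            if "informative_indices" in c:
                c["informative_indices"] = tuple(c["informative_indices"])
            d["cohort"] = CohortSpec(**c)
        if d.get("classifier") is not None and not isinstance(d["classifier"], ClassifierConfig):
            d["classifier"] = ClassifierConfig(**d["classifier"])
        if "selectors" in d:
            d["selectors"] = tuple(d["selectors"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ReportTable:
    """Summary grid: one row per (feature metric, validation, selector)."""

    rows: pd.DataFrame
    selections: dict = field(default_factory=dict, repr=False)
    summaries: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        missing = [c for c in REPORT_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"report missing column(s) {missing}")
        if self.rows[REPORT_COLUMNS].isna().any().any():
            raise ValueError("report has missing cells")
        key = self.rows[["feature", "validation", "selector"]]
        if key.duplicated().any():
            raise ValueError("duplicate (feature, validation, selector) rows")

    @staticmethod
    def concat(reports) -> "ReportTable":
        rows = pd.concat([r.rows for r in reports], ignore_index=True)
        sel: dict = {}
        summ: dict = {}
        for r in reports:
            sel.update(r.selections)
            summ.update(r.summaries)
        return ReportTable(rows=rows, selections=sel, summaries=summ)


def _load_table(config: ExperimentConfig) -> FeatureTable:
    if config.input_path is not None:
        return read_cohort(config.input_path)
    table, _ = generate_cohort(config.cohort)
    return table


def _derived_seed(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence(entropy=(int(seed), *tags)).generate_state(1)[0] % (2**31))


def _select_features(config: ExperimentConfig, table: FeatureTable, selector: str):
    """As-published selection on the full cohort.

    Returns (subset or None, pca_variance or None, artifact)."""
    if selector == "none":
        return None, None, None
    if selector == "pca":
        return None, config.pca_variance, None
    if selector == "relieff":
        Xz = apply_scaler(table, fit_scaler(table, use_sample_sd=config.use_sample_sd)).values
        est = ReliefFSelector(
            n_features_to_select=min(config.relieff_m, table.n_features),
            n_neighbors=config.relieff_k_neighbors,
        ).fit(Xz, table.labels)
        logger.info("relieff selected %s", est.selected_)
        return est.selected_, None, est
    if selector == "bs":
        result = beam_search(
            table,
            config=config.classifier,
            beam_width=config.beam_width,
            stop_delta=config.stop_delta,
            k_init=config.k_init,
            n_bootstrap=config.n_bootstrap,
            seed=_derived_seed(config.seed, 0xBEA2),
            leakage=config.leakage,
            return_previous_on_stop=config.return_previous_on_stop,
        )
        logger.info(
            "beam search optimal subset %s (trace %s)",
            result.optimal_subset, [round(a, 4) for a in result.auc_trace],
        )
        return result.optimal_subset, None, result
    raise ValueError(f"unknown selector {selector!r}")


def _nested_factory(config: ExperimentConfig, selector: str):
    """Selection callable re-run inside each training resample."""
    if selector in ("none", "pca"):
        return None

    if selector == "relieff":
        def factory(X_train, y_train):
            mu = X_train.mean(axis=0)
            sd = X_train.std(axis=0, ddof=1 if config.use_sample_sd else 0)
            sd = np.where(sd < 1e-12, 1.0, sd)
            k = min(config.relieff_k_neighbors, int(np.bincount(y_train, minlength=2).min()) - 1)
            w = relieff_weights((X_train - mu) / sd, y_train, k_neighbors=max(k, 1))
            return select_top_relieff(w, min(config.relieff_m, X_train.shape[1]))
        return factory

    def factory(X_train, y_train):
        result = beam_search(
            X_train, y_train,
            config=config.classifier,
            beam_width=config.beam_width,
            stop_delta=config.stop_delta,
            k_init=config.k_init,
            n_bootstrap=config.n_bootstrap,
            seed=_derived_seed(config.seed, 0xBEA2),
            leakage=config.leakage,
        )
        return result.optimal_subset
    return factory


def run_experiment(config: ExperimentConfig) -> ReportTable:
    """Execute the configured selector x validation grid; deterministic
    from ``config`` (including its seed)."""
    config.validate()
    table = _load_table(config)
    logger.info(
        "experiment: %d subjects (%d/%d), %d features, metric %s",
        table.n_subjects, int((table.labels == 0).sum()), int((table.labels == 1).sum()),
        table.n_features, table.metric_name,
    )
    schemes = VALIDATIONS if config.validation == "both" else (config.validation,)
    if config.selection_mode == "nested" and ("relieff" in config.selectors or "bs" in config.selectors):
        logger.warning(
            "nested selection: features are re-selected inside every training "
            "resample; results are not comparable with as-published mode"
        )

    rows = []
    selections: dict = {}
    summaries: dict = {}
    for selector in config.selectors:
        if config.selection_mode == "as_published":
            subset, pca_var, artifact = _select_features(config, table, selector)
            factory = None
        else:
            subset, artifact = None, None
            pca_var = config.pca_variance if selector == "pca" else None
            factory = _nested_factory(config, selector)
        if artifact is not None:
            selections[selector] = artifact
        for scheme in schemes:
            vseed = _derived_seed(config.seed, SELECTORS.index(selector), VALIDATIONS.index(scheme))
            common = dict(
                feature_subset=subset,
                config=config.classifier,
                seed=vseed,
                leakage=config.leakage,
                use_sample_sd=config.use_sample_sd,
                pca_variance=pca_var,
                selector_factory=factory,
            )
            if scheme == "bootstrap":
                summ = bootstrap_validate(
                    table, n_repetitions=config.bootstrap_repetitions, **common
                )
            else:
                summ = stratified_cv(
                    table, k=config.cv_k, n_repeats=config.cv_repeats,
                    sd_mode=config.cv_sd_mode, **common,
                )
            summaries[(table.metric_name, scheme, selector)] = summ
            s = summ.summary()
            row = {"feature": table.metric_name, "validation": scheme, "selector": selector}
            for long, short in _SHORT.items():
                row[f"{short}_mean"] = s[f"{long}_mean"]
                row[f"{short}_sd"] = s[f"{long}_sd"]
            rows.append(row)
            logger.info(
                "%s / %s / %s: AUC %.3f +/- %.3f, acc %.2f%%",
                table.metric_name, scheme, selector,
                row["auc_mean"], row["auc_sd"], row["acc_mean"],
            )
    return ReportTable(rows=pd.DataFrame(rows, columns=REPORT_COLUMNS),
                       selections=selections, summaries=summaries)


def write_report(report: ReportTable, path) -> None:
    """Serialize the grid as TSV: AUC to 3 decimals, percents to 2."""
    df = report.rows.copy()
    for c in ("auc_mean", "auc_sd"):
        df[c] = df[c].map(lambda v: f"{v:.3f}")
    for c in ("acc_mean", "acc_sd", "sens_mean", "sens_sd", "spec_mean", "spec_sd"):
        df[c] = df[c].map(lambda v: f"{v:.2f}")
    df.to_csv(path, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    """Parse a report TSV back into numbers (at printed precision)."""
    return pd.read_csv(path, sep="\t")


def write_selection(result: SelectionResult, feature_names, tsv_path, json_path=None) -> None:
    """Feature-frequency table (TSV) plus a JSON sidecar with the AUC trace
    and the final priority queue."""
    rows = [
        {"feature_index": f, "feature_name": feature_names[f], "frequency": freq}
        for f, freq in sorted(result.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    pd.DataFrame(rows, columns=["feature_index", "feature_name", "frequency"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    if json_path is not None:
        payload = {
            "optimal_subset": list(result.optimal_subset),
            "stopped_by": result.stopped_by,
            "auc_trace": result.auc_trace,
            "n_scored": result.n_scored,
            "final_queue": [
                {
                    "features": list(sc.features),
                    "mean_auc": sc.mean_auc,
                    "sd_auc": sc.sd_auc,
                    "n_bootstrap": sc.n_bootstrap,
                }
                for sc in result.final_queue
            ],
        }
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
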