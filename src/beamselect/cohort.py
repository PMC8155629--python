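"""Synthetic cohorts of region-wise white-matter diffusion features.

The clinical datasets this kind of analysis runs on (region-averaged LDH or
FA values for a few dozen dystonia patients dichotomized by severity) are
typically private.  This module generates feature tables with the same
statistical shape — two imbalanced groups, 68 atlas regions, a small set of
genuinely discriminative regions buried in noise — so the selection and
validation machinery can be exercised and tested end to end.

The generative model is deliberately simple: each region is Gaussian with a
region-specific baseline mean and standard deviation drawn once per cohort;
"informative" regions have their group-1 mean shifted by ``effect_size``
pooled standard deviations; optional equicorrelated blocks of adjacent
regions mimic anatomically neighbouring structures.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "FeatureTable",
    "GroundTruth",
    "CohortError",
    "CohortParseError",
    "default_region_names",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]


class CohortError(ValueError):
    """Invalid cohort specification or feature table."""


class CohortParseError(CohortError):
    """Malformed cohort CSV; message carries the offending location."""


#: Atlas structures named in the severity study's optimal subsets, keyed by
#: their 1-based atlas index.  The remaining region names of the 68-region
#: ICBM-DTI-81 white-matter parcellation are synthesized placeholders.
NAMED_REGIONS = {
    7: "Corticospinal_tract_R",
    8: "Corticospinal_tract_L",
    11: "Inferior_cerebellar_peduncle_R",
    12: "Inferior_cerebellar_peduncle_L",
    19: "Posterior_limb_of_internal_capsule_R",
    27: "Posterior_corona_radiata_R",
    49: "Tapetum_R",
    54: "Middle_frontal_blade_L",
    58: "Pre-central_blade_L",
    61: "Superior_parietal_blade_R",
    64: "Parieto-temporal_blade_L",
}


def default_region_names(n_features: int = 68) -> list[str]:
    """Region labels: ``"08_Corticospinal_tract_L"`` style, 1-based prefix."""
    names = []
    for pos in range(1, n_features + 1):
        base = NAMED_REGIONS.get(pos, f"WM_region_{pos:02d}")
        names.append(f"{pos:02d}_{base}")
    return names


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    Defaults emulate the 41-patient severity cohort: 12 non-functionally
    limited vs 29 functionally limited subjects, 68 region features.

    Parameters
    ----------
    n_group0, n_group1 : int
        Subjects per group (label 0 = non-functionally limited,
        label 1 = functionally limited).
    n_features : int
        Number of region features.
    informative_indices : tuple of int
        0-based feature indices carrying a planted group difference.
    effect_size : float
        Standardized mean shift (pooled-SD units) applied to informative
        features in group 1.
    block_correlation : float in [0, 1)
        Within-block equicorrelation of adjacent features; 0 disables.
    block_size : int
        Number of adjacent features per correlated block.
    noise_sd : float
        Scale of the per-feature standard deviations (each region's SD is
        drawn uniformly in ``[0.5, 1.5] * noise_sd``).
    metric_name : str
        Label for the diffusion metric, ``"LDH"`` or ``"FA"``.
    seed : int
        Seed making generation fully reproducible.
    """

    n_group0: int = 12
    n_group1: int = 29
    n_features: int = 68
    informative_indices: tuple[int, ...] = ()
    effect_size: float = 1.0
    block_correlation: float = 0.0
    block_size: int = 4
    noise_sd: float = 0.05
    metric_name: str = "LDH"
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "informative_indices", tuple(sorted(set(int(i) for i in self.informative_indices)))
        )
        self.validate()

    def validate(self) -> None:
        if self.n_group0 < 2:
            raise CohortError(f"n_group0 must be >= 2, got {self.n_group0}")
        if self.n_group1 < 2:
            raise CohortError(f"n_group1 must be >= 2, got {self.n_group1}")
        if self.n_features < 1:
            raise CohortError(f"n_features must be >= 1, got {self.n_features}")
        bad = [i for i in self.informative_indices if not 0 <= i < self.n_features]
        if bad:
            raise CohortError(f"informative_indices out of range [0, {self.n_features}): {bad}")
        if not 0.0 <= self.block_correlation < 1.0:
            raise CohortError(f"block_correlation must lie in [0, 1), got {self.block_correlation}")
        if self.block_size < 1:
            raise CohortError(f"block_size must be >= 1, got {self.block_size}")
        if not self.noise_sd > 0:
            raise CohortError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.metric_name not in ("LDH", "FA"):
            raise CohortError(f"metric_name must be 'LDH' or 'FA', got {self.metric_name!r}")


@dataclass
class FeatureTable:
    """Subjects x regions feature matrix with binary severity labels."""

    subject_ids: list[str]
    labels: np.ndarray
    values: np.ndarray
    feature_names: list[str]
    metric_name: str = "LDH"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.values = np.ascontiguousarray(np.asarray(self.values, dtype=np.float64))
        self.validate()

    def validate(self) -> None:
        n, p = self.values.shape
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise CohortError(
                f"row mismatch: {len(self.subject_ids)} ids, {len(self.labels)} labels, {n} value rows"
            )
        if len(set(self.subject_ids)) != n:
            raise CohortError("duplicate subject ids")
        if len(self.feature_names) != p:
            raise CohortError(f"{len(self.feature_names)} feature names for {p} columns")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise CohortError(f"non-finite value at row {i} ({self.subject_ids[i]}), column {j}")
        labset = set(np.unique(self.labels))
        if not labset <= {0, 1}:
            raise CohortError(f"labels must be 0/1, found {sorted(labset - {0, 1})}")
        if labset != {0, 1}:
            raise CohortError("both label groups must be present")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass(frozen=True)
class GroundTruth:
    """Which features were planted, and the effect sizes actually realized."""

    informative_indices: tuple[int, ...]
    realized_effect_sizes: dict[int, float] = field(default_factory=dict)


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    return np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))


def generate_cohort(spec: CohortSpec) -> tuple[FeatureTable, GroundTruth]:
    """Draw a synthetic cohort from ``spec``.

    Non-informative features are identically distributed in both groups;
    informative features have their group-1 mean shifted by
    ``effect_size x (per-feature SD)``.  Bit-reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(spec.seed), 0x5EED)))
    n = spec.n_group0 + spec.n_group1
    p = spec.n_features

    # region-specific baselines, drawn once per cohort; FA-like value range
    base_mean = rng.uniform(0.3, 0.8, size=p)
    base_sd = spec.noise_sd * rng.uniform(0.5, 1.5, size=p)

    z = rng.standard_normal(size=(n, p))
    if spec.block_correlation > 0.0:
        rho = spec.block_correlation
        for start in range(0, p, spec.block_size):
            stop = min(start + spec.block_size, p)
            shared = rng.standard_normal(size=(n, 1))
            z[:, start:stop] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * z[:, start:stop]

    values = base_mean + base_sd * z
    labels = np.concatenate([np.zeros(spec.n_group0, np.int64), np.ones(spec.n_group1, np.int64)])
    if spec.informative_indices:
        idx = np.asarray(spec.informative_indices)
        values[np.ix_(labels == 1, idx)] += spec.effect_size * base_sd[idx]

    subject_ids = [f"sub-{i + 1:03d}" for i in range(n)]
    table = FeatureTable(
        subject_ids=subject_ids,
        labels=labels,
        values=values,
        feature_names=default_region_names(p),
        metric_name=spec.metric_name,
    )

    realized = {}
    g0 = values[labels == 0]
    g1 = values[labels == 1]
    for j in spec.informative_indices:
        sd = _pooled_sd(g0[:, [j]], g1[:, [j]])[0]
        realized[j] = float((g1[:, j].mean() - g0[:, j].mean()) / sd)
    return table, GroundTruth(spec.informative_indices, realized)


def write_cohort(table: FeatureTable, path) -> None:
    """Write a feature table as UTF-8 CSV: subject_id, label, then regions."""
    table.validate()
    table.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_cohort(path, metric_name: str | None = None) -> FeatureTable:
    """Read a cohort CSV, validating structure cell by cell.

    Raises :class:`CohortParseError` naming the offending row/column for
    malformed headers, non-numeric or missing cells, non-binary labels, and
    duplicate subject ids.
    """
    if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__"):
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:  # file-like
        text = path.read()
    df = pd.read_csv(io.StringIO(text), dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "subject_id" or cols[1] != "label":
        raise CohortParseError(
            f"malformed header: expected 'subject_id,label,<regions...>', got {cols[:3]}..."
        )
    feature_names = cols[2:]
    ids = df["subject_id"].tolist()
    dup = {s for s in ids if ids.count(s) > 1}
    if dup:
        raise CohortParseError(f"duplicate subject id(s): {sorted(dup)}")

    labels = np.empty(len(df), dtype=np.int64)
    for i, raw in enumerate(df["label"]):
        if raw not in ("0", "1"):
            raise CohortParseError(f"row {i} ({ids[i]}): label must be 0 or 1, got {raw!r}")
        labels[i] = int(raw)

    values = np.empty((len(df), len(feature_names)), dtype=np.float64)
    for j, name in enumerate(feature_names):
        col = df[name]
        for i, raw in enumerate(col):
            if raw == "":
                raise CohortParseError(f"missing cell at row {i} ({ids[i]}), column {name!r}")
            try:
                values[i, j] = float(raw)
            except ValueError:
                raise CohortParseError(
                    f"non-numeric cell at row {i} ({ids[i]}), column {name!r}: {raw!r}"
                ) from None
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise CohortParseError(
            f"non-finite cell at row {i} ({ids[i]}), column {feature_names[j]!r}"
        )
    return FeatureTable(
        subject_ids=ids,
        labels=labels,
        values=values,
        feature_names=feature_names,
        metric_name=metric_name or "LDH",
    )
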