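import numpy as np
import pytest

from beamselect import CohortSpec, FeatureTable, generate_cohort


@pytest.fixture(scope="session")
def planted_table():
    """41-subject cohort, 20 regions, 3 strongly planted features."""
    table, gt = generate_cohort(
        CohortSpec(n_features=20, informative_indices=(2, 7, 13), effect_size=2.0, seed=1)
    )
    return table, gt


@pytest.fixture(scope="session")
def null_table():
    """41-subject, 68-region cohort with no planted signal."""
    table, _ = generate_cohort(CohortSpec(seed=3))
    return table


@pytest.fixture()
def separable_table():
    """Hand-built cohort whose first feature separates the groups exactly."""
    rng = np.random.default_rng(9)
    labels = np.array([0] * 12 + [1] * 29)
    values = rng.normal(size=(41, 3))
    values[:, 0] = labels * 10.0 + rng.normal(scale=0.1, size=41)
    return FeatureTable(
        subject_ids=[f"s{i}" for i in range(41)],
        labels=labels,
        values=values,
        feature_names=["sep", "noise_a", "noise_b"],
    )


class StubModel:
    """Fixed-prediction classifier for metric unit tests."""

    def __init__(self, predictions, scores):
        self._p = np.asarray(predictions)
        self._s = np.asarray(scores, dtype=float)

    def predict(self, X):
        return self._p

    def decision_function(self, X):
        return self._s


@pytest.fixture()
def stub_model_cls():
    return StubModel
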