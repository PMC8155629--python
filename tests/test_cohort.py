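import io

import numpy as np
import pytest
from scipy import stats

from beamselect import CohortSpec, FeatureTable, generate_cohort, read_cohort, write_cohort
from beamselect.cohort import CohortError, CohortParseError, default_region_names


class TestCohortSpec:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(n_group0=1), "n_group0"),
            (dict(n_group1=0), "n_group1"),
            (dict(informative_indices=(70,)), "informative_indices"),
            (dict(informative_indices=(-1,)), "informative_indices"),
            (dict(block_correlation=1.0), "block_correlation"),
            (dict(block_correlation=-0.1), "block_correlation"),
            (dict(noise_sd=0.0), "noise_sd"),
            (dict(metric_name="MD"), "metric_name"),
        ],
    )
    def test_invalid_spec_names_field(self, kwargs, field):
        with pytest.raises(CohortError, match=field):
            CohortSpec(**kwargs)

    def test_defaults_match_study_cohort(self):
        spec = CohortSpec()
        assert (spec.n_group0, spec.n_group1, spec.n_features) == (12, 29, 68)


class TestGenerate:
    def test_shape_and_labels(self):
        table, _ = generate_cohort(CohortSpec(n_group0=12, n_group1=29, n_features=68))
        assert table.values.shape == (41, 68)
        assert int((table.labels == 0).sum()) == 12
        assert int((table.labels == 1).sum()) == 29
        assert len(table.feature_names) == 68

    def test_determinism_bit_identical(self):
        spec = CohortSpec(informative_indices=(1, 5), effect_size=1.5, seed=42)
        t1, g1 = generate_cohort(spec)
        t2, g2 = generate_cohort(spec)
        assert np.array_equal(t1.values, t2.values)
        assert t1.subject_ids == t2.subject_ids
        assert g1.realized_effect_sizes == g2.realized_effect_sizes

    def test_planted_effect_realized(self):
        """Empirical standardized mean differences of planted features,
        recomputed directly from the emitted matrices, match the reported
        ground truth exactly and average to the nominal effect size within
        half a pooled SD."""
        realized = []
        for seed in range(20):
            spec = CohortSpec(effect_size=2.0, informative_indices=(0, 1, 2), seed=seed)
            table, gt = generate_cohort(spec)
            g0 = table.values[table.labels == 0]
            g1 = table.values[table.labels == 1]
            for j in (0, 1, 2):
                v0, v1 = g0[:, j], g1[:, j]
                pooled = np.sqrt(
                    ((len(v0) - 1) * v0.var(ddof=1) + (len(v1) - 1) * v1.var(ddof=1))
                    / (len(v0) + len(v1) - 2)
                )
                d = (v1.mean() - v0.mean()) / pooled
                assert abs(gt.realized_effect_sizes[j] - d) < 1e-12
                realized.append(d)
        assert abs(np.mean(realized) - 2.0) < 0.5

    def test_null_cohort_t_statistics_calibrated(self):
        """With no planted signal the per-feature two-sample t statistics
        behave as under the null: ~5% exceed |t| > 1.96."""
        n_exceed = 0
        n_total = 0
        for seed in range(40):
            table, _ = generate_cohort(CohortSpec(effect_size=0.0, seed=1000 + seed))
            g0 = table.values[table.labels == 0]
            g1 = table.values[table.labels == 1]
            t, _ = stats.ttest_ind(g1, g0)
            n_exceed += int((np.abs(t) > 1.96).sum())
            n_total += t.size
        frac = n_exceed / n_total
        assert abs(frac - 0.05) < 0.02

    def test_block_correlation_realized(self):
        spec = CohortSpec(
            n_group0=100, n_group1=100, n_features=8, block_correlation=0.6,
            block_size=4, seed=5,
        )
        table, _ = generate_cohort(spec)
        z = (table.values - table.values.mean(0)) / table.values.std(0)
        within = np.corrcoef(z[:, :4].T)
        off = within[np.triu_indices(4, 1)]
        assert abs(off.mean() - 0.6) < 0.15
        across = np.corrcoef(z[:, 0], z[:, 5])[0, 1]
        assert abs(across) < 0.2

    def test_region_names_place_known_structures(self):
        names = default_region_names(68)
        assert names[7] == "08_Corticospinal_tract_L"
        assert names[6] == "07_Corticospinal_tract_R"
        assert names[26] == "27_Posterior_corona_radiata_R"
        assert len(set(names)) == 68


class TestFeatureTableIO:
    def test_roundtrip_identity(self, tmp_path):
        table, _ = generate_cohort(CohortSpec(seed=2))
        path = tmp_path / "cohort.csv"
        write_cohort(table, path)
        back = read_cohort(path)
        assert back.subject_ids == table.subject_ids
        assert np.array_equal(back.labels, table.labels)
        assert np.array_equal(back.values, table.values)
        assert back.feature_names == table.feature_names

    def _csv(self, text):
        return io.StringIO(text)

    def test_non_binary_label_rejected(self):
        with pytest.raises(CohortParseError, match="label"):
            read_cohort(self._csv("subject_id,label,f1\na,2,0.5\nb,0,0.1\n"))

    def test_missing_cell_named(self):
        with pytest.raises(CohortParseError, match="row 1.*f1"):
            read_cohort(self._csv("subject_id,label,f1\na,0,0.5\nb,1,\n"))

    def test_non_numeric_cell_named(self):
        with pytest.raises(CohortParseError, match="f1.*'x'"):
            read_cohort(self._csv("subject_id,label,f1\na,0,x\nb,1,0.1\n"))

    def test_duplicate_subject_rejected(self):
        with pytest.raises(CohortParseError, match="duplicate"):
            read_cohort(self._csv("subject_id,label,f1\na,0,0.5\na,1,0.1\n"))

    def test_malformed_header_rejected(self):
        with pytest.raises(CohortParseError, match="header"):
            read_cohort(self._csv("id,group,f1\na,0,0.5\n"))


class TestFeatureTableInvariants:
    def test_single_class_rejected(self):
        with pytest.raises(CohortError, match="both label groups"):
            FeatureTable(["a", "b"], np.array([1, 1]), np.ones((2, 1)), ["f"])

    def test_non_finite_rejected(self):
        vals = np.ones((2, 2))
        vals[1, 0] = np.nan
        with pytest.raises(CohortError, match="non-finite"):
            FeatureTable(["a", "b"], np.array([0, 1]), vals, ["f", "g"])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(CohortError):
            FeatureTable(["a", "b"], np.array([0, 1]), np.ones((2, 2)), ["f"])
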