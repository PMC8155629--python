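import numpy as np
import pytest
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from beamselect import (
    BeamSearchSelector,
    CohortSpec,
    ReliefFSelector,
    beam_search,
    enumerate_initial_queue,
    feature_frequency,
    generate_cohort,
    pca_reduce,
    relieff_weights,
    select_top_relieff,
)
from beamselect.selection import SubsetScore


class TestEnumerateInitialQueue:
    def test_three_of_three(self):
        assert enumerate_initial_queue(3, 3) == [(0, 1, 2)]

    def test_matches_bruteforce_enumeration(self):
        got = enumerate_initial_queue(6, 3)
        expect = sorted(
            (a, b, c)
            for a in range(6)
            for b in range(a + 1, 6)
            for c in range(b + 1, 6)
        )
        assert got == expect
        assert len(got) == 20

    @pytest.mark.parametrize("k", [0, 4])
    def test_invalid_k_rejected(self, k):
        with pytest.raises(ValueError):
            enumerate_initial_queue(3, k)


class TestFeatureFrequency:
    def _q(self, *featsets):
        return [SubsetScore(f, 0.5, 0.0, 1) for f in featsets]

    def test_always_present_feature(self):
        q = self._q((0, 1), (0, 2), (0, 3))
        freqs = feature_frequency(q)
        assert freqs[0] == 1.0
        assert freqs.get(5, 0.0) == 0.0  # absent feature

    def test_fractional_count(self):
        q = self._q((1, 2), (1, 3), (1, 4), (2, 3))
        assert feature_frequency(q)[1] == pytest.approx(0.75)

    def test_conservation(self):
        q = self._q((0, 1, 2), (1, 2), (2, 3, 4, 5))
        freqs = feature_frequency(q)
        total = sum(freqs.values()) * len(q)
        assert total == pytest.approx(sum(len(s.features) for s in q))

    def test_empty_queue_rejected(self):
        with pytest.raises(ValueError):
            feature_frequency([])


class TestBeamSearch:
    def test_trivial_full_subset(self):
        table, _ = generate_cohort(CohortSpec(n_features=3, seed=0))
        res = beam_search(table, n_bootstrap=10, k_init=3, seed=0)
        assert res.optimal_subset == (0, 1, 2)
        assert len(res.final_queue) == 1

    def test_queue_sorted_and_deduplicated(self, planted_table):
        table, _ = planted_table
        res = beam_search(table, beam_width=30, n_bootstrap=20, seed=4, max_loops=2)
        for queue in res.queue_history:
            aucs = [sc.mean_auc for sc in queue]
            assert aucs == sorted(aucs, reverse=True)
            assert len({sc.features for sc in queue}) == len(queue)

    def test_trace_non_decreasing_before_termination(self, planted_table):
        table, _ = planted_table
        res = beam_search(table, beam_width=50, n_bootstrap=30, seed=2)
        if res.stopped_by == "stop_delta":
            trace = res.auc_trace[:-1]
        else:
            trace = res.auc_trace
        assert all(b >= a - 1e-12 for a, b in zip(trace, trace[1:]))

    def test_deterministic(self, planted_table):
        table, _ = planted_table
        a = beam_search(table, beam_width=20, n_bootstrap=15, seed=7, max_loops=1)
        b = beam_search(table, beam_width=20, n_bootstrap=15, seed=7, max_loops=1)
        assert a.optimal_subset == b.optimal_subset
        assert a.auc_trace == b.auc_trace
        assert [s.features for s in a.final_queue] == [s.features for s in b.final_queue]

    def test_optimal_is_queue_top_and_frequencies_match(self, planted_table):
        table, _ = planted_table
        res = beam_search(table, beam_width=25, n_bootstrap=20, seed=3, max_loops=1)
        assert res.optimal_subset == res.final_queue[0].features
        assert res.frequencies == feature_frequency(res.final_queue)

    def test_return_previous_on_stop(self, planted_table):
        # every queue of loop t holds subsets of size k_init + t; the default
        # returns the terminating loop's queue, the flag the one before it
        table, _ = planted_table
        kw = dict(beam_width=20, n_bootstrap=20, seed=5, k_init=3)
        last = beam_search(table, **kw)
        prev = beam_search(table, return_previous_on_stop=True, **kw)
        assert last.stopped_by == prev.stopped_by == "stop_delta"
        n_loops = len(last.auc_trace) - 1
        assert {len(s.features) for s in last.final_queue} == {3 + n_loops}
        assert {len(s.features) for s in prev.final_queue} == {3 + n_loops - 1}


class TestBeamSearchSelector:
    def test_sklearn_pipeline_integration(self, planted_table):
        table, _ = planted_table
        from beamselect import ZeroMeanScaler

        sel = BeamSearchSelector(beam_width=20, n_bootstrap=30, random_state=0)
        pipe = Pipeline(
            [("select", sel), ("scale", ZeroMeanScaler()), ("svm", SVC(kernel="linear"))]
        )
        pipe.fit(table.values, table.labels)
        assert pipe.score(table.values, table.labels) > 0.8
        mask = pipe.named_steps["select"].get_support()
        assert mask.sum() == len(sel.optimal_subset_)

    def test_clone_and_params(self):
        from sklearn.base import clone

        sel = BeamSearchSelector(beam_width=5, stop_delta=0.01)
        c = clone(sel)
        assert c.get_params()["beam_width"] == 5
        assert c.get_params()["stop_delta"] == 0.01


class TestReliefF:
    def test_toy_trace_oracle(self):
        """Frozen hand-trace: 4 instances, 2 features, k=1; weights obtained
        by applying the hit/miss update rule exhaustively."""
        X = np.array([[0.0, 0.0], [1.0, 0.1], [0.1, 0.9], [0.9, 1.0]])
        y = np.array([0, 0, 1, 1])
        w = relieff_weights(X, y, k_neighbors=1)
        assert np.allclose(w, [-0.8, 0.8], atol=1e-12)

    def test_matches_independent_oracle_on_random_data(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(14, 5))
        y = np.array([0] * 6 + [1] * 8)
        k = 3
        # independent literal reimplementation of the update rule
        span = X.max(0) - X.min(0)
        Xs = X / span
        prior = np.array([(y == 0).mean(), (y == 1).mean()])
        W = np.zeros(5)
        for i in range(14):
            d = np.abs(Xs - Xs[i]).sum(1)
            order = np.argsort(d, kind="stable")
            hits = [t for t in order if t != i and y[t] == y[i]][:k]
            miss = [t for t in order if y[t] != y[i]][:k]
            w_miss = prior[1 - y[i]] / (1 - prior[y[i]])
            W += (
                -np.abs(Xs[hits] - Xs[i]).sum(0) + w_miss * np.abs(Xs[miss] - Xs[i]).sum(0)
            ) / (14 * k)
        assert np.allclose(relieff_weights(X, y, k_neighbors=k), W, atol=1e-12)

    def test_separating_feature_dominates(self):
        rng = np.random.default_rng(1)
        y = np.array([0] * 10 + [1] * 10)
        X = rng.normal(size=(20, 6))
        X[:, 2] = y * 2.0 + rng.normal(scale=0.01, size=20)
        w = relieff_weights(X, y, k_neighbors=3)
        assert np.argmax(w) == 2
        assert w[2] > max(np.delete(w, 2)) + 0.1

    def test_constant_feature_zero_weight(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        X[:, 1] = 4.2
        y = np.array([0] * 6 + [1] * 6)
        w = relieff_weights(X, y, k_neighbors=2)
        assert w[1] == 0.0

    def test_k_too_large_rejected(self):
        X = np.zeros((6, 2))
        y = np.array([0, 0, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="k_neighbors"):
            relieff_weights(X + np.arange(6)[:, None], y, k_neighbors=2)

    def test_selector_estimator(self):
        rng = np.random.default_rng(3)
        y = np.array([0] * 8 + [1] * 12)
        X = rng.normal(size=(20, 10))
        X[:, 4] += y * 3
        sel = ReliefFSelector(n_features_to_select=2, n_neighbors=20).fit(X, y)
        assert 4 in sel.selected_
        assert sel.transform(X).shape == (20, 2)


class TestSelectTopRelieff:
    def test_examples(self):
        assert select_top_relieff([0.9, 0.1, 0.5], 2) == (0, 2)
        assert select_top_relieff([0.2, 0.1, 0.5], 3) == (0, 1, 2)

    def test_ties_prefer_smaller_index(self):
        assert select_top_relieff([0.5, 0.9, 0.5, 0.9], 2) == (1, 3)
        assert select_top_relieff([0.5, 0.9, 0.5, 0.9], 3) == (0, 1, 3)

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(5)
        w = rng.normal(size=30)
        expect = tuple(sorted(sorted(range(30), key=lambda i: (-w[i], i))[:5]))
        assert select_top_relieff(w, 5) == expect

    @pytest.mark.parametrize("m", [0, 4])
    def test_out_of_range_m(self, m):
        with pytest.raises(ValueError):
            select_top_relieff([0.1, 0.2, 0.3], m)


class TestPcaReduce:
    def test_rank_one_data(self):
        t = np.linspace(0, 1, 10)[:, None]
        X = t @ np.array([[1.0, -2.0, 0.5]])
        tr, te, ncomp = pca_reduce(X, X[:3], 0.95)
        assert ncomp == 1
        assert tr.shape == (10, 1)

    def test_threshold_one_is_lossless(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5))
        tr, te, ncomp = pca_reduce(X, X, 1.0)
        assert ncomp == np.linalg.matrix_rank(X - X.mean(0))
        # full-rank projection is an isometry of the centred data
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(tr), pdist(X), atol=1e-8)

    def test_variance_threshold_is_tight(self, null_table):
        X = null_table.values
        tr, te, ncomp = pca_reduce(X, X[:5], 0.95)
        var = tr.var(axis=0, ddof=1)
        total = (X - X.mean(0)).var(axis=0, ddof=1).sum()
        assert var.sum() / total >= 0.95
        assert (var.sum() - var[-1]) / total < 0.95

    def test_test_rows_use_training_loadings(self):
        rng = np.random.default_rng(6)
        Xtr = rng.normal(size=(20, 4))
        tr, te, _ = pca_reduce(Xtr, Xtr[:7], 0.99)
        assert np.allclose(te, tr[:7])

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate|zero variance"):
            pca_reduce(np.ones((5, 3)), np.ones((2, 3)), 0.95)
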