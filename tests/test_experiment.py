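import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coughkit.audio_core import stream_rng
from coughkit.experiment import (
    CoughDetector,
    FeatureCache,
    PoolExhaustedError,
    Split,
    attach_augmentations,
    compose_class0,
    confusion_metrics,
    evaluate,
    grid_search,
    make_splits,
    run_protocol,
    _event_key,
)
from coughkit.features import SelectionSpec
from coughkit.models import ModelSpec, fit_binary


class TestComposeClass0:
    def test_exact_division(self, small_corpus, rng):
        comp, events = compose_class0("guided", "animal", small_corpus.pool(), 15, rng)
        assert comp.per_type_counts == {t: 3 for t in comp.per_type_counts}
        assert len(events) == 15

    def test_guided_counts_differ_by_at_most_one(self, small_corpus, rng):
        comp, events = compose_class0("guided", "hardware", small_corpus.pool(), 17, rng)
        assert sum(comp.per_type_counts.values()) == 17
        assert set(comp.per_type_counts.values()) <= {3, 4}
        assert len(events) == 17

    def test_semi_guided_uses_all_fifteen_types(self, small_corpus, rng):
        comp, events = compose_class0("semi_guided", None, small_corpus.pool(), 30, rng)
        assert comp.r == 15
        assert len(comp.per_type_counts) == 15
        assert sum(comp.per_type_counts.values()) == 30

    def test_unguided_is_empty(self, small_corpus, rng):
        comp, events = compose_class0("unguided", None, small_corpus.pool(), 12, rng)
        assert comp.r == 0 and comp.per_type_counts == {} and events == []

    def test_sampling_without_replacement(self, small_corpus, rng):
        _, events = compose_class0("guided", "animal", small_corpus.pool(), 15, rng)
        keys = [_event_key(e) for e in events]
        assert len(keys) == len(set(keys))

    def test_pool_exhausted_lists_deficient_types(self, small_corpus, rng):
        with pytest.raises(PoolExhaustedError):
            compose_class0("guided", "animal", small_corpus.pool(), 100, rng)


class TestMakeSplits:
    def test_sizes_for_m106(self, rng):
        plan = make_splits(106, 10, 0.1, rng)
        assert plan.n_splits == 10
        for s in plan.splits:
            assert len(s.cough_train) == 96 and len(s.cough_test) == 10

    def test_partition_property(self, rng):
        plan = make_splits(10, 5, 0.1, rng)
        for s in plan.splits:
            assert len(s.cough_train) == 9 and len(s.cough_test) == 1
            assert sorted(np.r_[s.cough_train, s.cough_test].tolist()) == list(range(10))
            assert not set(s.cough_train) & set(s.cough_test)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            make_splits(1, 5, 0.1, rng)
        with pytest.raises(ValueError):
            make_splits(10, 5, 0.0, rng)


class TestAttachAugmentations:
    def test_counts_and_exclusivity_small(self, small_corpus, shared_cache, rng):
        coughs = small_corpus.coughs  # 12 originals
        _, class0 = compose_class0("semi_guided", None, small_corpus.pool(), 12, rng)
        plan = make_splits(12, 2, 0.1, rng)
        for split in plan.splits:
            Xtr, ytr, Xte, yte = attach_augmentations(split, coughs, class0, shared_cache)
            # 11 train / 1 test originals, each expanded 18x, both classes
            assert (ytr == 1).sum() == 11 * 18 and (ytr == 0).sum() == 11 * 18
            assert (yte == 1).sum() == 1 * 18 and (yte == 0).sum() == 1 * 18

    def test_overlapping_indices_rejected(self, small_corpus, shared_cache):
        coughs = small_corpus.coughs
        bad = Split(np.array([0, 1]), np.array([1, 2]), np.zeros(0, int), np.zeros(0, int))
        with pytest.raises(RuntimeError):
            attach_augmentations(bad, coughs, [], shared_cache)


class TestMetrics:
    def test_known_confusion_table(self):
        row = confusion_metrics(tp=9, fn=1, fp=0, tn=10)
        assert row["recall"] == 0.9
        assert row["FPR"] == 0.0
        assert row["precision"] == 1.0
        assert row["ACC"] == 0.95

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_identities_on_random_tables(self, tp, fn, fp, tn):
        if tp + fn + fp + tn == 0:
            return
        row = confusion_metrics(tp, fn, fp, tn)
        n = tp + fn + fp + tn
        assert row["ACC"] == (tp + tn) / n
        if fn + tp:
            assert row["SEN"] == 1.0 - row["FNR"]
        if fp + tn:
            assert row["SPE"] == 1.0 - row["FPR"]
        p, r = row["precision"], row["recall"]
        if (tp + fp) and (tp + fn) and (p + r):
            assert row["F1"] == pytest.approx(2 * p * r / (p + r))

    def test_evaluate_perfect_separator_has_auc_one(self, rng):
        X = np.vstack([rng.standard_normal((20, 4)), rng.standard_normal((20, 4)) + 10])
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        h = fit_binary(ModelSpec("semi_guided", "RF"), X, y, seed=0)
        row = evaluate(h, X, y)
        assert row["AUC_ROC"] == 1.0 and row["ACC"] == 1.0

    def test_evaluate_cough_only_reports_recall_as_accuracy(self, rng):
        X = np.vstack([rng.standard_normal((30, 4)), rng.standard_normal((30, 4)) + 10])
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        h = fit_binary(ModelSpec("semi_guided", "RF"), X, y, seed=0)
        coughs_only = X[y == 1]
        row = evaluate(h, coughs_only, np.ones(30, int))
        assert row["ACC"] == row["recall"]
        assert np.isnan(row["FPR"]) and np.isnan(row["SPE"])

    def test_evaluate_rejects_bad_labels(self, rng):
        X = np.vstack([rng.standard_normal((10, 4)), rng.standard_normal((10, 4)) + 10])
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        h = fit_binary(ModelSpec("semi_guided", "DT"), X, y, seed=0)
        with pytest.raises(ValueError):
            evaluate(h, X, y + 1)


class TestGridSearch:
    def _split_data(self, rng, sep=3.0):
        data = []
        for _ in range(3):
            X0 = rng.standard_normal((30, 8))
            X1 = rng.standard_normal((30, 8)) + sep
            data.append((np.vstack([X0, X1]), np.r_[np.zeros(30, int), np.ones(30, int)]))
        return data

    def test_single_point_grid_returned(self, rng):
        template = ModelSpec("semi_guided", "RF")
        hp, sel, table = grid_search(template, {"n_estimators": [100]}, self._split_data(rng))
        assert hp == {"n_estimators": 100}
        assert len(table) == 1

    def test_svm_poly_grid_has_nine_points(self, rng):
        template = ModelSpec("semi_guided", "SVM_poly")
        _, _, table = grid_search(template, None, self._split_data(rng))
        assert len(table) == 9

    def test_planted_optimum_selected(self, rng):
        # kNN with k=1 memorizes training data exactly; larger k cannot beat it
        data = self._split_data(rng, sep=0.3)
        template = ModelSpec("semi_guided", "kNN")
        hp, _, table = grid_search(template, {"k": [1, 3]}, data)
        assert hp == {"k": 1}
        best = table.loc[table["mean_ACC"].idxmax()]
        assert best["hyperparameters"] == {"k": 1}

    def test_empty_grid_rejected(self, rng):
        template = ModelSpec("semi_guided", "RF")
        with pytest.raises(ValueError):
            grid_search(template, {"n_estimators": []}, self._split_data(rng))


class TestDetectorProtocol:
    def test_results_shape_and_aggregation(self, small_corpus, shared_cache):
        det = CoughDetector("semi_guided", "DT", n_splits=3, seed=2)
        res = det.fit(small_corpus, cache=shared_cache)
        assert len(res.per_split) == 3
        agg = res.aggregate()
        assert ("ACC", "mean") in agg.columns
        assert "S-B DT-15" == res.name
        assert "ACC=" in res.summary()

    def test_unguided_detector_runs_and_reports_no_auc(self, small_corpus, shared_cache):
        det = CoughDetector("unguided", "USVM_poly", n_splits=2, seed=2)
        res = det.fit(small_corpus, cache=shared_cache)
        assert res.per_split["AUC_ROC"].isna().all()
        assert res.spec.selection == SelectionSpec("variance", 70, "smallest")

    def test_detector_deterministic_given_seed(self, small_corpus, shared_cache):
        r1 = CoughDetector("semi_guided", "DT", n_splits=2, seed=9).fit(
            small_corpus, cache=shared_cache)
        r2 = CoughDetector("semi_guided", "DT", n_splits=2, seed=9).fit(
            small_corpus, cache=shared_cache)
        pd.testing.assert_frame_equal(r1.per_split, r2.per_split)

    def test_run_protocol_table_structure(self, small_corpus, shared_cache):
        table = run_protocol(small_corpus, seed=4, n_splits=2,
                             classifiers={"unguided": ["USVM_poly"],
                                          "guided": ["DT"], "semi_guided": ["DT"]},
                             cache=shared_cache)
        # 1 unguided + 3 guided + 1 semi-guided rows (matched envs only)
        assert len(table) == 5
        assert set(table["scheme"]) == {"unguided", "guided", "semi_guided"}
        assert table["ACC_mean"].between(0, 1).all()
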