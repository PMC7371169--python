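import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ethocv as ec
from ethocv.errors import EmptyDatasetError, UnknownBehaviourError, ValidationError
from ethocv.evaluation import Fold, mean_ci


def oracle_threshold_counts(segments, tau):
    """Independent rule application: segments are (correct, p) pairs."""
    tp = tn = fp = fn = 0
    for correct, p in segments:
        if correct and p >= tau:
            tp += 1
        elif correct:
            fn += 1
        elif p >= tau:
            fp += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def segments_to_arrays(segments):
    """Encode (correct, p) pairs as a 2-class probability problem."""
    n = len(segments)
    proba = np.zeros((n, 2))
    predicted = np.empty(n, dtype=object)
    true = np.empty(n, dtype=object)
    for i, (correct, p) in enumerate(segments):
        predicted[i] = "a"
        proba[i] = (p, 1 - p)
        true[i] = "a" if correct else "b"
    return proba, predicted, true


class TestOverallAccuracy:
    def test_identical_vectors(self):
        v = ["walk"] * 10
        assert ec.overall_accuracy(v, v) == 1.0

    def test_fully_disagreeing(self):
        assert ec.overall_accuracy(["a"] * 5, ["b"] * 5) == 0.0

    def test_three_quarters(self):
        assert ec.overall_accuracy(
            ["a", "b", "b", "b"], ["a", "a", "b", "b"]) == 0.75

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            ec.overall_accuracy(["a"], ["a", "b"])

    def test_empty_rejected(self):
        with pytest.raises(EmptyDatasetError):
            ec.overall_accuracy([], [])


class TestThresholdCounts:
    def test_correct_confident_is_tp(self):
        proba, pred, true = segments_to_arrays([(True, 0.9)])
        c = ec.threshold_counts(proba, pred, true, 0.5, ("a", "b"))
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 0, 0, 0)

    def test_incorrect_unconfident_is_tn(self):
        proba, pred, true = segments_to_arrays([(False, 0.3)])
        c = ec.threshold_counts(proba, pred, true, 0.5, ("a", "b"))
        assert (c.tp, c.tn, c.fp, c.fn) == (0, 1, 0, 0)

    def test_eight_segment_example(self):
        segments = ([(True, 0.9)] * 3 + [(False, 0.2)] * 2
                    + [(False, 0.8)] + [(True, 0.3)] * 2)
        proba, pred, true = segments_to_arrays(segments)
        c = ec.threshold_counts(proba, pred, true, 0.5, ("a", "b"))
        assert (c.tp, c.tn, c.fp, c.fn) == (3, 2, 1, 2)

    def test_equality_counts_as_above(self):
        proba, pred, true = segments_to_arrays([(True, 0.5)])
        c = ec.threshold_counts(proba, pred, true, 0.5, ("a", "b"))
        assert c.tp == 1

    def test_tau_outside_unit_interval_rejected(self):
        proba, pred, true = segments_to_arrays([(True, 0.9)])
        for tau in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValidationError):
                ec.threshold_counts(proba, pred, true, tau, ("a", "b"))

    def test_counts_partition_segments(self):
        rng = np.random.default_rng(0)
        segments = [(bool(rng.integers(2)), float(rng.random()))
                    for _ in range(100)]
        proba, pred, true = segments_to_arrays(segments)
        c = ec.threshold_counts(proba, pred, true, 0.7, ("a", "b"))
        assert c.total == 100

    def test_exhaustive_oracle_up_to_12_segments(self):
        # every combination of the four segment kinds with <= 12 segments
        tau = 0.6
        kinds = [(True, 0.9), (True, 0.3), (False, 0.9), (False, 0.3)]
        for counts in itertools.product(range(4), repeat=4):
            if not 0 < sum(counts) <= 12:
                continue
            segments = [k for k, c in zip(kinds, counts) for _ in range(c)]
            proba, pred, true = segments_to_arrays(segments)
            got = ec.threshold_counts(proba, pred, true, tau, ("a", "b"))
            assert (got.tp, got.tn, got.fp, got.fn) == \
                oracle_threshold_counts(segments, tau)


class TestThresholdAccuracy:
    def test_eq1_arithmetic(self):
        assert ec.threshold_accuracy(ec.ThresholdCounts(3, 2, 1, 2)) == 0.625

    def test_zero_total_rejected(self):
        with pytest.raises(EmptyDatasetError):
            ec.threshold_accuracy(ec.ThresholdCounts(0, 0, 0, 0))

    @given(st.lists(st.tuples(st.booleans(),
                              st.floats(min_value=0.0, max_value=1.0)),
                    min_size=1, max_size=50),
           st.sampled_from([0.5, 0.6, 0.7, 0.8, 0.9]))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_metric_identities(self, segments, tau):
        proba, pred, true = segments_to_arrays(segments)
        counts = ec.threshold_counts(proba, pred, true, tau, ("a", "b"))
        ta = ec.threshold_accuracy(counts)
        oa = ec.overall_accuracy(pred, true)
        ps = [p for _, p in segments]
        if all(p >= tau for p in ps):
            assert ta == pytest.approx(oa)
        if all(p < tau for p in ps):
            assert ta == pytest.approx(1.0 - oa)

    def test_tau_at_or_below_chance_forces_equality_with_overall(self):
        # row maxima of a K-class probability vector are >= 1/K, so any
        # tau <= 1/K makes every segment confident
        rng = np.random.default_rng(1)
        K = 4
        raw = rng.random((200, K))
        proba = raw / raw.sum(axis=1, keepdims=True)
        classes = tuple("abcd")
        pred = ec.model.predict_from_proba(proba, classes)
        true = np.array([classes[i] for i in rng.integers(0, K, 200)],
                        dtype=object)
        counts = ec.threshold_counts(proba, pred, true, 1.0 / K, classes)
        assert ec.threshold_accuracy(counts) == \
            pytest.approx(ec.overall_accuracy(pred, true))
        assert counts.fn == counts.tn == 0


class TestChooseBestThreshold:
    def test_always_wrong_never_confident_degeneracy(self):
        # the degenerate optimum: every answer wrong, every probability
        # under every candidate threshold -> all true negatives
        proba, pred, true = segments_to_arrays([(False, 0.4)] * 20)
        tau, value = ec.choose_best_threshold(proba, pred, true)
        assert tau == 0.5
        assert value == 1.0
        assert ec.overall_accuracy(pred, true) == 0.0

    def test_perfect_model_ties_resolve_to_smallest_tau(self):
        proba, pred, true = segments_to_arrays([(True, 0.95)] * 10)
        tau, value = ec.choose_best_threshold(proba, pred, true)
        assert tau == 0.5
        assert value == 1.0

    def test_single_candidate(self):
        proba, pred, true = segments_to_arrays([(True, 0.9)] * 3)
        tau, _ = ec.choose_best_threshold(
            proba, pred, true, ec.ThresholdConfig((0.7,)))
        assert tau == 0.7

    def test_threshold_config_validation(self):
        with pytest.raises(ValidationError):
            ec.ThresholdConfig((0.5, 0.5))
        with pytest.raises(ValidationError):
            ec.ThresholdConfig((0.0, 0.5))
        with pytest.raises(ValidationError):
            ec.ThresholdConfig(())


class TestFolds:
    def test_seven_individuals_give_seven_folds(self, default_group):
        script = ec.EthogramScript((("walk", 4.0), ("run", 4.0)))
        cohort = ec.generate_cohort(7, default_group, script, 0.3, seed=2)
        ds = ec.build_feature_dataset(ec.dataset_windows(cohort))
        folds = ec.make_individual_folds(ds)
        assert len(folds) == 7
        for f in folds:
            assert len(set(ds.individual_id[f.test_idx])) == 1

    def test_folds_partition_rows(self, small_dataset):
        folds = ec.make_individual_folds(small_dataset)
        all_test = np.concatenate([f.test_idx for f in folds])
        assert sorted(all_test) == list(range(small_dataset.n))

    def test_no_individual_on_both_sides(self, small_dataset):
        for f in ec.make_individual_folds(small_dataset):
            train_ids = set(small_dataset.individual_id[f.train_idx])
            test_ids = set(small_dataset.individual_id[f.test_idx])
            assert not train_ids & test_ids

    def test_single_individual_rejected(self, small_dataset):
        one = small_dataset.subset(
            np.flatnonzero(small_dataset.individual_id
                           == small_dataset.individuals[0]))
        with pytest.raises(ValidationError):
            ec.make_individual_folds(one)

    def test_shuffle_split_sizes(self):
        ds = ec.FeatureDataset(np.random.default_rng(0).normal(size=(1000, 2)),
                               ("f0", "f1"),
                               ["a", "b"] * 500, [f"i{j % 5}" for j in
                                                  range(1000)], ["g"] * 1000)
        folds = ec.make_random_folds(ds, ec.CVConfig(strategy="random",
                                                     seed=1))
        assert len(folds) == 7
        for f in folds:
            assert len(f.test_idx) == 300

    def test_kfold_partitions(self):
        ds = ec.FeatureDataset(np.zeros((700, 1)), ("f0",),
                               ["a", "b"] * 350,
                               [f"i{j % 5}" for j in range(700)],
                               ["g"] * 700)
        folds = ec.make_random_folds(
            ds, ec.CVConfig(strategy="random", mode="kfold", k=7, seed=0))
        assert len(folds) == 7
        sizes = [len(f.test_idx) for f in folds]
        assert sizes == [100] * 7
        all_test = np.concatenate([f.test_idx for f in folds])
        assert sorted(all_test) == list(range(700))

    def test_same_seed_identical_splits(self, small_dataset):
        cfg = ec.CVConfig(strategy="random", seed=9)
        a = ec.make_random_folds(small_dataset, cfg)
        b = ec.make_random_folds(small_dataset, cfg)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.test_idx, fb.test_idx)


class TestConfusionMatrix:
    def test_perfect_predictions_identity(self):
        truths = ["a", "b", "c"] * 4
        conf = ec.confusion_matrix(truths, truths, ("a", "b", "c"))
        np.testing.assert_array_equal(conf.normalized, np.eye(3))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        classes = ("a", "b", "c")
        truths = [classes[i] for i in rng.integers(0, 3, 60)]
        preds = [classes[i] for i in rng.integers(0, 3, 60)]
        conf = ec.confusion_matrix(preds, truths, classes)
        np.testing.assert_allclose(conf.normalized.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_two_class_tally(self):
        conf = ec.confusion_matrix(["a", "b", "b", "b"],
                                   ["a", "a", "b", "b"], ("a", "b"))
        np.testing.assert_allclose(conf.normalized,
                                   [[0.5, 0.5], [0.0, 1.0]])

    def test_unknown_label_rejected(self):
        with pytest.raises(UnknownBehaviourError):
            ec.confusion_matrix(["z"], ["a"], ("a", "b"))

    def test_empty_row_flagged(self):
        conf = ec.confusion_matrix(["a"], ["a"], ("a", "b"))
        assert conf.empty_rows == ("b",)


class TestMergeClasses:
    def _random_confusion(self, seed, classes=("a", "b", "c", "d")):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 20, (len(classes), len(classes)))
        counts[np.arange(len(classes)), np.arange(len(classes))] += 1
        return ec.evaluation.ConfusionMatrix(counts, classes)

    def test_identity_map_unchanged(self):
        conf = self._random_confusion(0)
        merged = ec.merge_classes(conf, {c: (c,) for c in conf.classes})
        np.testing.assert_array_equal(merged.counts, conf.counts)

    def test_merge_all_gives_scalar_one(self):
        conf = self._random_confusion(1)
        merged = ec.merge_classes(conf, {"all": conf.classes})
        assert merged.counts.shape == (1, 1)
        assert merged.normalized[0, 0] == 1.0

    def test_non_partition_rejected(self):
        conf = self._random_confusion(2)
        with pytest.raises(ValidationError):
            ec.merge_classes(conf, {"x": ("a", "b")})  # c, d missing
        with pytest.raises(ValidationError):
            ec.merge_classes(conf, {"x": ("a", "b"), "y": ("b", "c", "d")})

    def test_merged_diagonal_mass_never_decreases(self):
        # counting argument, brute-forced over random matrices/partitions
        rng = np.random.default_rng(3)
        for seed in range(20):
            conf = self._random_confusion(seed)
            labels = rng.integers(0, 2, 4)
            merge_map = {}
            for g in set(labels):
                merge_map[f"m{g}"] = tuple(
                    c for c, l in zip(conf.classes, labels) if l == g)
            if any(not v for v in merge_map.values()):
                continue
            merged = ec.merge_classes(conf, merge_map)
            assert np.trace(merged.counts) >= np.trace(conf.counts)


class TestMeanCI:
    def test_normal_interval(self):
        vals = [0.5, 0.6, 0.7]
        mean, lo, hi = mean_ci(vals)
        assert mean == pytest.approx(0.6)
        assert hi - mean == pytest.approx(mean - lo)
        sem = np.std(vals, ddof=1) / np.sqrt(3)
        assert hi == pytest.approx(0.6 + 1.959963984540054 * sem)

    def test_t_interval_wider(self):
        vals = [0.5, 0.6, 0.7, 0.55]
        _, lo_n, hi_n = mean_ci(vals, method="normal")
        _, lo_t, hi_t = mean_ci(vals, method="t")
        assert hi_t > hi_n and lo_t < lo_n


class TestCrossValidate:
    def test_separable_cohort_near_one(self, default_group):
        # lambda = 0: individuals exchangeable, classes cleanly separable
        script = ec.EthogramScript.uniform(5.0)
        cohort = ec.generate_cohort(3, default_group, script, 0.0, seed=4)
        ds = ec.build_feature_dataset(ec.dataset_windows(cohort))
        rep = ec.cross_validate(ds, ec.HyperParams(10.0, 0.02),
                                ec.make_individual_folds(ds))
        assert rep.mean > 0.9

    def test_fold_values_in_unit_interval_and_mean(self, small_dataset):
        rep = ec.cross_validate(small_dataset, ec.HyperParams(10.0, 0.02),
                                ec.make_individual_folds(small_dataset))
        assert all(0.0 <= v <= 1.0 for v in rep.fold_values)
        assert rep.mean == pytest.approx(np.mean(rep.fold_values))

    def test_shuffled_labels_near_chance(self, small_dataset):
        rng = np.random.default_rng(0)
        y = small_dataset.y.copy()
        rng.shuffle(y)
        ds = ec.FeatureDataset(small_dataset.X, small_dataset.feature_names,
                               y, small_dataset.individual_id,
                               small_dataset.group_id)
        rep = ec.cross_validate(ds, ec.HyperParams(10.0, 0.02),
                                ec.make_individual_folds(ds))
        # binomial noise around 1/8 over ~n test windows
        n = ds.n
        sd = np.sqrt(0.125 * 0.875 / n)
        assert abs(rep.mean - 0.125) < 4 * sd

    def test_single_class_training_fold_rejected(self, two_cluster_dataset):
        n = two_cluster_dataset.n
        bad = [Fold("bad", np.arange(n // 2), np.arange(n // 2, n))]
        with pytest.raises(ValidationError, match="bad"):
            ec.cross_validate(two_cluster_dataset, ec.HyperParams(1.0, 0.5),
                              bad)

    def test_threshold_metric_reports_chosen_tau(self, small_dataset):
        rep = ec.cross_validate(small_dataset, ec.HyperParams(10.0, 0.02),
                                ec.make_individual_folds(small_dataset),
                                metric="threshold")
        assert rep.threshold in (0.5, 0.6, 0.7, 0.8, 0.9)
        assert 0.0 <= rep.mean <= 1.0

    def test_report_serializes(self, small_dataset, tmp_path):
        rep = ec.cross_validate(small_dataset, ec.HyperParams(10.0, 0.02),
                                ec.make_individual_folds(small_dataset))
        rep.to_json(tmp_path / "report.json")
        import json
        payload = json.loads((tmp_path / "report.json").read_text())
        assert payload["params"] == {"C": 10.0, "gamma": 0.02}
        assert payload["extras"]["chance_level"] == 0.125


class TestGridSearch:
    def test_two_by_three_grid_evaluates_six_points(self, two_cluster_dataset):
        grid = ec.GridSpec(c_min=0.1, c_max=10, c_count=2,
                           gamma_min=0.01, gamma_max=1.0, gamma_count=3)
        folds = ec.make_individual_folds(two_cluster_dataset)
        result = ec.grid_search(two_cluster_dataset, grid, folds)
        assert len(result.table) == 6

    def test_best_value_is_table_maximum(self, two_cluster_dataset):
        grid = ec.GridSpec(c_min=0.1, c_max=10, c_count=2,
                           gamma_min=0.01, gamma_max=1.0, gamma_count=2)
        folds = ec.make_individual_folds(two_cluster_dataset)
        result = ec.grid_search(two_cluster_dataset, grid, folds)
        assert result.best_report.mean == \
            pytest.approx(result.table["metric_value"].max())

    def test_tie_breaks_to_smallest_c_then_gamma(self, two_cluster_dataset):
        # fully separable data: many grid points reach accuracy 1.0
        grid = ec.GridSpec(c_min=1.0, c_max=100.0, c_count=2,
                           gamma_min=0.05, gamma_max=0.5, gamma_count=2)
        folds = ec.make_individual_folds(two_cluster_dataset)
        result = ec.grid_search(two_cluster_dataset, grid, folds)
        table = result.table
        top = table[table["metric_value"]
                    >= result.best_report.mean - 1e-12]
        assert result.best_params.C == top["C"].min()
        sub = top[top["C"] == result.best_params.C]
        assert result.best_params.gamma == sub["gamma"].min()
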