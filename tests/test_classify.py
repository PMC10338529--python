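"""Fold construction, grid search, SVM training, baselines, nested CV."""

import numpy as np
import pandas as pd
import pytest

import gaitprint as gp
from gaitprint.classify import TASKS, c_grid, grid_search_C, inner_splits, make_folds

from conftest import FAST_SVM, SMALL_GRID


def _meta(n_subjects, n_conditions, n_trials):
    rows = [
        {"subject_id": s, "footwear_id": f"cond{c}", "trial_id": t}
        for s in range(1, n_subjects + 1)
        for c in range(n_conditions)
        for t in range(1, n_trials + 1)
    ]
    return pd.DataFrame(rows)


class TestCGrid:
    def test_default_grid_has_81_values_spanning_the_range(self):
        grid = c_grid()
        assert len(grid) == 81
        assert grid[0] == 2.0**-5 and grid[-1] == 2.0**15

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            c_grid(5.0, 1.0)


class TestMakeFolds:
    def test_pair_task_balances_every_cell_across_folds(self):
        meta = _meta(5, 4, 10)
        folds = make_folds("subject_x_footwear", meta, k=4, seed=0)
        for _, grp in meta.groupby(["subject_id", "footwear_id"]):
            counts = np.bincount(folds[grp.index], minlength=4)
            assert set(counts) <= {2, 3} and counts.sum() == 10

    def test_subject_task_folds_are_footwear_disjoint(self):
        meta = _meta(6, 4, 5)
        folds = make_folds("subject", meta, k=4, seed=3)
        for f in range(4):
            test_conditions = set(meta.loc[folds == f, "footwear_id"])
            train_conditions = set(meta.loc[folds != f, "footwear_id"])
            assert len(test_conditions) == 1
            assert test_conditions.isdisjoint(train_conditions)

    def test_subject_task_requires_matching_k(self):
        with pytest.raises(ValueError, match="k == n_conditions"):
            make_folds("subject", _meta(6, 3, 5), k=4)

    def test_footwear_task_folds_are_subject_disjoint(self):
        meta = _meta(8, 4, 5)
        folds = make_folds("footwear", meta, k=4, seed=0)
        for f in range(4):
            test_subjects = set(meta.loc[folds == f, "subject_id"])
            assert len(test_subjects) == 2
            assert test_subjects.isdisjoint(set(meta.loc[folds != f, "subject_id"]))

    def test_footwear_task_group_sizes_for_30_subjects(self):
        meta = _meta(30, 4, 2)
        folds = make_folds("footwear", meta, k=4, seed=0)
        sizes = sorted(
            meta.loc[folds == f, "subject_id"].nunique() for f in range(4)
        )
        assert sizes == [7, 7, 8, 8]

    @pytest.mark.parametrize("task", sorted(TASKS))
    def test_partition_property(self, task):
        meta = _meta(8, 4, 4)
        folds = make_folds(task, meta, k=4, seed=1)
        assert folds.min() >= 0 and folds.max() < 4
        assert len(folds) == len(meta)  # every recording in exactly one fold


class TestGridSearch:
    def test_separable_toy_ties_resolve_to_smallest_C(self):
        X = np.array([[0.0], [0.1], [1.0], [0.9]] * 4)
        y = np.array(["A", "A", "B", "B"] * 4)
        best, scores = grid_search_C(X, y, grid=c_grid(step=5.0), seed=0)
        assert np.all(scores == 1.0)
        assert best == 2.0**-5

    def test_one_class_training_rejected(self):
        with pytest.raises(ValueError):
            grid_search_C(np.zeros((4, 2)), np.array(["A"] * 4), grid=SMALL_GRID)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search_C(np.zeros((4, 2)), np.array(["A", "A", "B", "B"]), grid=np.array([]))


class TestLinearStanceSVM:
    def test_separable_two_class_toy(self):
        X = np.array([[0.0], [1.0]])
        model = gp.train_svm(np.repeat(X, 3, axis=0), np.array(["A"] * 3 + ["B"] * 3), C=1.0)
        assert list(model.predict(X)) == ["A", "B"]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 6))
        y = np.array(["A", "B", "C", "D"] * 10)
        test = rng.normal(size=(10, 6))
        m1 = gp.train_svm(X, y, C=1.0)
        perm = rng.permutation(40)
        m2 = gp.train_svm(X[perm], y[perm], C=1.0)
        assert np.array_equal(m1.predict(test), m2.predict(test))

    def test_clearly_separated_class_is_recovered(self):
        # Class C sits far from A and B; a hand-written hyperplane
        # (x0 > 5) separates it, so the one-vs-rest model must too.
        rng = np.random.default_rng(2)
        X = np.vstack(
            [rng.normal(0, 0.3, (10, 2)), rng.normal([1, 1], 0.3, (10, 2)),
             rng.normal([10, 10], 0.3, (10, 2))]
        )
        y = np.array(["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        assert np.all(X[y == "C", 0] > 5.0) and np.all(X[y != "C", 0] < 5.0)
        model = gp.train_svm(X, y, C=10.0)
        test_c = rng.normal([10, 10], 0.3, (5, 2))
        assert np.all(model.predict(test_c) == "C")

    def test_non_finite_features_rejected(self):
        X = np.array([[0.0], [np.nan], [1.0], [1.0]])
        with pytest.raises(ValueError):
            gp.train_svm(X, np.array(["A", "A", "B", "B"]), C=1.0)

    def test_sklearn_param_interface(self):
        model = gp.LinearStanceSVM(C=2.0)
        assert model.get_params()["C"] == 2.0
        model.set_params(C=4.0)
        assert model.C == 4.0


class TestZeroRule:
    @pytest.mark.parametrize(
        "n_classes,expected_pct",
        [(120, 0.8), (30, 3.3), (4, 25.0)],
    )
    def test_balanced_task_baselines(self, n_classes, expected_pct):
        y = np.repeat(np.arange(n_classes), 10)
        assert round(100 * gp.zero_rule_baseline(y), 1) == expected_pct

    def test_modal_class(self):
        assert gp.zero_rule_baseline(["A", "A", "B"]) == pytest.approx(2 / 3)

    def test_tie_keeps_first_encountered_label(self):
        assert gp.zero_rule_baseline(["B", "A", "B", "A"]) == 0.5

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            gp.zero_rule_baseline([])


class TestRunTask:
    def test_each_recording_tested_exactly_once(self, tiny_report, tiny_features):
        X, _, meta = tiny_features
        assert len(tiny_report.predictions) == len(meta)
        assert np.all(np.isin(tiny_report.folds, [0, 1, 2, 3]))
        # pooled test predictions cover the whole dataset
        assert tiny_report.confusion.to_numpy().sum() == len(meta)

    def test_confusion_matrix_consistency(self, tiny_report):
        cm = tiny_report.confusion.to_numpy()
        assert np.trace(cm) / cm.sum() == pytest.approx(tiny_report.pooled_accuracy)
        true_counts = tiny_report.predictions["y_true"].value_counts()
        for cls in tiny_report.confusion.index:
            assert cm[list(tiny_report.confusion.index).index(cls)].sum() == true_counts[cls]

    def test_footwear_task_per_class_test_counts(self, tiny_features):
        X, _, meta = tiny_features
        rep = gp.run_task(X, meta, "footwear", seed=0, grid=SMALL_GRID, **FAST_SVM)
        counts = rep.predictions["y_true"].value_counts()
        # every condition is tested subject x trial times in the pooled folds
        assert set(counts) == {4 * 3}

    def test_scaling_and_tuning_ignore_test_fold(self, tiny_features):
        # Multiplying the fold-0 test recordings by 10 must not change the
        # scaler or the C selected for fold 0 (both are training-only).
        X, _, meta = tiny_features
        rep1 = gp.run_task(X, meta, "subject_x_footwear", seed=1, grid=SMALL_GRID, **FAST_SVM)
        X2 = X.copy()
        test0 = np.flatnonzero(rep1.folds == 0)
        X2[test0] *= 10.0
        rep2 = gp.run_task(X2, meta, "subject_x_footwear", seed=1, grid=SMALL_GRID, **FAST_SVM)
        assert rep1.selected_C[0] == rep2.selected_C[0]
        assert np.array_equal(rep1.models[0].scaler_.data_min_, rep2.models[0].scaler_.data_min_)
        assert np.array_equal(rep1.models[0].scaler_.data_max_, rep2.models[0].scaler_.data_max_)

    def test_rerun_is_deterministic(self, tiny_features, tiny_report):
        X, _, meta = tiny_features
        rep2 = gp.run_task(X, meta, "subject_x_footwear", seed=1, grid=SMALL_GRID, **FAST_SVM)
        assert tiny_report.fold_accuracies == rep2.fold_accuracies
        assert tiny_report.selected_C == rep2.selected_C
        assert tiny_report.predictions.equals(rep2.predictions)

    def test_inner_splits_respect_task_rules(self, tiny_features):
        _, _, meta = tiny_features
        train_meta = meta[meta["footwear_id"] != "barefoot"].reset_index(drop=True)
        for tr, va in inner_splits("subject", train_meta, seed=0):
            conds_tr = set(train_meta.loc[tr, "footwear_id"])
            conds_va = set(train_meta.loc[va, "footwear_id"])
            assert conds_tr.isdisjoint(conds_va)
        for tr, va in inner_splits("footwear", meta, seed=0):
            assert set(meta.loc[tr, "subject_id"]).isdisjoint(set(meta.loc[va, "subject_id"]))
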