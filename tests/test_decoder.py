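"""Decoder contracts: grouped folds, tuning, ECOC training/prediction,
cross-validation determinism and leakage prevention."""

import numpy as np
import pytest

from colouremotion import (
    FeatureTable,
    GeneratorConfig,
    HyperParams,
    apply_model,
    chance_level,
    colour_feature_table,
    cross_validate,
    generate,
    grouped_folds,
    predict,
    train,
    tune_hyperparams,
)


def toy_table(n_per_class=20, n_classes=2, spread=10.0, seed=0, classes=None):
    """Well-separated Gaussian clouds, one participant per row."""
    rng = np.random.default_rng(seed)
    classes = classes or [f"c{i}" for i in range(n_classes)]
    X, labels = [], []
    for i, cls in enumerate(classes):
        X.append(rng.normal(loc=i * spread, scale=0.5, size=(n_per_class, 3)))
        labels += [cls] * n_per_class
    X = np.vstack(X)
    groups = np.array([f"p{i}" for i in range(len(labels))], dtype=object)
    return FeatureTable(
        X=X, labels=np.array(labels, dtype=object), groups=groups,
        feature_names=("f0", "f1", "f2"), classes=tuple(classes), task="colour",
    )


class TestGroupedFolds:
    def test_balanced_partition_711_participants(self):
        ids = [f"p{i}" for i in range(711)]
        folds = grouped_folds(ids, k=10, seed=0)
        sizes = sorted(len(folds.participants_in(f)) for f in range(10))
        assert set(sizes) == {71, 72}
        assert sum(sizes) == 711

    def test_partition_covers_every_participant_once(self):
        ids = [f"p{i}" for i in range(23)]
        folds = grouped_folds(ids, k=4, seed=3)
        seen = [p for f in range(4) for p in folds.participants_in(f)]
        assert sorted(seen) == sorted(ids)

    def test_deterministic_given_seed(self):
        ids = [f"p{i}" for i in range(50)]
        a = grouped_folds(ids, k=5, seed=7)
        b = grouped_folds(ids, k=5, seed=7)
        assert a.assignment == b.assignment
        c = grouped_folds(ids, k=5, seed=8)
        assert a.assignment != c.assignment

    def test_fewer_participants_than_folds_rejected(self):
        with pytest.raises(ValueError, match="< 5 folds"):
            grouped_folds(["a", "b", "c"], k=5, seed=0)

    def test_row_level_ids_collapse_to_participants(self):
        ids = np.repeat([f"p{i}" for i in range(12)], 12)  # 12 rows each
        folds = grouped_folds(ids, k=3, seed=0)
        assert len(folds.assignment) == 12


class TestHyperParams:
    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            HyperParams(C=0.0, kernel_width=1.0)
        with pytest.raises(ValueError):
            HyperParams(C=1.0, kernel_width=-1.0)

    def test_singleton_grid_short_circuits(self):
        table = toy_table()
        p = HyperParams(3.0, 0.5)
        assert tune_hyperparams(table, [p], k=2, seed=0) is p

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tune_hyperparams(toy_table(), [], k=2, seed=0)

    def test_tie_breaks_towards_smaller_c_then_width(self):
        # trivially separable: every grid point scores 1.0
        table = toy_table(n_per_class=10, spread=50.0)
        grid = [
            HyperParams(10.0, 1.0), HyperParams(1.0, 1.0),
            HyperParams(1.0, 0.1), HyperParams(10.0, 0.1),
        ]
        best = tune_hyperparams(table, grid, k=2, seed=0)
        assert best == HyperParams(1.0, 0.1)

    def test_grid_search_never_beaten_by_other_grid_points(self):
        table = toy_table(n_per_class=15, n_classes=3, spread=2.0, seed=5)
        grid = [HyperParams(c, w) for c in (0.1, 10.0) for w in (0.01, 1.0)]

        def inner_cv_accuracy(params):
            res = cross_validate(table, k=3, grid=[params], seed=0)
            return res.accuracy

        best = tune_hyperparams(table, grid, k=3, seed=0)
        # exhaustive evaluation of the grid is its own oracle
        best_score = inner_cv_accuracy(best)
        assert best_score >= max(inner_cv_accuracy(p) for p in grid) - 1e-9


class TestTrainPredict:
    def test_separable_two_class_perfect_training_recall(self):
        table = toy_table()
        model = train(table, HyperParams(10.0, 0.5))
        labels, scores = predict(model, table.X)
        assert (labels == table.labels).all()
        assert scores.shape == (table.n_rows, 2)

    def test_label_attains_row_maximum_score(self):
        table = toy_table(n_classes=4, spread=3.0)
        model = train(table, HyperParams(1.0, 0.1))
        labels, scores = predict(model, table.X)
        for row, label in enumerate(labels):
            assert label == model.classes[scores[row].argmax()]

    def test_scores_finite_for_all_zero_rows(self):
        table = toy_table()
        model = train(table, HyperParams(1.0, 0.5))
        _, scores = predict(model, np.zeros((3, 3)))
        assert np.isfinite(scores).all()

    def test_uniform_prior_on_imbalanced_separable_toy(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 0.3, (90, 3)), rng.normal(8, 0.3, (10, 3))]
        )
        labels = np.array(["big"] * 90 + ["small"] * 10, dtype=object)
        table = FeatureTable(
            X=X, labels=labels, groups=np.arange(100).astype(object),
            feature_names=("a", "b", "c"), classes=("big", "small"), task="colour",
        )
        model = train(table, HyperParams(10.0, 0.5), uniform_prior=True)
        pred, _ = predict(model, X)
        assert (pred == labels).all()

    def test_single_class_rejected(self):
        table = toy_table()
        mask = table.labels == "c0"
        bad = FeatureTable(
            X=table.X[mask], labels=table.labels[mask], groups=table.groups[mask],
            feature_names=table.feature_names, classes=table.classes, task="colour",
        )
        with pytest.raises(ValueError, match="two classes"):
            train(bad, HyperParams(1.0, 0.5))

    def test_dimensionality_mismatch_rejected(self):
        model = train(toy_table(), HyperParams(1.0, 0.5))
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.zeros((2, 7)))


class TestCrossValidate:
    def test_one_prediction_per_row_and_no_leakage(self, small_dataset, fixed_params):
        table = colour_feature_table(small_dataset)
        res = cross_validate(table, k=5, grid=fixed_params, seed=0)
        assert len(res.predictions) == table.n_rows
        assert not any(p is None for p in res.predictions)
        # every participant sits in exactly one fold
        folds = res.fold_assignment
        for pid in np.unique(table.groups):
            assert pid in folds.assignment
        # rows of one participant all predicted out-of-fold together
        assert len(folds.assignment) == small_dataset.n_participants

    def test_determinism(self, small_dataset, fixed_params):
        table = colour_feature_table(small_dataset)
        a = cross_validate(table, k=5, grid=fixed_params, seed=3)
        b = cross_validate(table, k=5, grid=fixed_params, seed=3)
        assert a.accuracy == b.accuracy
        assert a.auc_weighted == b.auc_weighted
        np.testing.assert_array_equal(a.predictions, b.predictions)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_strong_colour_signal_beats_three_times_chance(
        self, small_dataset, fixed_params
    ):
        table = colour_feature_table(small_dataset)
        res = cross_validate(table, k=5, grid=fixed_params, seed=0)
        assert res.accuracy > 3 * chance_level(12)
        assert res.auc_weighted >= 0.5

    def test_nested_vs_global_tuning_modes(self, fixed_params):
        cfg = GeneratorConfig(n_per_country=5, colour_specificity=2.0, seed=4)
        table = colour_feature_table(generate(cfg))
        grid = [HyperParams(1.0, 0.01), HyperParams(10.0, 0.01)]
        nested = cross_validate(table, k=3, grid=grid, seed=0, tuning="nested")
        global_ = cross_validate(table, k=3, grid=grid, seed=0, tuning="global")
        assert len(set(global_.params_per_fold)) == 1
        assert all(p in grid for p in nested.params_per_fold)
        with pytest.raises(ValueError, match="tuning"):
            cross_validate(table, k=3, grid=grid, seed=0, tuning="magic")


class TestApplyModel:
    def test_training_table_reproduces_training_accuracy(self):
        table = toy_table(n_classes=3)
        model = train(table, HyperParams(10.0, 0.5))
        acc, auc, cm = apply_model(model, table)
        pred, _ = predict(model, table.X)
        assert acc == pytest.approx(float((pred == table.labels).mean()))
        assert cm.counts.sum() == table.n_rows
        assert 0.0 <= auc <= 1.0

    def test_permuted_heldout_labels_give_chance_accuracy(self, fixed_params):
        cfg = GeneratorConfig(n_per_country=25, colour_specificity=2.0, seed=8)
        ds = generate(cfg)
        pids = ds.participant_ids
        train_tab = colour_feature_table(ds.subset(pids[:50]))
        test_tab = colour_feature_table(ds.subset(pids[50:]))  # 600 rows
        model = train(train_tab, fixed_params[0])
        rng = np.random.default_rng(0)
        from colouremotion import permute_labels

        permuted = permute_labels(test_tab, rng)
        acc, _, _ = apply_model(model, permuted)
        assert acc == pytest.approx(chance_level(12), abs=0.05)

    def test_empty_table_rejected(self):
        table = toy_table()
        model = train(table, HyperParams(1.0, 0.5))
        empty = FeatureTable(
            X=np.zeros((0, 3)), labels=np.array([], dtype=object),
            groups=np.array([], dtype=object), feature_names=table.feature_names,
            classes=table.classes, task="colour",
        )
        with pytest.raises(ValueError, match="empty"):
            apply_model(model, empty)

    def test_unseen_labels_rejected(self):
        table = toy_table()
        model = train(table, HyperParams(1.0, 0.5))
        alien = FeatureTable(
            X=table.X, labels=np.array(["zz"] * table.n_rows, dtype=object),
            groups=table.groups, feature_names=table.feature_names,
            classes=("zz",), task="colour",
        )
        with pytest.raises(ValueError, match="unseen"):
            apply_model(model, alien)
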