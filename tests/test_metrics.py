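"""Confusion matrices, AUC (against a brute-force pairwise oracle and
sklearn), chance levels, and permutation-test arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from colouremotion import (
    ConfusionMatrix,
    GeneratorConfig,
    HyperParams,
    PermutationResult,
    accuracy,
    chance_level,
    colour_feature_table,
    confusion,
    generate,
    multiclass_auc,
    permutation_test,
    permute_labels,
)
from colouremotion.data import country_feature_table


def pairwise_auc_oracle(scores, labels, classes, weighting):
    """Exhaustive positive-negative pair comparison; ties count 1/2."""
    aucs, weights = [], []
    labels = np.asarray(labels, dtype=object)
    for j, cls in enumerate(classes):
        pos = scores[labels == cls, j]
        neg = scores[labels != cls, j]
        if len(pos) == 0 or len(neg) == 0:
            continue
        wins = sum(
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        )
        aucs.append(wins / (len(pos) * len(neg)))
        weights.append(len(pos) if weighting == "weighted" else 1.0)
    return float(np.average(aucs, weights=weights))


class TestConfusion:
    def test_hand_counted_example(self):
        cm = confusion(["A", "A", "B", "B"], ["A", "B", "B", "B"], ["A", "B"])
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 2]])
        assert cm.recall("A") == 0.5
        assert cm.recall("B") == 1.0
        assert accuracy(cm) == 0.75

    def test_all_correct_gives_identity_proportions(self):
        cm = confusion(["x", "y", "z"], ["x", "y", "z"], ["x", "y", "z"])
        np.testing.assert_array_equal(cm.proportions, np.eye(3))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        classes = ["a", "b", "c"]
        t = rng.choice(classes, 60)
        p = rng.choice(classes, 60)
        cm = confusion(t, p, classes)
        np.testing.assert_allclose(cm.proportions.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_row_flagged_not_divided(self):
        cm = confusion(["a", "a"], ["a", "b"], ["a", "b"])
        assert cm.empty_rows == ["b"]
        assert np.isfinite(cm.proportions).all()

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            confusion(["a"], ["a", "b"], ["a", "b"])
        with pytest.raises(ValueError, match="unknown"):
            confusion(["a"], ["q"], ["a", "b"])

    def test_accuracy_equals_label_agreement(self):
        rng = np.random.default_rng(1)
        classes = list("abcd")
        t = rng.choice(classes, 200)
        p = rng.choice(classes, 200)
        assert accuracy(confusion(t, p, classes)) == pytest.approx(
            float(np.mean(t == p))
        )


class TestChanceLevel:
    @pytest.mark.parametrize("n,expected", [(12, 1 / 12), (4, 0.25), (2, 0.5)])
    def test_values(self, n, expected):
        assert chance_level(n) == pytest.approx(expected)

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            chance_level(1)


class TestMulticlassAUC:
    def test_perfect_ranking_gives_one(self):
        labels = ["a"] * 3 + ["b"] * 3
        scores = np.array(
            [[3, 0], [2, 0], [1, 0], [0, 1], [0, 2], [0, 3]], dtype=float
        )
        assert multiclass_auc(scores, labels, ["a", "b"]) == 1.0

    def test_constant_scores_give_half(self):
        labels = ["a", "a", "b", "b"]
        scores = np.ones((4, 2))
        assert multiclass_auc(scores, labels, ["a", "b"]) == 0.5

    def test_two_class_worked_value(self):
        # positives scored (0.9, 0.4), negatives (0.8, 0.1): 3 of 4 pairs won
        labels = ["pos", "pos", "neg", "neg"]
        scores = np.array([[0.9, 0.0], [0.4, 0.0], [0.8, 0.0], [0.1, 0.0]])
        # class "pos" (col 0): 3 of 4 pairs won -> 0.75; class "neg" (col 1):
        # constant scores -> 0.5; prevalence-weighted average = 0.625
        assert multiclass_auc(scores, labels, ["pos", "neg"]) == pytest.approx(0.625)
        # the positive class alone has AUC 0.75
        pos_auc = pairwise_auc_oracle(scores[:, :1], labels, ["pos"], "macro")
        assert pos_auc == 0.75

    @pytest.mark.parametrize("weighting", ["weighted", "macro"])
    def test_matches_pairwise_oracle_and_sklearn(self, weighting):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        classes = ["a", "b", "c", "d"]
        for trial in range(10):
            n = int(rng.integers(10, 50))
            labels = rng.choice(classes, n)
            while len(set(labels)) < len(classes):
                labels = rng.choice(classes, n)
            scores = np.round(rng.normal(size=(n, 4)), 1)  # coarse -> many ties
            ours = multiclass_auc(scores, labels, classes, weighting)
            oracle = pairwise_auc_oracle(scores, labels, classes, weighting)
            assert ours == pytest.approx(oracle, abs=1e-12)
            per_class = [
                roc_auc_score((labels == c).astype(int), scores[:, j])
                for j, c in enumerate(classes)
            ]
            w = (
                [float((labels == c).sum()) for c in classes]
                if weighting == "weighted"
                else None
            )
            assert ours == pytest.approx(np.average(per_class, weights=w), abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice(["a", "b", "c"], 30)
        if len(set(labels)) < 3:
            return
        scores = rng.normal(size=(30, 3))
        base = multiclass_auc(scores, labels, ["a", "b", "c"])
        for f in (lambda x: 3 * x + 1, np.tanh, lambda x: x ** 3):
            assert multiclass_auc(f(scores), labels, ["a", "b", "c"]) == pytest.approx(
                base, abs=1e-12
            )

    def test_degenerate_class_skipped_with_warning(self):
        labels = ["a", "a", "b", "b"]
        scores = np.random.default_rng(0).normal(size=(4, 3))
        with pytest.warns(UserWarning, match="lacks positives"):
            value = multiclass_auc(scores, labels, ["a", "b", "c"])
        assert 0.0 <= value <= 1.0


class TestPermutation:
    def test_p_value_arithmetic(self):
        # observed below every null -> p = 1; above all 10 nulls -> 1/11
        low = PermutationResult(
            observed_auc=0.4, observed_accuracy=0.05,
            null_auc=tuple(np.linspace(0.45, 0.55, 10)),
            null_accuracy=tuple(np.linspace(0.06, 0.12, 10)),
            n_perm=10, seed=0,
        )
        assert low.p_value_auc == 1.0
        high = PermutationResult(
            observed_auc=0.9, observed_accuracy=0.5,
            null_auc=tuple(np.linspace(0.45, 0.55, 10)),
            null_accuracy=tuple(np.linspace(0.06, 0.12, 10)),
            n_perm=10, seed=0,
        )
        assert high.p_value_auc == pytest.approx(1 / 11)
        assert high.p_value_accuracy == pytest.approx(1 / 11)
        assert high.p_value_auc_ttest < 0.001

    def test_null_length_enforced(self):
        with pytest.raises(ValueError):
            PermutationResult(
                observed_auc=0.5, observed_accuracy=0.1,
                null_auc=(0.5,), null_accuracy=(0.1,), n_perm=2, seed=0,
            )

    def test_permute_preserves_label_multiset(self, small_dataset):
        table = colour_feature_table(small_dataset)
        permuted = permute_labels(table, np.random.default_rng(0))
        assert sorted(permuted.labels) == sorted(table.labels)
        assert not np.array_equal(permuted.labels, table.labels)

    def test_country_permutation_is_participant_level(self, small_dataset):
        table = country_feature_table(small_dataset)
        permuted = permute_labels(table, np.random.default_rng(0))
        assert sorted(permuted.labels) == sorted(table.labels)
        # all rows of one participant keep a single (permuted) country
        for pid in np.unique(permuted.groups):
            assert len(set(permuted.labels[permuted.groups == pid])) == 1

    def test_signal_yields_smallest_attainable_p(self, fixed_params):
        cfg = GeneratorConfig(
            n_per_country=8, colour_specificity=2.0, country_divergence=0.0, seed=2
        )
        table = colour_feature_table(generate(cfg))
        result = permutation_test(
            table, k=4, grid=fixed_params, n_perm=5, seed=0
        )
        assert result.p_value_auc == pytest.approx(1 / 6)
        assert result.observed_auc > max(result.null_auc)

    def test_type_one_error_controlled_on_null_data(self, fixed_params):
        """Colour-unspecific data (s = 0): the permutation p should rarely be
        small. Loose bound, coarse 10-permutation null."""
        rejections = 0
        n_runs = 20
        for seed in range(n_runs):
            cfg = GeneratorConfig(
                n_per_country=4, colour_specificity=0.0, country_divergence=0.0,
                seed=300 + seed,
            )
            table = colour_feature_table(generate(cfg))
            res = permutation_test(table, k=3, grid=fixed_params, n_perm=10,
                                   seed=seed)
            if res.p_value_auc <= 0.2:
                rejections += 1
        assert rejections / n_runs <= 0.35
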