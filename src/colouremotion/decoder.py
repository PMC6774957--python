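"""Multiclass decoding engine.

The decoder reduces the multiclass problem to error-correcting output codes
(ECOC) over binary RBF-kernel support vector machines: a one-vs-one coding
design (all class pairs) whose binary margins are combined by loss-weighted
decoding with the hinge loss. Class scores are the negated average binary
hinge loss, so the predicted class is the score argmax; because ROC analysis
is rank-based, these scores serve directly as the per-class scores for AUC.

Model evaluation is by participant-grouped k-fold cross-validation: folds
partition *participants*, never rows, so no individual ever contributes data
to both the training and the test side of a fold. Hyperparameters (the SVM
complexity constant C and the RBF kernel width) are selected by grid search
on an inner grouped cross-validation within each training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .data import FeatureTable
from .metrics import ConfusionMatrix, confusion, accuracy as cm_accuracy, multiclass_auc

__all__ = [
    "HyperParams",
    "DEFAULT_GRID",
    "DEFAULT_PARAMS",
    "FoldAssignment",
    "CVResult",
    "DecoderModel",
    "grouped_folds",
    "tune_hyperparams",
    "train",
    "predict",
    "cross_validate",
    "apply_model",
]

#: Score assigned to classes absent from a fold's training data (finite so
#: downstream rank statistics stay defined, low enough never to win).
ABSENT_CLASS_SCORE = -1e6


@dataclass(frozen=True, order=True)
class HyperParams:
    """SVM complexity constant C and RBF kernel width (the coefficient of
    the squared distance in exp(-width * ||x - y||^2))."""

    C: float
    kernel_width: float

    def __post_init__(self) -> None:
        if not (self.C > 0 and np.isfinite(self.C)):
            raise ValueError("C must be positive and finite")
        if not (self.kernel_width > 0 and np.isfinite(self.kernel_width)):
            raise ValueError("kernel_width must be positive and finite")


DEFAULT_GRID: tuple[HyperParams, ...] = tuple(
    HyperParams(C=c, kernel_width=w)
    for c in (0.1, 1.0, 10.0, 100.0)
    for w in (0.001, 0.01, 0.1, 1.0)
)

#: Sensible fixed setting for 0-5-scaled rating features when no grid search
#: is requested.
DEFAULT_PARAMS = HyperParams(C=10.0, kernel_width=0.01)


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of participants (not rows) into k folds of near-equal size."""

    k: int
    assignment: dict
    seed: int

    def fold_of(self, participant_id) -> int:
        return self.assignment[participant_id]

    def participants_in(self, fold: int) -> list:
        return [p for p, f in self.assignment.items() if f == fold]

    def test_mask(self, groups: np.ndarray, fold: int) -> np.ndarray:
        return np.array([self.assignment[g] == fold for g in groups])


def grouped_folds(participant_ids, k: int, seed: int) -> FoldAssignment:
    """Randomly partition distinct participants into k balanced folds.

    Fold sizes differ by at most one; the partition is deterministic given
    the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    unique = sorted(set(participant_ids), key=str)
    if len(unique) < k:
        raise ValueError(f"{len(unique)} participants < {k} folds")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    order = rng.permutation(len(unique))
    assignment = {}
    for pos, idx in enumerate(order):
        assignment[unique[idx]] = pos % k
    return FoldAssignment(k=k, assignment=assignment, seed=seed)


@dataclass
class DecoderModel:
    """Fitted ECOC combination of pairwise binary SVMs.

    ``coding_matrix[c, l]`` is +1 / -1 / 0: the role of class c in binary
    learner l (one-vs-one design: each learner separates one class pair).
    """

    classes: tuple[str, ...]
    coding_matrix: np.ndarray
    learners: list
    params: HyperParams
    class_weights: dict
    n_features: int
    uniform_prior: bool

    def score_rows(self, X: np.ndarray) -> np.ndarray:
        """Negated mean binary hinge loss per class; higher = more likely."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features}-dimensional rows, got {X.shape}"
            )
        margins = np.column_stack(
            [learner.decision_function(X) for learner in self.learners]
        )  # (n, L); positive margin favours the +1-coded class
        M = self.coding_matrix  # (C, L)
        # hinge(code * margin) for every (row, class, learner)
        hinge = np.maximum(0.0, 1.0 - M[None, :, :] * margins[:, None, :])
        relevant = (M != 0).astype(float)
        losses = (hinge * relevant[None, :, :]).sum(axis=2) / relevant.sum(axis=1)[None, :]
        return -losses


def _class_weights(labels: np.ndarray, classes, uniform_prior: bool) -> dict:
    if not uniform_prior:
        return {c: 1.0 for c in classes}
    n = len(labels)
    weights = {}
    for c in classes:
        n_c = int((labels == c).sum())
        weights[c] = n / (len(classes) * n_c) if n_c else 0.0
    return weights


def train(
    table: FeatureTable,
    params: HyperParams = DEFAULT_PARAMS,
    uniform_prior: bool = True,
) -> DecoderModel:
    """Fit the one-vs-one ECOC decoder.

    With ``uniform_prior`` the training rows are weighted inversely to their
    class frequency so that unequal class sizes (e.g. unequal country
    samples) do not tilt the decision boundaries.
    """
    labels = np.asarray(table.labels, dtype=object)
    present = [c for c in table.classes if (labels == c).any()]
    if len(present) < 2:
        raise ValueError("training data must contain at least two classes")
    weights = _class_weights(labels, present, uniform_prior)

    pairs = [(i, j) for i in range(len(present)) for j in range(i + 1, len(present))]
    coding = np.zeros((len(present), len(pairs)))
    learners = []
    X = np.asarray(table.X, dtype=float)
    for l, (i, j) in enumerate(pairs):
        coding[i, l] = 1.0
        coding[j, l] = -1.0
        ci, cj = present[i], present[j]
        mask = (labels == ci) | (labels == cj)
        y = np.where(labels[mask] == ci, 1, -1)
        sw = np.where(y == 1, weights[ci], weights[cj])
        svc = SVC(kernel="rbf", C=params.C, gamma=params.kernel_width)
        svc.fit(X[mask], y, sample_weight=sw)
        learners.append(svc)

    return DecoderModel(
        classes=tuple(present),
        coding_matrix=coding,
        learners=learners,
        params=params,
        class_weights=weights,
        n_features=table.n_features,
        uniform_prior=uniform_prior,
    )


def predict(model: DecoderModel, rows: np.ndarray):
    """Decode class labels and per-class scores for a matrix of rows.

    The label is the class minimising the loss-weighted ECOC decoding loss,
    i.e. the argmax of the returned scores; exact ties resolve to the class
    earliest in the vocabulary order.
    """
    scores = model.score_rows(rows)
    labels = np.array([model.classes[i] for i in scores.argmax(axis=1)], dtype=object)
    return labels, scores


def _expand_scores(scores: np.ndarray, model_classes, all_classes) -> np.ndarray:
    """Embed a model's score columns into the full class vocabulary order."""
    out = np.full((scores.shape[0], len(all_classes)), ABSENT_CLASS_SCORE)
    col = {c: j for j, c in enumerate(all_classes)}
    for i, c in enumerate(model_classes):
        out[:, col[c]] = scores[:, i]
    return out


def _subset_table(table: FeatureTable, mask: np.ndarray) -> FeatureTable:
    return FeatureTable(
        X=table.X[mask],
        labels=table.labels[mask],
        groups=table.groups[mask],
        feature_names=table.feature_names,
        classes=table.classes,
        task=table.task,
    )


def tune_hyperparams(
    table: FeatureTable,
    grid,
    k: int = 5,
    seed: int = 0,
    uniform_prior: bool = True,
) -> HyperParams:
    """Grid search maximising grouped cross-validated accuracy.

    Every grid point is evaluated with the same fold assignment; ties are
    broken towards smaller C, then smaller kernel width.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if len(grid) == 1:
        return grid[0]
    folds = grouped_folds(table.groups, k=k, seed=seed)
    best_params, best_acc = None, -1.0
    for params in sorted(grid):  # sorted => deterministic tie-breaking
        correct = total = 0
        for fold in range(k):
            test_mask = folds.test_mask(table.groups, fold)
            model = train(_subset_table(table, ~test_mask), params, uniform_prior)
            pred, _ = predict(model, table.X[test_mask])
            correct += int((pred == table.labels[test_mask]).sum())
            total += int(test_mask.sum())
        acc = correct / total
        if acc > best_acc:
            best_params, best_acc = params, acc
    return best_params


@dataclass
class CVResult:
    """Pooled out-of-fold predictions of a grouped cross-validation."""

    classes: tuple[str, ...]
    predictions: np.ndarray
    scores: np.ndarray
    true_labels: np.ndarray
    accuracy: float
    auc_weighted: float
    auc_macro: float
    per_fold_accuracy: tuple[float, ...]
    fold_assignment: FoldAssignment
    params_per_fold: tuple[HyperParams, ...]

    @property
    def confusion(self) -> ConfusionMatrix:
        return confusion(self.true_labels, self.predictions, self.classes)


def cross_validate(
    table: FeatureTable,
    k: int = 10,
    grid=None,
    seed: int = 0,
    uniform_prior: bool = True,
    inner_k: int = 5,
    tuning: str = "nested",
) -> CVResult:
    """Participant-grouped k-fold cross-validation with grid-search tuning.

    For each fold, hyperparameters are tuned by an inner grouped
    cross-validation restricted to the fold's training participants
    (``tuning="nested"``), or once on the full table (``tuning="global"``,
    mimicking a single global grid search); a single-point grid skips tuning.
    The leakage invariant — no participant on both sides of any fold — is
    asserted for every fold.
    """
    if tuning not in {"nested", "global"}:
        raise ValueError(f"unknown tuning mode {tuning!r}")
    grid = list(grid) if grid is not None else [DEFAULT_PARAMS]
    folds = grouped_folds(table.groups, k=k, seed=seed)

    global_params = None
    if tuning == "global" or len(grid) == 1:
        global_params = tune_hyperparams(
            table, grid, k=inner_k, seed=seed, uniform_prior=uniform_prior
        )

    n = table.n_rows
    predictions = np.empty(n, dtype=object)
    scores = np.full((n, len(table.classes)), np.nan)
    per_fold_acc, params_used = [], []
    seen = np.zeros(n, dtype=bool)
    for fold in range(k):
        test_mask = folds.test_mask(table.groups, fold)
        train_table = _subset_table(table, ~test_mask)
        # grouped-CV validity: participants never straddle the fold boundary
        leaked = set(train_table.groups) & set(table.groups[test_mask])
        assert not leaked, f"participant leakage across fold {fold}: {leaked}"
        params = global_params or tune_hyperparams(
            train_table, grid, k=inner_k, seed=seed + fold + 1,
            uniform_prior=uniform_prior,
        )
        model = train(train_table, params, uniform_prior)
        pred, fold_scores = predict(model, table.X[test_mask])
        predictions[test_mask] = pred
        scores[test_mask] = _expand_scores(fold_scores, model.classes, table.classes)
        per_fold_acc.append(float((pred == table.labels[test_mask]).mean()))
        params_used.append(params)
        seen |= test_mask
    assert seen.all(), "every row must receive exactly one out-of-fold prediction"

    acc = float((predictions == table.labels).mean())
    auc_w = multiclass_auc(scores, table.labels, table.classes, "weighted")
    auc_m = multiclass_auc(scores, table.labels, table.classes, "macro")
    return CVResult(
        classes=tuple(table.classes),
        predictions=predictions,
        scores=scores,
        true_labels=np.asarray(table.labels, dtype=object),
        accuracy=acc,
        auc_weighted=auc_w,
        auc_macro=auc_m,
        per_fold_accuracy=tuple(per_fold_acc),
        fold_assignment=folds,
        params_per_fold=tuple(params_used),
    )


def apply_model(model: DecoderModel, table: FeatureTable):
    """Evaluate a trained decoder on an independent sample (no refitting).

    Returns (accuracy, weighted AUC, confusion matrix) over the new table.
    """
    if table.n_rows == 0:
        raise ValueError("empty test table")
    unseen = set(table.labels) - set(model.classes)
    if unseen:
        raise ValueError(f"test labels unseen in training: {sorted(unseen)}")
    pred, scores = predict(model, table.X)
    cm = confusion(table.labels, pred, model.classes)
    auc = multiclass_auc(scores, table.labels, model.classes, "weighted")
    return cm_accuracy(cm), auc, cm
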