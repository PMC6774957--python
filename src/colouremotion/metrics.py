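"""Classification metrics: confusion matrices, accuracy, chance level,
multiclass ROC-AUC and the permutation-null significance procedure.

The AUC is the rank-based (Mann-Whitney) one-vs-rest statistic with midrank
tie handling, averaged over classes either with class-prevalence weights
("weighted", matching the convention of reporting a weighted average AUC) or
with equal weights ("macro"). Significance of an observed decoding
performance is assessed against a null distribution obtained by re-running
the identical cross-validation on label-permuted copies of the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "PermutationResult",
    "confusion",
    "accuracy",
    "chance_level",
    "multiclass_auc",
    "permutation_test",
    "permute_labels",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts ``N[i, j]`` of true class i predicted as j, plus row-normalised
    proportions. Rows with zero total are flagged rather than divided."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if counts.shape[0] != len(self.classes):
            raise ValueError("class list does not match matrix size")
        if (counts < 0).any():
            raise ValueError("negative counts")
        object.__setattr__(self, "counts", counts)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def empty_rows(self) -> list[str]:
        return [c for c, t in zip(self.classes, self.row_totals) if t == 0]

    @property
    def proportions(self) -> np.ndarray:
        totals = self.row_totals.astype(float)
        safe = np.where(totals > 0, totals, 1.0)
        return self.counts / safe[:, None]

    def recall(self, cls: str) -> float:
        i = self.classes.index(cls)
        if self.row_totals[i] == 0:
            return float("nan")
        return self.counts[i, i] / self.row_totals[i]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion(true_labels, predicted_labels, classes) -> ConfusionMatrix:
    """Count-based confusion matrix in the given class order."""
    true_labels = np.asarray(true_labels, dtype=object)
    predicted_labels = np.asarray(predicted_labels, dtype=object)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    n = len(classes)
    counts = np.zeros((n, n), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes=classes, counts=counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Proportion of correctly classified instances: trace / total."""
    total = cm.counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / total)


def chance_level(n_classes: int) -> float:
    """Guessing rate for balanced n-class classification: 1 / n."""
    if n_classes < 2:
        raise ValueError("need at least two classes")
    return 1.0 / n_classes


def multiclass_auc(
    score_matrix: np.ndarray,
    true_labels,
    classes,
    weighting: str = "weighted",
) -> float:
    """One-vs-rest ROC-AUC averaged across classes.

    Per class, the AUC is the Mann-Whitney statistic computed from midranks of
    the class score column (ties contribute 1/2). ``weighting`` is
    "weighted" (class prevalence) or "macro" (equal). Classes without both a
    positive and a negative example are skipped with a warning.
    """
    score_matrix = np.asarray(score_matrix, dtype=float)
    true_labels = np.asarray(true_labels, dtype=object)
    classes = tuple(classes)
    if score_matrix.shape != (len(true_labels), len(classes)):
        raise ValueError("score matrix shape does not match labels/classes")
    if not np.isfinite(score_matrix).all():
        raise ValueError("scores must be finite")
    if weighting not in {"weighted", "macro"}:
        raise ValueError(f"unknown weighting {weighting!r}")

    aucs, weights = [], []
    n = len(true_labels)
    for j, cls in enumerate(classes):
        pos = true_labels == cls
        n_pos = int(pos.sum())
        n_neg = n - n_pos
        if n_pos == 0 or n_neg == 0:
            warnings.warn(
                f"class {cls!r} lacks positives or negatives; skipped in AUC",
                stacklevel=2,
            )
            continue
        ranks = stats.rankdata(score_matrix[:, j])  # midranks
        auc_j = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        aucs.append(auc_j)
        weights.append(n_pos if weighting == "weighted" else 1.0)
    if not aucs:
        raise ValueError("no class had both positives and negatives")
    return float(np.average(aucs, weights=weights))


# ---------------------------------------------------------------------------
# permutation-null significance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermutationResult:
    """Observed decoding performance against a label-permutation null.

    ``p_value_*`` use the add-one permutation estimator
    ``(1 + #{null >= observed}) / (1 + n_perm)``; with the conventional 10
    permutations the smallest attainable p is 1/11. ``p_value_auc_ttest`` is a
    secondary two-sided one-sample comparison of the observed AUC against the
    null AUC values (reported because coarse permutation counts bound the
    primary p away from small values).
    """

    observed_auc: float
    observed_accuracy: float
    null_auc: tuple[float, ...]
    null_accuracy: tuple[float, ...]
    n_perm: int
    seed: int
    p_value_auc: float = field(init=False)
    p_value_accuracy: float = field(init=False)
    p_value_auc_ttest: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.null_auc) != self.n_perm or len(self.null_accuracy) != self.n_perm:
            raise ValueError("null list length must equal n_perm")
        null_auc = np.asarray(self.null_auc)
        null_acc = np.asarray(self.null_accuracy)
        p_auc = (1 + int((null_auc >= self.observed_auc).sum())) / (1 + self.n_perm)
        p_acc = (1 + int((null_acc >= self.observed_accuracy).sum())) / (1 + self.n_perm)
        if self.n_perm >= 2 and np.std(null_auc) > 0:
            p_t = float(stats.ttest_1samp(null_auc, self.observed_auc).pvalue)
        else:
            p_t = float("nan")
        object.__setattr__(self, "p_value_auc", float(p_auc))
        object.__setattr__(self, "p_value_accuracy", float(p_acc))
        object.__setattr__(self, "p_value_auc_ttest", p_t)


def permute_labels(table, rng: np.random.Generator):
    """Return a copy of a feature table with class labels permuted.

    The permutation respects the repeated-measures structure the
    cross-validation respects: colour-task labels are shuffled within each
    participant's own rows (every participant still rates each colour term
    exactly once, so the permuted data remain a draw from the null design
    and the permutation p-value is exact), while country-task labels are
    shuffled at the participant level (all rows of a participant keep a
    common, permuted country).
    """
    from .data import FeatureTable

    if table.task == "country":
        # one label per participant; permute participants' labels
        pids, first_idx = np.unique(table.groups, return_index=True)
        pid_labels = table.labels[first_idx]
        permuted = pid_labels[rng.permutation(len(pid_labels))]
        mapping = dict(zip(pids, permuted))
        new_labels = np.array([mapping[g] for g in table.groups], dtype=object)
    else:
        new_labels = table.labels.copy()
        for pid in np.unique(table.groups):
            idx = np.flatnonzero(table.groups == pid)
            new_labels[idx] = new_labels[idx[rng.permutation(len(idx))]]
    return FeatureTable(
        X=table.X,
        labels=new_labels,
        groups=table.groups,
        feature_names=table.feature_names,
        classes=table.classes,
        task=table.task,
    )


def permutation_test(
    table,
    k: int = 10,
    grid=None,
    n_perm: int = 10,
    seed: int = 0,
    uniform_prior: bool = True,
    observed=None,
) -> PermutationResult:
    """Compare observed cross-validated decoding with a permutation null.

    Runs the full grouped cross-validation once on the intact table (unless a
    precomputed ``CVResult`` is passed as ``observed``) and once per permuted
    copy, recording AUC (weighted) and accuracy each time.
    """
    from .decoder import cross_validate

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if observed is None:
        observed = cross_validate(
            table, k=k, grid=grid, seed=seed, uniform_prior=uniform_prior
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
    null_auc, null_acc = [], []
    for _ in range(n_perm):
        permuted = permute_labels(table, rng)
        res = cross_validate(
            permuted, k=k, grid=grid, seed=seed, uniform_prior=uniform_prior
        )
        null_auc.append(res.auc_weighted)
        null_acc.append(res.accuracy)
    return PermutationResult(
        observed_auc=observed.auc_weighted,
        observed_accuracy=observed.accuracy,
        null_auc=tuple(null_auc),
        null_accuracy=tuple(null_acc),
        n_perm=n_perm,
        seed=seed,
    )
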