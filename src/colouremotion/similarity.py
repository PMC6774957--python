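"""Inter-class similarity from decoding confusions (Luce biased-choice model).

Under the biased-choice model, the probability of responding j to a stimulus
of class i is proportional to a response bias b_j times a symmetric
similarity eta_ij with eta_ii = 1. Classes whose emotion-association
patterns are similar get confused more often by the decoder, and the model
lets the confusion matrix be inverted into pairwise similarities via the
closed-form moment estimator

    eta_ij = sqrt( (p_ij * p_ji) / (p_ii * p_jj) ),

where p is the row-normalised confusion proportion matrix. The estimator is
invariant to the response biases (they cancel in the products), symmetric by
construction, and equals 1 on the diagonal by definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import ConfusionMatrix

__all__ = ["SimilarityMatrix", "estimate_similarity", "similarity_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric biased-choice similarities with unit diagonal.

    ``bias`` is the estimated response-bias vector (normalised to sum 1);
    it is reported for transparency but not used downstream. ``n_clipped``
    counts estimates above 1 that were clipped (a sign of model misfit).
    """

    classes: tuple[str, ...]
    eta: np.ndarray
    bias: np.ndarray
    n_clipped: int = 0

    def __post_init__(self) -> None:
        eta = np.asarray(self.eta, dtype=float)
        if eta.shape != (len(self.classes),) * 2:
            raise ValueError("similarity matrix shape does not match classes")
        if not np.allclose(eta, eta.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(eta), 1.0):
            raise ValueError("diagonal must be exactly 1")
        if ((eta < 0) | (eta > 1)).any():
            raise ValueError("similarities must lie in [0, 1]")
        object.__setattr__(self, "eta", eta)

    def value(self, a: str, b: str) -> float:
        i, j = self.classes.index(a), self.classes.index(b)
        return float(self.eta[i, j])

    def to_frame(self, upper_only: bool = False) -> pd.DataFrame:
        eta = self.eta.copy()
        if upper_only:
            eta[np.tril_indices_from(eta, k=-1)] = np.nan
        return pd.DataFrame(eta, index=list(self.classes), columns=list(self.classes))


def estimate_similarity(
    cm: ConfusionMatrix, smoothing: float = 0.5
) -> SimilarityMatrix:
    """Estimate pairwise similarities from a confusion matrix.

    ``smoothing`` counts are added to every cell before row normalisation
    (sparse confusion matrices contain zero cells and the estimator divides
    by the diagonal). Estimates above 1 are clipped to 1 and logged.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    counts = cm.counts.astype(float) + smoothing
    row_sums = counts.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("zero row total after smoothing")
    p = counts / row_sums[:, None]
    d = np.diag(p)
    if (d == 0).any():
        bad = [c for c, v in zip(cm.classes, d) if v == 0]
        raise ValueError(f"zero diagonal proportion after smoothing for {bad}")

    eta = np.sqrt((p * p.T) / np.outer(d, d))
    np.fill_diagonal(eta, 1.0)
    n_clipped = int((eta > 1.0).sum() // 2)
    if n_clipped:
        logger.warning(
            "clipped %d similarity estimates above 1 (biased-choice misfit)",
            n_clipped,
        )
    eta = np.minimum(eta, 1.0)

    # bias: geometric mean over rows i of p[i, j] / eta[i, j], normalised
    with np.errstate(divide="ignore"):
        ratio = np.log(np.where(eta > 0, p / np.where(eta > 0, eta, 1.0), np.nan))
    bias = np.exp(np.nanmean(ratio, axis=0))
    bias = bias / bias.sum()

    return SimilarityMatrix(
        classes=cm.classes, eta=eta, bias=bias, n_clipped=n_clipped
    )


def similarity_report(sm: SimilarityMatrix, top_n: int | None = None):
    """Off-diagonal pairs ranked by similarity, highest first.

    Each symmetric pair appears once (upper triangle); ties break towards the
    pair earliest in vocabulary order. ``top_n`` truncates the list.
    """
    K = len(sm.classes)
    pairs = [
        (sm.classes[i], sm.classes[j], float(sm.eta[i, j]))
        for i in range(K)
        for j in range(i + 1, K)
    ]
    pairs.sort(key=lambda t: (-t[2], sm.classes.index(t[0]), sm.classes.index(t[1])))
    if top_n is not None:
        pairs = pairs[: max(0, top_n)]
    return pairs
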