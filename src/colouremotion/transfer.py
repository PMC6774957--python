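"""Cross-country generalisation of the colour decoder.

For K countries the transfer matrix A holds colour-decoding accuracies:
A[i, i] is the participant-grouped 10-fold cross-validated accuracy within
country i, and A[i, j] (i != j) the accuracy of a decoder trained on all of
country i's data and tested on all of country j's data. The in-group
advantage D[i, j] = A[j, j] - A[i, j] measures how much better a country's
own decoder does on its data than a foreign-trained one; its mean over the
K(K-1) ordered country pairs summarises the cultural specificity of the
colour-emotion associations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import RatingDataset, colour_feature_table
from .decoder import cross_validate, train, apply_model, tune_hyperparams, DEFAULT_PARAMS

__all__ = [
    "TransferMatrix",
    "AdvantageSummary",
    "transfer_matrix",
    "advantage_matrix",
    "summarize_advantage",
]


@dataclass(frozen=True)
class TransferMatrix:
    """K x K colour-decoding accuracies across training/test countries.

    Rows index the training country, columns the test country; diagonal
    entries come from within-country grouped cross-validation (never
    train=test resubstitution).
    """

    countries: tuple[str, ...]
    accuracies: np.ndarray  # (K, K)
    k: int
    seed: int

    def __post_init__(self) -> None:
        A = np.asarray(self.accuracies, dtype=float)
        if A.shape != (len(self.countries),) * 2:
            raise ValueError("accuracy matrix shape does not match countries")
        if np.isfinite(A).all() and ((A < 0) | (A > 1)).any():
            raise ValueError("accuracies must lie in [0, 1]")
        object.__setattr__(self, "accuracies", A)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.accuracies, index=list(self.countries), columns=list(self.countries)
        )


@dataclass(frozen=True)
class AdvantageSummary:
    """In-group advantage matrix and its off-diagonal summary statistics."""

    countries: tuple[str, ...]
    advantage: np.ndarray  # (K, K), nan on the diagonal
    mean: float
    sd: float
    min: float
    max: float

    def off_diagonal(self) -> np.ndarray:
        K = len(self.countries)
        mask = ~np.eye(K, dtype=bool)
        return self.advantage[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.advantage, index=list(self.countries), columns=list(self.countries)
        )


def transfer_matrix(
    dataset: RatingDataset,
    k: int = 10,
    grid=None,
    seed: int = 0,
    uniform_prior: bool = True,
    inner_k: int = 5,
) -> TransferMatrix:
    """Compute the K x K within/between-country colour-decoding accuracies.

    Hyperparameters are tuned per training country by inner grouped
    cross-validation (mirroring the within-country procedure), so the
    advantage is not confounded by tuning protocol. Requires every country to
    have at least k participants.
    """
    countries = dataset.countries_present()
    if len(countries) < 2:
        raise ValueError("need at least two countries")
    by_country = {c: dataset.restrict_to_country(c) for c in countries}
    for c, sub in by_country.items():
        if sub.n_participants < k:
            raise ValueError(
                f"country {c} has {sub.n_participants} participants < k={k}"
            )
    tables = {c: colour_feature_table(sub) for c, sub in by_country.items()}

    K = len(countries)
    A = np.zeros((K, K))
    grid_list = list(grid) if grid is not None else [DEFAULT_PARAMS]
    for i, ci in enumerate(countries):
        res = cross_validate(
            tables[ci], k=k, grid=grid_list, seed=seed, uniform_prior=uniform_prior,
            inner_k=inner_k,
        )
        A[i, i] = res.accuracy
        params = tune_hyperparams(
            tables[ci], grid_list, k=inner_k, seed=seed, uniform_prior=uniform_prior
        )
        model = train(tables[ci], params, uniform_prior)
        for j, cj in enumerate(countries):
            if i == j:
                continue
            acc, _, _ = apply_model(model, tables[cj])
            A[i, j] = acc
    return TransferMatrix(countries=tuple(countries), accuracies=A, k=k, seed=seed)


def advantage_matrix(tm: TransferMatrix) -> AdvantageSummary:
    """In-group advantage D[i, j] = A[j, j] - A[i, j] for i != j.

    Positive entries mean the test country's own decoder beats the
    foreign-trained one on that country's data.
    """
    A = tm.accuracies
    K = len(tm.countries)
    D = A.diagonal()[None, :] - A
    D = D.astype(float)
    np.fill_diagonal(D, np.nan)
    off = D[~np.eye(K, dtype=bool)]
    return AdvantageSummary(
        countries=tm.countries,
        advantage=D,
        mean=float(off.mean()),
        sd=float(off.std(ddof=1)) if off.size > 1 else 0.0,
        min=float(off.min()),
        max=float(off.max()),
    )


def summarize_advantage(summary: AdvantageSummary) -> tuple[float, float, float, float]:
    """(mean, sample sd, min, max) over the K(K-1) off-diagonal entries."""
    return summary.mean, summary.sd, summary.min, summary.max
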