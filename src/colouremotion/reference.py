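"""Published reference values for the four-country colour-decoding analysis.

``PUBLISHED_TRANSFER_ACCURACY`` holds the colour-decoding accuracy matrix
reported for the China/Germany/Greece/UK survey cohorts: rows are the
training country, columns the test country; diagonal entries are
within-country 10-fold cross-validated accuracies and off-diagonal entries
train-on-row / test-on-column accuracies. ``PUBLISHED_ADVANTAGE`` holds the
correspondingly reported in-group-advantage entries (within-country accuracy
minus transfer accuracy, rounded to three decimals as printed).

These numbers are inputs for arithmetic reconstruction and sanity checks;
they are not recomputed from raw survey data by this package.
"""

from __future__ import annotations

import numpy as np

from .transfer import TransferMatrix

__all__ = [
    "PUBLISHED_COUNTRIES",
    "PUBLISHED_TRANSFER_ACCURACY",
    "PUBLISHED_ADVANTAGE",
    "published_transfer_matrix",
]

PUBLISHED_COUNTRIES = ("CN", "DE", "GR", "GB")

#: rows: training country; columns: test country (order as PUBLISHED_COUNTRIES)
PUBLISHED_TRANSFER_ACCURACY = np.array([
    [0.337, 0.334, 0.270, 0.321],
    [0.290, 0.421, 0.311, 0.350],
    [0.274, 0.362, 0.371, 0.309],
    [0.279, 0.384, 0.289, 0.372],
])

#: reported in-group advantage A[j, j] - A[i, j]; nan on the diagonal
PUBLISHED_ADVANTAGE = np.array([
    [np.nan, 0.087, 0.101, 0.051],
    [0.047, np.nan, 0.061, 0.022],
    [0.063, 0.059, np.nan, 0.063],
    [0.058, 0.037, 0.082, np.nan],
])


def published_transfer_matrix() -> TransferMatrix:
    """The published accuracy panel wrapped as a :class:`TransferMatrix`."""
    return TransferMatrix(
        countries=PUBLISHED_COUNTRIES,
        accuracies=PUBLISHED_TRANSFER_ACCURACY.copy(),
        k=10,
        seed=0,
    )
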