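"""Rating data model, validation, I/O and descriptive proportion summaries.

A rating dataset holds, for every participant, the full 12 x 20 grid of
colour-emotion association intensities on the 0-5 scale of the Geneva Emotion
Wheel (0 = no association, 1 = weak ... 5 = strong), plus the participant's
country and optional demographics. The two downstream decoding tasks consume
it through two flattened views:

* the *colour task*: one row per (participant, colour term), 20 features
  (the emotion ratings for that colour), label = colour term;
* the *country task*: one row per participant, 240 features (the full grid,
  colour-major), label = country.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .vocab import Vocabulary, DEFAULT_VOCABULARY

__all__ = [
    "RatingDataset",
    "FeatureTable",
    "ProportionSummary",
    "ValidationError",
    "load_dataset",
    "write_dataset",
    "colour_feature_table",
    "country_feature_table",
    "rating_proportions",
]

MIN_INTENSITY, MAX_INTENSITY = 0, 5
N_CATEGORIES = MAX_INTENSITY - MIN_INTENSITY + 1

LONG_COLUMNS = [
    "participant_id", "country", "age", "gender", "colour", "emotion", "intensity",
]


class ValidationError(ValueError):
    """A dataset violated the rating-grid contract."""


@dataclass(frozen=True)
class FeatureTable:
    """Flat numeric matrix consumed by the decoder.

    ``groups`` carries the participant id of every row so cross-validation can
    split at the participant level and never leak a participant across the
    train/test boundary of a fold.
    """

    X: np.ndarray
    labels: np.ndarray
    groups: np.ndarray
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    task: str  # "colour" or "country"

    def __post_init__(self) -> None:
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        n = self.X.shape[0]
        if not (len(self.labels) == len(self.groups) == n):
            raise ValueError("labels/groups length must match number of rows")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match number of columns")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class ProportionSummary:
    """Per-country and pooled rating-category proportions.

    ``per_country[c, k, e, r]`` is the proportion of participants from country
    ``c`` who gave rating category ``r`` (0-5) to (colour ``k``, emotion ``e``).
    ``pooled`` is the unweighted arithmetic mean over countries, so countries
    with very different sample sizes contribute equally.
    """

    vocabulary: Vocabulary
    countries: tuple[str, ...]
    per_country: np.ndarray  # (n_countries, 12, 20, 6)
    pooled: np.ndarray       # (12, 20, 6)

    def pooled_frame(self) -> pd.DataFrame:
        """Pooled proportions as a long DataFrame (colour, emotion, p0..p5)."""
        v = self.vocabulary
        rows = []
        for k, colour in enumerate(v.colour_terms):
            for e, emotion in enumerate(v.emotion_terms):
                rows.append(
                    {"colour": colour, "emotion": emotion}
                    | {f"p{r}": self.pooled[k, e, r] for r in range(N_CATEGORIES)}
                )
        return pd.DataFrame(rows)


@dataclass
class RatingDataset:
    """Validated set of complete 12 x 20 rating grids.

    Internal layout: ``participants`` (one row each: participant_id, country,
    age, gender, in a fixed deterministic order) and ``intensities`` of shape
    (n_participants, 12, 20) aligned with the vocabulary orderings.
    """

    vocabulary: Vocabulary
    participants: pd.DataFrame
    intensities: np.ndarray
    _pid_index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.participants)
        expected = (n, len(self.vocabulary.colour_terms), len(self.vocabulary.emotion_terms))
        if self.intensities.shape != expected:
            raise ValidationError(
                f"intensity grid shape {self.intensities.shape} != {expected}"
            )
        if n and (self.intensities.min() < MIN_INTENSITY or self.intensities.max() > MAX_INTENSITY):
            raise ValidationError("intensities outside the 0-5 scale")
        pids = self.participants["participant_id"]
        if pids.duplicated().any():
            dup = pids[pids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate participant id {dup!r}")
        unknown = set(self.participants["country"]) - set(self.vocabulary.countries)
        if unknown:
            raise ValidationError(f"unknown countries: {sorted(unknown)}")
        self._pid_index = {pid: i for i, pid in enumerate(pids)}

    # -- basic introspection ----------------------------------------------
    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def participant_ids(self) -> np.ndarray:
        return self.participants["participant_id"].to_numpy()

    @property
    def country_of(self) -> pd.Series:
        return self.participants.set_index("participant_id")["country"]

    def countries_present(self) -> list[str]:
        present = set(self.participants["country"])
        return [c for c in self.vocabulary.countries if c in present]

    def subset(self, participant_ids) -> "RatingDataset":
        idx = [self._pid_index[p] for p in participant_ids]
        return RatingDataset(
            vocabulary=self.vocabulary,
            participants=self.participants.iloc[idx].reset_index(drop=True),
            intensities=self.intensities[idx],
        )

    def restrict_to_country(self, country: str) -> "RatingDataset":
        mask = self.participants["country"] == country
        return RatingDataset(
            vocabulary=self.vocabulary,
            participants=self.participants[mask].reset_index(drop=True),
            intensities=self.intensities[mask.to_numpy()],
        )

    # -- conversions -------------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        """Long format: one row per rating, deterministic order
        (participant, colour in vocabulary order, emotion in vocabulary order)."""
        v = self.vocabulary
        n, nk, ne = self.intensities.shape
        part = self.participants
        frame = pd.DataFrame(
            {
                "participant_id": np.repeat(part["participant_id"].to_numpy(), nk * ne),
                "country": np.repeat(part["country"].to_numpy(), nk * ne),
                "age": np.repeat(part["age"].to_numpy(), nk * ne),
                "gender": np.repeat(part["gender"].to_numpy(), nk * ne),
                "colour": np.tile(np.repeat(np.array(v.colour_terms), ne), n),
                "emotion": np.tile(np.array(v.emotion_terms), n * nk),
                "intensity": self.intensities.reshape(-1),
            }
        )
        return frame

    def to_wide(self) -> pd.DataFrame:
        """Wide format: one row per participant, 240 colour_emotion columns."""
        v = self.vocabulary
        wide = pd.DataFrame(
            self.intensities.reshape(self.n_participants, -1),
            columns=v.feature_names(),
        )
        return pd.concat([self.participants.reset_index(drop=True), wide], axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RatingDataset):
            return NotImplemented
        return (
            self.vocabulary == other.vocabulary
            and np.array_equal(self.intensities, other.intensities)
            and self.participants["participant_id"].tolist()
            == other.participants["participant_id"].tolist()
            and self.participants["country"].tolist()
            == other.participants["country"].tolist()
        )


# ---------------------------------------------------------------------------
# construction and I/O
# ---------------------------------------------------------------------------

def dataset_from_long(
    frame: pd.DataFrame, vocabulary: Vocabulary = DEFAULT_VOCABULARY
) -> RatingDataset:
    """Validate a long-format frame and assemble a :class:`RatingDataset`.

    Every participant must contribute exactly one rating for each of the
    12 x 20 = 240 (colour, emotion) cells; colour/emotion/country tokens are
    matched case-insensitively against the vocabulary. Rows whose ``emotion``
    is not in the vocabulary but equals ``different_emotion`` are dropped
    (free-text responses are not analysed).
    """
    required = {"participant_id", "country", "colour", "emotion", "intensity"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")

    frame = frame.copy()
    frame = frame[frame["emotion"].astype(str).str.strip().str.lower() != "different_emotion"]

    try:
        frame["colour"] = [vocabulary.canonical_colour(t) for t in frame["colour"].astype(str)]
        frame["emotion"] = [vocabulary.canonical_emotion(t) for t in frame["emotion"].astype(str)]
        frame["country"] = [vocabulary.canonical_country(t) for t in frame["country"].astype(str)]
    except KeyError as exc:
        raise ValidationError(str(exc)) from None

    intens = pd.to_numeric(frame["intensity"], errors="raise")
    if (intens != intens.round()).any():
        raise ValidationError("non-integer intensity value")
    intens = intens.astype(int)
    bad = (intens < MIN_INTENSITY) | (intens > MAX_INTENSITY)
    if bad.any():
        row = frame[bad].iloc[0]
        raise ValidationError(
            f"intensity {row['intensity']!r} out of range 0-5 for participant "
            f"{row['participant_id']!r}, cell ({row['colour']}, {row['emotion']})"
        )
    frame["intensity"] = intens

    nk = len(vocabulary.colour_terms)
    ne = len(vocabulary.emotion_terms)

    if frame.duplicated(["participant_id", "colour", "emotion"]).any():
        row = frame[frame.duplicated(["participant_id", "colour", "emotion"])].iloc[0]
        raise ValidationError(
            f"duplicate cell ({row['colour']}, {row['emotion']}) for participant "
            f"{row['participant_id']!r}"
        )

    counts = frame.groupby("participant_id", sort=False).size()
    incomplete = counts[counts != nk * ne]
    if len(incomplete):
        pid = incomplete.index[0]
        raise ValidationError(
            f"participant {pid!r} has {incomplete.iloc[0]} ratings, expected {nk * ne}"
        )
    ncountry = frame.groupby("participant_id", sort=False)["country"].nunique()
    if (ncountry > 1).any():
        pid = ncountry[ncountry > 1].index[0]
        raise ValidationError(f"participant {pid!r} assigned to multiple countries")

    # deterministic participant order: sorted by id (as string)
    pid_order = sorted(counts.index, key=str)
    ci = frame["colour"].map(vocabulary.colour_index).to_numpy()
    ei = frame["emotion"].map(vocabulary.emotion_index).to_numpy()
    pi = frame["participant_id"].map({p: i for i, p in enumerate(pid_order)}).to_numpy()
    grid = np.zeros((len(pid_order), nk, ne), dtype=np.int64)
    grid[pi, ci, ei] = frame["intensity"].to_numpy()

    meta = frame.groupby("participant_id", sort=False).first()
    parts = pd.DataFrame(
        {
            "participant_id": pid_order,
            "country": [meta.loc[p, "country"] for p in pid_order],
            "age": [meta.loc[p, "age"] if "age" in meta.columns else np.nan for p in pid_order],
            "gender": [
                meta.loc[p, "gender"] if "gender" in meta.columns else "" for p in pid_order
            ],
        }
    )
    return RatingDataset(vocabulary=vocabulary, participants=parts, intensities=grid)


def load_dataset(
    path: str | Path, vocabulary: Vocabulary = DEFAULT_VOCABULARY
) -> RatingDataset:
    """Read a long-format CSV (UTF-8) and return a validated dataset."""
    try:
        frame = pd.read_csv(path, dtype={"participant_id": str, "gender": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    return dataset_from_long(frame, vocabulary)


def write_dataset(dataset: RatingDataset, path: str | Path) -> None:
    """Write the long-format CSV; repeated writes are byte-identical."""
    frame = dataset.to_long()[LONG_COLUMNS]
    frame.to_csv(path, index=False, lineterminator="\n")


def write_wide(dataset: RatingDataset, path: str | Path) -> None:
    dataset.to_wide().to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def colour_feature_table(dataset: RatingDataset) -> FeatureTable:
    """One row per (participant, colour): the 20 emotion ratings, labelled
    with the colour term rated. 12 rows per participant."""
    v = dataset.vocabulary
    n, nk, ne = dataset.intensities.shape
    X = dataset.intensities.reshape(n * nk, ne).astype(float)
    labels = np.tile(np.array(v.colour_terms, dtype=object), n)
    groups = np.repeat(dataset.participant_ids, nk)
    return FeatureTable(
        X=X,
        labels=labels,
        groups=groups,
        feature_names=tuple(v.emotion_terms),
        classes=tuple(v.colour_terms),
        task="colour",
    )


def country_feature_table(dataset: RatingDataset) -> FeatureTable:
    """One row per participant: all 240 ratings (colour-major, emotion-minor),
    labelled with the participant's country of origin."""
    v = dataset.vocabulary
    n = dataset.n_participants
    X = dataset.intensities.reshape(n, -1).astype(float)
    labels = dataset.participants["country"].to_numpy(dtype=object)
    groups = dataset.participant_ids
    return FeatureTable(
        X=X,
        labels=labels,
        groups=groups,
        feature_names=tuple(v.feature_names()),
        classes=tuple(c for c in v.countries),
        task="country",
    )


# ---------------------------------------------------------------------------
# descriptive proportions
# ---------------------------------------------------------------------------

def rating_proportions(dataset: RatingDataset) -> ProportionSummary:
    """Rating-category proportions per country, pooled by unweighted means.

    The proportions of each of the six rating categories are computed within
    each country first and then averaged across countries with equal weights,
    so unequal country sample sizes do not bias the pooled summary.
    """
    if dataset.n_participants == 0:
        raise ValidationError("empty dataset")
    v = dataset.vocabulary
    countries = dataset.countries_present()
    nk, ne = len(v.colour_terms), len(v.emotion_terms)
    per = np.zeros((len(countries), nk, ne, N_CATEGORIES))
    for ci, country in enumerate(countries):
        mask = (dataset.participants["country"] == country).to_numpy()
        grid = dataset.intensities[mask]  # (n_c, 12, 20)
        for r in range(N_CATEGORIES):
            per[ci, :, :, r] = (grid == r).mean(axis=0)
    pooled = per.mean(axis=0)
    return ProportionSummary(
        vocabulary=v, countries=tuple(countries), per_country=per, pooled=pooled
    )
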