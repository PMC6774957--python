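"""Vocabularies of colour terms, emotion terms and country codes.

The ordering of the terms is part of the contract: it fixes the feature-column
order of every feature table and the row/column order of every confusion,
transfer and similarity matrix produced downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["Vocabulary", "DEFAULT_VOCABULARY"]

N_COLOURS = 12
N_EMOTIONS = 20

#: The 11 basic English colour terms plus turquoise, in canonical order.
DEFAULT_COLOUR_TERMS = (
    "white", "black", "grey", "red", "yellow", "green",
    "blue", "orange", "purple", "pink", "brown", "turquoise",
)

#: The 20 discrete emotion terms of the Geneva Emotion Wheel (GEW v3.0).
DEFAULT_EMOTION_TERMS = (
    "admiration", "amusement", "anger", "compassion", "contempt",
    "contentment", "disappointment", "disgust", "fear", "guilt",
    "hate", "interest", "joy", "love", "pleasure",
    "pride", "regret", "relief", "sadness", "shame",
)

#: Two-letter codes of the four surveyed countries (China, Germany, UK, Greece).
DEFAULT_COUNTRIES = ("CN", "DE", "GB", "GR")


@dataclass(frozen=True)
class Vocabulary:
    """Ordered colour, emotion and country identifiers.

    Exactly 12 colour terms and 20 emotion terms are required (the rating
    instrument is a fixed 12 x 20 grid); at least two countries. Identifiers
    are matched case-insensitively against incoming data but stored and
    reported in their canonical (lower/upper) form.
    """

    colour_terms: tuple[str, ...] = DEFAULT_COLOUR_TERMS
    emotion_terms: tuple[str, ...] = DEFAULT_EMOTION_TERMS
    countries: tuple[str, ...] = DEFAULT_COUNTRIES
    _colour_index: dict[str, int] = field(init=False, repr=False, compare=False)
    _emotion_index: dict[str, int] = field(init=False, repr=False, compare=False)
    _country_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "colour_terms", tuple(self.colour_terms))
        object.__setattr__(self, "emotion_terms", tuple(self.emotion_terms))
        object.__setattr__(self, "countries", tuple(self.countries))
        if len(self.colour_terms) != N_COLOURS:
            raise ValueError(
                f"expected {N_COLOURS} colour terms, got {len(self.colour_terms)}"
            )
        if len(self.emotion_terms) != N_EMOTIONS:
            raise ValueError(
                f"expected {N_EMOTIONS} emotion terms, got {len(self.emotion_terms)}"
            )
        if len(self.countries) < 2:
            raise ValueError("need at least two countries")
        for name, terms in (
            ("colour", self.colour_terms),
            ("emotion", self.emotion_terms),
            ("country", self.countries),
        ):
            lowered = [t.lower() for t in terms]
            if len(set(lowered)) != len(terms):
                raise ValueError(f"duplicate {name} identifiers: {terms}")
        object.__setattr__(
            self, "_colour_index",
            {t.lower(): i for i, t in enumerate(self.colour_terms)},
        )
        object.__setattr__(
            self, "_emotion_index",
            {t.lower(): i for i, t in enumerate(self.emotion_terms)},
        )
        object.__setattr__(
            self, "_country_index",
            {t.lower(): i for i, t in enumerate(self.countries)},
        )

    # -- canonicalisation -------------------------------------------------
    def canonical_colour(self, token: str) -> str:
        try:
            return self.colour_terms[self._colour_index[token.strip().lower()]]
        except KeyError:
            raise KeyError(f"unknown colour term: {token!r}") from None

    def canonical_emotion(self, token: str) -> str:
        try:
            return self.emotion_terms[self._emotion_index[token.strip().lower()]]
        except KeyError:
            raise KeyError(f"unknown emotion term: {token!r}") from None

    def canonical_country(self, token: str) -> str:
        try:
            return self.countries[self._country_index[token.strip().lower()]]
        except KeyError:
            raise KeyError(f"unknown country code: {token!r}") from None

    def colour_index(self, token: str) -> int:
        return self._colour_index[token.strip().lower()]

    def emotion_index(self, token: str) -> int:
        return self._emotion_index[token.strip().lower()]

    #: Ordered names of the 240 wide-format features, colour-major.
    def feature_names(self) -> list[str]:
        return [
            f"{c}_{e}" for c in self.colour_terms for e in self.emotion_terms
        ]

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "colour_terms": list(self.colour_terms),
            "emotion_terms": list(self.emotion_terms),
            "countries": list(self.countries),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Vocabulary":
        return cls(
            colour_terms=tuple(d["colour_terms"]),
            emotion_terms=tuple(d["emotion_terms"]),
            countries=tuple(d["countries"]),
        )

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "Vocabulary":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yml", ".yaml"}:
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


#: Vocabulary used throughout unless the caller provides another one.
DEFAULT_VOCABULARY = Vocabulary()
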