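"""Seeded generator of synthetic colour-emotion rating datasets.

The generator emulates the structure of cross-cultural colour-emotion survey
data: each (colour, emotion) cell has a universal association profile shared
by all countries, countries deviate from it by a smaller country-specific
component, and participants differ in their overall propensity to report
associations. Ratings follow a zero-inflated bounded ordinal model: a cell is
either "no association" (rating 0) or, with a cell- and participant-specific
probability, an association whose intensity 1-5 is drawn from a shifted
(beta-)binomial.

Generative model, for country c, colour k, emotion e, participant p:

    U[k,e]   ~ s     * Normal(0, 1)        universal colour-specific profile
    V[c,k,e] ~ delta * Normal(0, 1)        country-specific deviation
    pi[c,k,e]  = squash(logit(base) + U + V)   association probability
    mu[c,k,e]  = 0.1 + 0.8 * squash(U + V)     mean intensity level in (0,1)
    a_p        ~ Normal(0, rho)                participant propensity offset
    associated ~ Bernoulli(squash(logit(pi) + a_p))
    intensity  = 0 if not associated else 1 + Binomial(4, q),
                 q ~ Beta(mu * kappa, (1 - mu) * kappa)

``squash`` is the logistic function with output clipped to
[clip_floor, 1 - clip_floor] so no cell is deterministically all-0 or all-5
unless the floor is explicitly disabled. ``s = 0`` makes profiles identical
across colours (colour decoding at chance); ``delta = 0`` makes them
identical across countries (country decoding at chance, zero expected
in-group advantage). A single global seed feeds a hierarchical stream
(profiles, then one child stream per participant) so subsets reproduce
independently of how many participants are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .vocab import Vocabulary, DEFAULT_VOCABULARY
from .data import RatingDataset

__all__ = [
    "GeneratorConfig",
    "CountryProfiles",
    "make_profiles",
    "simulate_dataset",
    "generate",
]


def logistic(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic rating model.

    Defaults describe a plausible four-country cohort: moderate colour
    specificity, weaker country divergence, a base association rate giving
    roughly two-thirds "no association" responses, and noticeable
    participant heterogeneity.
    """

    vocabulary: Vocabulary = DEFAULT_VOCABULARY
    n_per_country: int = 150
    colour_specificity: float = 1.0   # s: sd of the universal profile
    country_divergence: float = 0.5   # delta: sd of country deviations
    association_base: float = 0.3     # base probability of any association
    heterogeneity: float = 0.5        # rho: sd of participant offsets
    intensity_concentration: float = 10.0  # kappa of the beta-binomial
    seed: int = 0
    clip_floor: float = 0.02          # 0 disables the probability floor

    def __post_init__(self) -> None:
        if self.n_per_country < 1:
            raise ValueError("n_per_country must be >= 1")
        if not (0 < self.association_base < 1):
            raise ValueError("association_base must be in (0, 1)")
        if self.colour_specificity < 0 or self.country_divergence < 0:
            raise ValueError("specificity/divergence must be >= 0")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be >= 0")
        if self.intensity_concentration <= 0:
            raise ValueError("intensity_concentration must be > 0")
        if not (0 <= self.clip_floor < 0.5):
            raise ValueError("clip_floor must be in [0, 0.5)")
        for name in (
            "colour_specificity", "country_divergence", "association_base",
            "heterogeneity", "intensity_concentration",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def squash(self, x: np.ndarray) -> np.ndarray:
        p = logistic(np.asarray(x, dtype=float))
        if self.clip_floor > 0:
            p = np.clip(p, self.clip_floor, 1.0 - self.clip_floor)
        return p

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vocabulary"] = self.vocabulary.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "vocabulary" in d and not isinstance(d["vocabulary"], Vocabulary):
            d["vocabulary"] = Vocabulary.from_dict(d["vocabulary"])
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class CountryProfiles:
    """Per-country association probabilities and intensity means.

    ``pi[c, k, e]`` is the association probability and ``mu[c, k, e]`` the
    mean intensity level for country ``c``, colour ``k``, emotion ``e``;
    ``universal`` is the shared component the country profiles deviate from.
    """

    vocabulary: Vocabulary
    countries: tuple[str, ...]
    pi: np.ndarray         # (C, 12, 20)
    mu: np.ndarray         # (C, 12, 20)
    universal: np.ndarray  # (12, 20)
    country_dev: np.ndarray  # (C, 12, 20)


def _profiles_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), 0]))


def _participant_rng(seed: int, country_index: int, j: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), 1, int(country_index), int(j)])
    )


def make_profiles(config: GeneratorConfig) -> CountryProfiles:
    """Draw the universal and country-specific profile components.

    Deterministic given ``config.seed``; with ``country_divergence = 0`` all
    countries share one profile, and with ``colour_specificity = 0`` the
    association probability is flat at ``association_base`` for every cell.
    """
    v = config.vocabulary
    nk, ne, nc = len(v.colour_terms), len(v.emotion_terms), len(v.countries)
    rng = _profiles_rng(config.seed)
    universal = config.colour_specificity * rng.standard_normal((nk, ne))
    dev = config.country_divergence * rng.standard_normal((nc, nk, ne))
    lin = universal[None, :, :] + dev
    pi = config.squash(logit(np.full((1, 1, 1), config.association_base)) + lin)
    mu = 0.1 + 0.8 * config.squash(lin)
    return CountryProfiles(
        vocabulary=v, countries=v.countries, pi=pi, mu=mu,
        universal=universal, country_dev=dev,
    )


def simulate_dataset(
    profiles: CountryProfiles, config: GeneratorConfig
) -> RatingDataset:
    """Sample a complete rating dataset from country profiles.

    ``n_per_country`` participants are drawn for every country in the
    vocabulary; each receives an id ``<CC>####``, a propensity offset
    ``a_p ~ Normal(0, heterogeneity)``, and a full 12 x 20 grid of ratings.
    """
    if profiles.vocabulary != config.vocabulary:
        raise ValueError("profiles and config use different vocabularies")
    v = config.vocabulary
    nk, ne = len(v.colour_terms), len(v.emotion_terms)
    kappa = config.intensity_concentration

    pids, countries, ages, genders, grids = [], [], [], [], []
    for ci, country in enumerate(v.countries):
        pi_c = profiles.pi[ci]
        mu_c = profiles.mu[ci]
        lo = logit(np.clip(pi_c, 1e-12, 1 - 1e-12))
        for j in range(config.n_per_country):
            rng = _participant_rng(config.seed, ci, j)
            a_p = rng.normal(0.0, config.heterogeneity) if config.heterogeneity > 0 else 0.0
            p_assoc = config.squash(lo + a_p)
            associated = rng.random((nk, ne)) < p_assoc
            interior = (mu_c > 0) & (mu_c < 1)
            q = np.where(interior, 0.5, mu_c)
            if interior.any():
                q = np.where(
                    interior,
                    rng.beta(np.clip(mu_c, 1e-12, None) * kappa,
                             np.clip(1 - mu_c, 1e-12, None) * kappa),
                    q,
                )
            intensity = np.where(associated, 1 + rng.binomial(4, q), 0)
            grids.append(intensity)
            pids.append(f"{country}{j:05d}")
            countries.append(country)
            ages.append(int(rng.integers(18, 71)))
            genders.append(["female", "male", "other"][int(rng.integers(0, 3))])

    participants = pd.DataFrame(
        {"participant_id": pids, "country": countries, "age": ages, "gender": genders}
    )
    order = np.argsort(np.array(pids, dtype=object))
    participants = participants.iloc[order].reset_index(drop=True)
    intensities = np.stack(grids, axis=0)[order]
    return RatingDataset(
        vocabulary=v, participants=participants, intensities=intensities
    )


def generate(config: GeneratorConfig) -> RatingDataset:
    """Convenience wrapper: profiles + simulation in one call."""
    return simulate_dataset(make_profiles(config), config)


def expected_zero_fraction(
    profiles: CountryProfiles, config: GeneratorConfig, n_mc: int = 200_000,
    seed: int = 12345,
) -> float:
    """Monte-Carlo estimate of the marginal probability of a zero rating.

    Integrates ``1 - squash(logit(pi) + a_p)`` over the participant offset
    distribution; used as an oracle for the simulator's zero-rating fraction.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, config.heterogeneity, size=n_mc)
    lo = logit(np.clip(profiles.pi, 1e-12, 1 - 1e-12))
    # E over cells and countries of E_a[1 - squash(lo + a)]
    total = 0.0
    for ai in np.array_split(a, max(1, n_mc // 2000)):
        total += config.squash(lo[..., None] + ai[None, None, None, :]).sum()
    return 1.0 - total / (lo.size * n_mc)
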