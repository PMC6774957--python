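import numpy as np
import pandas as pd
import pytest

from colouremotion import (
    DEFAULT_VOCABULARY,
    GeneratorConfig,
    HyperParams,
    RatingDataset,
    generate,
)


@pytest.fixture(scope="session")
def vocab():
    return DEFAULT_VOCABULARY


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 participants (3 per country), full 12 x 20 grids."""
    return generate(GeneratorConfig(n_per_country=3, seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """80 participants with clear colour structure, no country divergence."""
    return generate(
        GeneratorConfig(
            n_per_country=20, colour_specificity=2.0, country_divergence=0.0, seed=1
        )
    )


@pytest.fixture(scope="session")
def fixed_params():
    """Hyperparameters suited to 0-5-scaled, 20-dimensional rating rows."""
    return [HyperParams(C=10.0, kernel_width=0.01)]


def make_dataset(intensities, countries, vocab=DEFAULT_VOCABULARY):
    """Build a dataset directly from an (n, 12, 20) grid and country labels."""
    intensities = np.asarray(intensities)
    n = intensities.shape[0]
    participants = pd.DataFrame(
        {
            "participant_id": [f"p{i:03d}" for i in range(n)],
            "country": list(countries),
            "age": [30] * n,
            "gender": ["female"] * n,
        }
    )
    return RatingDataset(
        vocabulary=vocab, participants=participants, intensities=intensities
    )
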