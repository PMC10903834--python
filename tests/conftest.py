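import numpy as np
import pytest

from phytovuln import generate_climate, generate_virtual_species, sample_occurrences
from phytovuln.synthetic import NicheSpec


@pytest.fixture(scope="session")
def climate_small():
    """40x40 landscape with an engineered r=0.85 collinear pair."""
    return generate_climate((40, 40), seed=42, collinearity=("tseason", "tmean", 0.85))


@pytest.fixture(scope="session")
def species_small(climate_small):
    return generate_virtual_species(12, climate_small, NicheSpec(n_families=4), seed=7)


@pytest.fixture(scope="session")
def occurrences_small(climate_small, species_small):
    return sample_occurrences(
        species_small, climate_small["present"], n_per_species=120, seed=11,
        morphospecies_fraction=0.05,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
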