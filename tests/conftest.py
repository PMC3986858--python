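import numpy as np
import pytest

from eelclines.synthetic_data import (
    CytbConfig,
    GeographyConfig,
    SpeciesPoolConfig,
    gen_cytb_haplotypes,
    gen_geography,
    gen_species_pools,
)


@pytest.fixture(scope="session")
def default_pools():
    """Calibrated species pools at the eel-like differentiation level."""
    return gen_species_pools(SpeciesPoolConfig(seed=1))


@pytest.fixture(scope="session")
def strong_pools():
    """Strongly diverged pools (per-individual ancestry is identifiable)."""
    return gen_species_pools(
        SpeciesPoolConfig(seed=1, target_fst=0.15, fst_tolerance=0.03)
    )


@pytest.fixture(scope="session")
def geography():
    return gen_geography(GeographyConfig(seed=1))


@pytest.fixture(scope="session")
def cytb_alignment():
    return gen_cytb_haplotypes(CytbConfig(seed=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
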