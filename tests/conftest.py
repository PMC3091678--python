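import numpy as np
import pytest

from regulonscan.motif_profile import build_profile, load_reference_sites
from regulonscan.sequence_model import BackgroundModel
from regulonscan.synthetic_data import SimulationConfig, simulate_genomes


@pytest.fixture(scope="session")
def uniform_bg():
    return BackgroundModel("uniform", np.full(4, 0.25))


@pytest.fixture(scope="session")
def ref_sites():
    return load_reference_sites()


@pytest.fixture(scope="session")
def ref_profile(ref_sites, uniform_bg):
    return build_profile(ref_sites, uniform_bg)


@pytest.fixture(scope="session")
def small_dataset():
    """Three 80-TU genomes with 6 planted TUs; shared across tests."""
    config = SimulationConfig(
        seed=20240911, n_genomes=3, n_tus_per_genome=80, n_planted_tus=6
    )
    return simulate_genomes(config)
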