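import numpy as np
import pytest

from ghtirt.simulate import SCENARIOS, draw_item_parameters, generate_responses, sample_latent


@pytest.fixture(scope="session")
def toy_bank():
    """Fixed 5-item bank inside the study's parameter ranges."""
    a0 = np.array([-0.5, 0.2, 0.9, -0.1, 0.6])
    a1 = np.array([0.8, 1.2, 0.6, 1.4, 1.0])
    return a0, a1


@pytest.fixture(scope="session")
def toy_data(toy_bank):
    """n=400 responses under a standard-normal latent trait."""
    a0, a1 = toy_bank
    z = sample_latent(SCENARIOS["A"], 400, np.random.SeedSequence(2024))
    return generate_responses(a0, a1, z, np.random.SeedSequence(2025))


@pytest.fixture(scope="session")
def medium_data():
    """p=10, n=1000 scenario-A dataset with a drawn item bank."""
    a0, a1 = draw_item_parameters(10, np.random.SeedSequence(31))
    z = sample_latent(SCENARIOS["A"], 1000, np.random.SeedSequence(32))
    return (a0, a1), generate_responses(a0, a1, z, np.random.SeedSequence(33))
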