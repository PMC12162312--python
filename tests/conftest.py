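import numpy as np
import pytest

from audioclust import Audiogram, SimulationConfig, simulate_cohort


@pytest.fixture
def flat_audiogram():
    return Audiogram.from_values([10, 10, 10, 10, 10, 10])


@pytest.fixture(scope="session")
def default_cohort():
    """One default-size synthetic cohort, shared across tests."""
    return simulate_cohort(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort for cheap pipeline tests."""
    return simulate_cohort(SimulationConfig(n_patients=80, seed=7))


def random_audiogram(rng: np.random.Generator) -> Audiogram:
    """A valid random audiogram on the 0.01 dB grid."""
    values = np.round(rng.uniform(-10, 110, size=6), 2)
    return Audiogram.from_values(values)
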