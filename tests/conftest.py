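import numpy as np
import pytest

from growthmix import LongitudinalDataset, ScenarioConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset() -> LongitudinalDataset:
    """5 subjects x 5 occasions, complete, from scenario 1."""
    return generate_dataset(ScenarioConfig(1, "low", 5, seed=11))


@pytest.fixture(scope="session")
def small_dataset() -> LongitudinalDataset:
    """300 subjects from scenario 1, low separation (shared across tests)."""
    return generate_dataset(ScenarioConfig(1, "low", 300, seed=5))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
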