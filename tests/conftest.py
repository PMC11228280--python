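import numpy as np
import pytest

from omicsmix import SimulationConfig, preprocess_dataset, simulate_multiomics


@pytest.fixture(scope="session")
def small_cohort():
    """A small raw synthetic cohort shared by unit tests (never mutated)."""
    cfg = SimulationConfig(
        n_samples=80,
        K=3,
        dims=(60, 40, 30, 20),
        n_informative=8,
        seed=11,
    )
    return simulate_multiomics(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    dataset, _ = small_cohort
    return dataset


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset):
    return preprocess_dataset(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
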