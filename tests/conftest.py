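import numpy as np
import pytest

from seizurepca import (ExperimentConfig, SimulationConfig, run_comparison,
                        simulate_dataset)

#: Root seed of the default synthetic study used across the suite.
DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_dataset():
    """The default study: 100 seizures with 60 s margins + 1.5 h non-seizure."""
    return simulate_dataset(SimulationConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_report(default_dataset):
    return run_comparison(default_dataset, ExperimentConfig(split_seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced study (12 seizures, 10 min non-seizure) for cheap tests."""
    return simulate_dataset(
        SimulationConfig(seed=3, n_seizures=12, nonseizure_duration_s=600.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
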