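import warnings

import numpy as np
import pytest

from rgevo.synthetic_data import SimulationConfig, simulate

warnings.filterwarnings("ignore", category=DeprecationWarning)


@pytest.fixture(scope="session")
def small_sim():
    """Compact 8-species dataset used by unit tests (10 R families)."""
    return simulate(SimulationConfig(n_r_families=10,
                                     n_background_families=160, seed=7))


@pytest.fixture(scope="session")
def default_sim():
    """The study-condition dataset: default config, seed 42."""
    return simulate(SimulationConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
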