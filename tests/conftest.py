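import numpy as np
import pytest

from reporterscreen.annotation import default_annotation
from reporterscreen.simulate import SimulationConfig


@pytest.fixture(scope="session")
def annotation():
    return default_annotation()


@pytest.fixture
def rng():
    return np.random.default_rng(20120209)


@pytest.fixture
def small_config():
    """A small but structurally complete screen for fast end-to-end tests."""
    return SimulationConfig(seed=7, n_mutant_genotypes=40,
                            n_cells_control=20_000, n_cells_treated=20_000,
                            n_control_replicates=12)
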