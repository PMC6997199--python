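import numpy as np
import pytest

from coelosim import SimulationConfig, lab_default_params


@pytest.fixture(scope="session")
def lab():
    """Laboratory default (FitnessParams, DevelopmentParams, HabitatParams)."""
    return lab_default_params()


@pytest.fixture(scope="session")
def lab_cfg():
    """Experimental-evolution demography: K=1000, 5 generations, p0=0.32."""
    return SimulationConfig(k=1000, n_generations=5, p0=0.32,
                            n_replicates=30, seed=1234)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
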