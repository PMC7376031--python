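import numpy as np
import pytest

from raresdm import SimulationConfig, simulate_community


@pytest.fixture(scope="session")
def default_dataset():
    """One default-size community shared by read-only tests."""
    return simulate_community(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A small community for fast pipeline tests."""
    cfg = SimulationConfig(n_sites=60, n_common=8, n_rare=2,
                           rare_prevalence_targets=(0.08, 0.13),
                           seed=5)
    return simulate_community(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
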