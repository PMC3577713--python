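import numpy as np
import pytest

from trflpkit.simulate import ScenarioConfig, simulate_taxa


@pytest.fixture(scope="session")
def default_config():
    return ScenarioConfig(seed=0)


@pytest.fixture(scope="session")
def default_taxa(default_config):
    return simulate_taxa(default_config)


@pytest.fixture(scope="session")
def small_clone_config():
    """Reduced scenario for alignment-heavy clone tests."""
    return ScenarioConfig(
        seed=0,
        n_rare_taxa=3,
        ref_length=(300, 340),
        clone_library_size=30,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
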