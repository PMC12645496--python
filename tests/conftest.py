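import numpy as np
import pytest

from gcthybrid import ModelConfig, StateLayout, default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def layout(params, config):
    return StateLayout.for_config(params, config)


def random_states(layout, n, seed=0, scale=1.0):
    """Nonnegative random states spanning several orders of magnitude."""
    rng = np.random.default_rng(seed)
    mags = rng.uniform(-3, 2, size=(n, layout.n_state))
    return scale * 10.0 ** mags * rng.random((n, layout.n_state))
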