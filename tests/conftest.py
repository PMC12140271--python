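import numpy as np
import pytest

from pasom import ModelConfig, NetworkSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A 60-agent, 25-round configuration for fast end-to-end tests."""
    return ModelConfig(
        n_agents=60, n_rounds=25, n_sims=4,
        network=NetworkSpec(n_clusters=12, mean_cluster_size=5,
                            p_between=2.0 / 60.0),
    )
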