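import numpy as np
import pytest

from memflex import ModelConfig


@pytest.fixture
def config() -> ModelConfig:
    """Default published parameterisation."""
    return ModelConfig()


@pytest.fixture
def small_config() -> ModelConfig:
    """A miniature network for fast structural tests."""
    return ModelConfig(n_hc=10, n_pfc=20, k_hc=3, k_pfc=4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
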