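import numpy as np
import pytest

from multipath_unet import ModelConfig, PathwaySpec


@pytest.fixture
def tiny_config() -> ModelConfig:
    """Two coherent pathways (2^2 == 4^1) at 16x16, no dropout."""
    return ModelConfig(
        input_height=16, input_width=16, input_channels=1,
        pathways=(PathwaySpec(2, (3, 4), 5), PathwaySpec(4, (3,), 5)),
        dropout_rate=0.0, seed=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
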