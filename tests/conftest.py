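import numpy as np
import pytest

from gallnet.model_core import (ArchitectureConfig, ConvStageSpec,
                                DenseHeadSpec, MSFEBlockSpec, build_model)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A narrow six-stage configuration on 64x64 inputs: cheap enough for
    forward/backward unit tests while exercising both stage kinds."""
    return ArchitectureConfig(
        stages=(
            ConvStageSpec(4),
            MSFEBlockSpec(2, 2, 2),
            ConvStageSpec(8),
            MSFEBlockSpec(3, 3, 3),
            ConvStageSpec(8),
            ConvStageSpec(8),
        ),
        head=DenseHeadSpec(hidden=(16, 8), dropout=0.1, l2=0.01),
        input_size=64,
    )


@pytest.fixture
def tiny_model(tiny_config):
    return build_model(tiny_config, seed=7)
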