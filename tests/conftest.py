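import numpy as np
import pytest

from darunet.config import NetworkConfig, SynthConfig
from darunet.data import SegmentationSample, standardize
from darunet.synthetic import generate_samples


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synth_samples():
    """Eight standardized 64x64 speckle phantoms (the overfit bench)."""
    cfg = SynthConfig(n_samples=8, seed=7)
    return [
        SegmentationSample(s.id, standardize(s.image)[0], s.mask)
        for s in generate_samples(cfg)
    ]


@pytest.fixture
def tiny_cfg():
    """Two-level architecture for fast wiring tests (divisor 4)."""
    return NetworkConfig(encoder_filters=(3, 6), decoder_filters=(4,),
                         n_residual_blocks=2)


@pytest.fixture
def reduced_cfg():
    return NetworkConfig.reduced()
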