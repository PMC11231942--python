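import numpy as np
import pytest

from bvocgame import ModelParams, SimConfig


@pytest.fixture
def focal_params() -> ModelParams:
    """The focal parameter set of the study: c=0.1, p=0.4, n=8, d=0.05."""
    return ModelParams(alpha1=0.5, alpha2=0.9, p=0.4, c=0.1, n=8, d=0.05)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config(focal_params) -> SimConfig:
    """A desk-tiny lattice configuration for fast structural tests."""
    return SimConfig(params=focal_params, L=20, steps=50, seed=42,
                     density_emitter=0.05, density_nonemitter=0.05)
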