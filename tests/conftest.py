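import numpy as np
import pytest

from invasim import ModelParameters


@pytest.fixture
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture
def fast_params() -> ModelParameters:
    """Scaled-down run-control settings for quick engine tests."""
    return ModelParameters(warmup_cycles=50, max_cycles=100, n_0=5, k_0=40.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
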