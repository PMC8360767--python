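import numpy as np
import pytest

from oscivm import forward_model as fm
from oscivm import synthetic_data as synth


@pytest.fixture
def hrf():
    return fm.HrfParams()


@pytest.fixture
def components():
    return fm.ModelComponents()


@pytest.fixture
def quiet_cfg():
    """Small noiseless BOLD config for exact-recovery tests."""
    return synth.GeneratorConfig(
        seed=11, n_runs=2, noise_sd=0.0, shared_sd=0.0, drift_slope=0.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
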