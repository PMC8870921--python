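import numpy as np
import pytest

from lesionquant import PhantomSpec, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Compact phantom for fast unit tests."""
    return PhantomSpec(seed=7)


@pytest.fixture
def clean_spec():
    """Phantom without noise, bias or misalignment (pure geometry)."""
    return PhantomSpec(noise_sigma=0.0, bias_amplitude=0.0,
                       max_shift_mm=0.0, max_rotation_rad=0.0, seed=7)


@pytest.fixture
def random_volume(rng):
    return Volume(rng.random((12, 10, 4)), (1.0, 1.5, 2.0))
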