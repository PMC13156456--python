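import numpy as np
import pytest

from hp_lvpool.phantom import PhantomSpec, make_study
from hp_lvpool.preprocess import NoiseEstimate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """Noiseless 64x64 study spec with an exactly exponential profile."""
    return PhantomSpec(grid_size=64, lv_center=(32.0, 32.0),
                       endo_radii=(8.6, 8.4), planted_B=0.0105,
                       planted_Imax=1286.0, noise_sigma=0.0, seed=7)


@pytest.fixture
def noiseless_study(small_spec):
    return make_study(small_spec)


@pytest.fixture
def noisy_study():
    spec = PhantomSpec(grid_size=64, lv_center=(32.0, 32.0),
                       endo_radii=(8.6, 8.4), planted_B=0.0105,
                       planted_Imax=1286.0, noise_sigma=0.15, seed=11)
    return make_study(spec)


@pytest.fixture
def unit_noise():
    return NoiseEstimate(sigma=1.0)
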