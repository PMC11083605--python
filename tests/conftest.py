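import numpy as np
import pytest

from chewsim.synthetic import MixSpec
from chewsim.transposition import InVitroSetting, in_vitro_saliva_volume


@pytest.fixture
def make_setting():
    def _make(n_compressions: int, rpm: float) -> InVitroSetting:
        return InVitroSetting(
            n_compressions=n_compressions,
            rotation_speed=rpm,
            saliva_volume=in_vitro_saliva_volume(0.05, 7, n_compressions),
            cheese_mass=32.69,
        )

    return _make


@pytest.fixture
def small_mix():
    """Small, noise-free mixing spec for fast deterministic image tests."""
    return MixSpec(shape=(96, 96), noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
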