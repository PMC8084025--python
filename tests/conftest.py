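import numpy as np
import pytest
from hypothesis import settings

from hydricniche import GEOCRINIA_ALBA, GEOCRINIA_VITELLINA, IncubationRegime

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def alba():
    return GEOCRINIA_ALBA


@pytest.fixture
def vitellina():
    return GEOCRINIA_VITELLINA


@pytest.fixture
def constant_regime():
    def make(temp, regime_id=None):
        return IncubationRegime(
            regime_id=regime_id or f"const{temp:g}", kind="constant", constant_temp=temp
        )

    return make


@pytest.fixture
def square_wave_regime():
    """Hourly alternation between two temperatures."""

    def make(t_low, t_high, regime_id="square"):
        return IncubationRegime(
            regime_id=regime_id, kind="fluctuating",
            hourly_temps=tuple([t_low, t_high] * 12),
        )

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
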