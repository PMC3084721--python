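import numpy as np
import pytest

from forcemap import ForceCurve, InstrumentConfig


@pytest.fixture
def config():
    return InstrumentConfig()


def make_curve(z, F, direction="approach", k_c=0.0104):
    return ForceCurve(z=np.asarray(z, float), F=np.asarray(F, float),
                      direction=direction, k_c=k_c)


@pytest.fixture
def noise_curve():
    """Flat pure-noise approach curve (no contact anywhere)."""
    rng = np.random.default_rng(42)
    z = np.linspace(-2000.0, 500.0, 2700)
    return make_curve(z, rng.normal(0.0, 0.01, z.size))
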