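import numpy as np
import pytest

from preedge import Spectrum


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_spectrum(rng):
    """A 20-point spectrum with an irregular grid and smooth-ish values."""
    e = np.sort(rng.uniform(6530.0, 6550.0, size=20))
    y = np.sin(0.7 * (e - 6530.0)) + rng.normal(0, 0.05, size=20) + 2.0
    return Spectrum(e, y, {"provenance": "fixture"})
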