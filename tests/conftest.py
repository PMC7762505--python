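import numpy as np
import pytest

from megnpt.spectral import Recording


@pytest.fixture
def white_noise_recording():
    """Unit-variance white noise, 60 s at 200 Hz, 2 channels."""
    rng = np.random.default_rng(42)
    return Recording(samples=rng.standard_normal((2, 12000)), fs=200.0)


@pytest.fixture
def uniform_psdn():
    """Uniform PSDn on the 1-70 Hz grid at 0.1 Hz spacing."""
    from megnpt.spectral import NormalizedPsd

    freqs = np.round(np.arange(1.0, 70.0 + 0.05, 0.1), 10)
    mass = np.full(freqs.size, 1.0 / freqs.size)
    return NormalizedPsd(freqs=freqs, mass=mass)
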