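import numpy as np
import pytest

from esnet.session.types import Recording
from esnet.synth.render import default_montage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_recording(samples: np.ndarray, rate: float = 500.0) -> Recording:
    """Wrap raw samples with the default montage for their channel count."""
    n = samples.shape[0]
    montage = default_montage(n)
    return Recording(samples, rate, list(montage.keys()), montage)


def sinusoids(freqs, rate=500.0, duration=30.0, phases=None, amplitudes=None):
    """Channels x samples matrix of pure tones."""
    t = np.arange(0.0, duration, 1.0 / rate)
    freqs = np.atleast_1d(freqs)
    phases = np.zeros(len(freqs)) if phases is None else np.atleast_1d(phases)
    amplitudes = np.ones(len(freqs)) if amplitudes is None else np.atleast_1d(amplitudes)
    return np.stack([a * np.sin(2 * np.pi * f * t + p)
                     for f, p, a in zip(freqs, phases, amplitudes)])


@pytest.fixture
def noise_recording(rng):
    return make_recording(rng.standard_normal((4, 15000)), rate=500.0)
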