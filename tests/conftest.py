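import numpy as np
import pytest

from gsconn.preprocess import ContinuousRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sine_recording(freq_hz, rate_hz=250.0, duration_s=8.0, amplitude=1.0):
    t = np.arange(int(duration_s * rate_hz)) / rate_hz
    samples = amplitude * np.sin(2 * np.pi * freq_hz * t)[None, :]
    return ContinuousRecording(
        samples=samples, rate_hz=rate_hz, channel_labels=["Cz"], events=np.empty(0)
    )


@pytest.fixture
def sine_recording():
    return make_sine_recording


def steady_rms(x, discard_s=1.0, rate_hz=250.0):
    """RMS of the middle of a signal, away from filter edge transients."""
    k = int(discard_s * rate_hz)
    core = x[..., k:-k]
    return np.sqrt(np.mean(core**2))
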