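import numpy as np
import pytest

from eegecg.recording import Recording

AMPS = {"delta": 8.0, "theta": 6.0, "alpha": 10.0, "beta": 4.0, "gamma": 2.0}


@pytest.fixture(scope="session")
def amps():
    """Reference per-band generating amplitudes used across tests."""
    return dict(AMPS)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def sine_recording(freq_hz, fs=250.0, duration_s=20.0, amplitude=1.0, labels=("Cz",)):
    """Single- or multi-channel pure sinusoid Recording."""
    t = np.arange(int(duration_s * fs)) / fs
    row = amplitude * np.sin(2 * np.pi * freq_hz * t)
    data = np.tile(row, (len(labels), 1))
    return Recording(labels, fs, data)


@pytest.fixture(scope="session")
def small_eeg():
    """One deterministic synthetic 4-channel EEG segment (session-cached)."""
    from eegecg.synth import gen_eeg

    return gen_eeg(
        ["F3", "F4", "Fz", "Cz"], 250.0, 120.0, AMPS, faa_shift=0.0, noise_sd=5.0, seed=7
    )
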