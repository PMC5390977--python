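import numpy as np
import pytest

from rrestim.core import RespiratorySignal, Waveform
from rrestim.simulate import SimulationConfig, generate_modulated_train


def tone(freq_bpm: float, duration_s: float = 32.0, fs: float = 5.0,
         amplitude: float = 1.0, technique: str = "xb1"
         ) -> RespiratorySignal:
    """Noiseless single-tone respiratory signal."""
    t = np.arange(int(duration_s * fs)) / fs
    return RespiratorySignal(
        amplitude * np.sin(2 * np.pi * freq_bpm / 60.0 * t), fs, technique,
        "bw")


@pytest.fixture(scope="session")
def am_ecg():
    return generate_modulated_train(
        SimulationConfig("ecg", "am", hr=80.0, rr=18.0))


@pytest.fixture(scope="session")
def fm_ecg():
    return generate_modulated_train(
        SimulationConfig("ecg", "fm", hr=80.0, rr=12.0))


@pytest.fixture(scope="session")
def am_ppg():
    return generate_modulated_train(
        SimulationConfig("ppg", "am", hr=80.0, rr=18.0))


@pytest.fixture(scope="session")
def plain_ecg():
    """Unmodulated beat train (zero modulation depth)."""
    return generate_modulated_train(
        SimulationConfig("ecg", "bw", hr=80.0, rr=18.0, depth=0.0))


def dominant_bpm(values: np.ndarray, fs: float) -> float:
    """DFT-based dominant frequency of a series, in cycles/min."""
    v = np.asarray(values, dtype=float)
    v = v - v.mean()
    mag = np.abs(np.fft.rfft(v, n=max(4096, v.size)))
    freqs = np.fft.rfftfreq(max(4096, v.size), d=1.0 / fs) * 60.0
    mag[0] = 0.0
    return float(freqs[np.argmax(mag)])
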