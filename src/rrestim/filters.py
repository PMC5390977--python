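"""Zero-phase Butterworth filtering helpers.

All quoted cutoffs are the design (-3 dB) frequencies of the one-pass filter;
filters are applied forward-backward (``sosfiltfilt``) so fiducial timing is
not shifted. Pad lengths are clamped for short windows.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

BPM_TO_HZ = 1.0 / 60.0


def _sosfiltfilt(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    padlen = min(3 * (2 * sos.shape[0] + 1), x.size - 1)
    return signal.sosfiltfilt(sos, x, padlen=max(padlen, 0))


def highpass(x: np.ndarray, fs: float, cutoff_hz: float,
             order: int = 2) -> np.ndarray:
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=fs,
                        output="sos")
    return _sosfiltfilt(sos, x)


def lowpass(x: np.ndarray, fs: float, cutoff_hz: float,
            order: int = 4) -> np.ndarray:
    if cutoff_hz >= fs / 2:
        warnings.warn(
            f"low-pass cutoff {cutoff_hz} Hz >= Nyquist ({fs / 2} Hz); "
            "stage skipped", stacklevel=2)
        return x
    sos = signal.butter(order, cutoff_hz, btype="lowpass", fs=fs,
                        output="sos")
    return _sosfiltfilt(sos, x)


def bandpass(x: np.ndarray, fs: float, lo_hz: float, hi_hz: float,
             order: int = 2) -> np.ndarray:
    hi_hz = min(hi_hz, 0.99 * fs / 2)
    sos = signal.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs,
                        output="sos")
    return _sosfiltfilt(sos, x)


def bandpass_bpm(x: np.ndarray, fs: float, lo_bpm: float = 4.0,
                 hi_bpm: float = 60.0, order: int = 2) -> np.ndarray:
    """Band-pass with cutoffs quoted in breaths/min."""
    return bandpass(x, fs, lo_bpm * BPM_TO_HZ, hi_bpm * BPM_TO_HZ,
                    order=order)


def notch(x: np.ndarray, fs: float, freq_hz: float = 50.0,
          q: float = 30.0) -> np.ndarray:
    if freq_hz >= fs / 2:
        return x
    b, a = signal.iirnotch(freq_hz, q, fs=fs)
    padlen = min(3 * max(len(a), len(b)), x.size - 1)
    return signal.filtfilt(b, a, x, padlen=max(padlen, 0))


def resample_to(x: np.ndarray, fs: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling to a new uniform rate."""
    if fs == fs_out:
        return np.asarray(x, dtype=float)
    from fractions import Fraction
    frac = Fraction(fs_out / fs).limit_denominator(1000)
    return signal.resample_poly(x, frac.numerator, frac.denominator)
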