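"""Autoregressive and Fourier spectral helpers.

AR coefficients are estimated with Burg's recursion (stable on short
windows). A model ``A(z) = 1 + a1 z^-1 + ... + ap z^-p`` has power spectral
density ``var / |A(e^{jw})|^2`` and poles at the roots of ``A``.
"""
from __future__ import annotations

import numpy as np
from scipy import signal as sig

BPM_TO_HZ = 1.0 / 60.0


def burg(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Burg AR fit; returns (coefficients [1, a1..ap], noise variance)."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    if n <= order:
        raise ValueError(f"need more than {order} samples, got {n}")
    f = x.copy()
    b = x.copy()
    a = np.array([1.0])
    var = float(np.dot(x, x) / n)
    for _ in range(order):
        fm = f[1:]
        bm = b[:-1]
        den = np.dot(fm, fm) + np.dot(bm, bm)
        k = -2.0 * np.dot(fm, bm) / den if den > 0 else 0.0
        a = np.concatenate([a, [0.0]]) + k * np.concatenate([[0.0], a[::-1]])
        f, b = fm + k * bm, bm + k * fm
        var *= max(1.0 - k * k, np.finfo(float).tiny)
    return a, var


def ar_psd(a: np.ndarray, var: float, freqs_hz: np.ndarray,
           fs: float) -> np.ndarray:
    """AR power spectral density on an arbitrary frequency grid."""
    w = 2 * np.pi * np.asarray(freqs_hz) / fs
    z = np.exp(-1j * np.outer(w, np.arange(a.size)))
    denom = np.abs(z @ a) ** 2
    return var / np.maximum(denom, np.finfo(float).tiny)


def ar_poles(a: np.ndarray) -> np.ndarray:
    """Poles of the AR model (roots of A(z))."""
    return np.roots(a)


def poles_in_band(a: np.ndarray, fs: float, lo_bpm: float = 4.0,
                  hi_bpm: float = 60.0) -> list[tuple[float, float]]:
    """Upper-half-plane poles with angle inside the respiratory band.

    Returns (frequency_bpm, magnitude) pairs.
    """
    out = []
    for p in ar_poles(a):
        if p.imag <= 0:
            continue
        f_bpm = np.angle(p) / (2 * np.pi) * fs * 60.0
        if lo_bpm <= f_bpm <= hi_bpm:
            out.append((float(f_bpm), float(np.abs(p))))
    return out


def bpm_grid(fs: float, n: int = 2048, lo_bpm: float = 4.0,
             hi_bpm: float = 60.0) -> np.ndarray:
    """Dense frequency grid over the respiratory band, in bpm."""
    return np.linspace(lo_bpm, hi_bpm, n)


def fft_spectrum(x: np.ndarray, fs: float,
                 nfft: int = 2048) -> tuple[np.ndarray, np.ndarray]:
    """Zero-padded magnitude spectrum; returns (freqs_bpm, magnitude)."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    nfft = max(nfft, x.size)
    mag = np.abs(np.fft.rfft(x, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs) * 60.0
    return freqs, mag


def welch_spectrum(x: np.ndarray, fs: float,
                   n_segments: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with ``n_segments`` half-overlapping segments.

    Returns (freqs_bpm, power) with the grid refined by zero-padding so the
    respiratory band is well resolved on 32 s windows.
    """
    x = np.asarray(x, dtype=float)
    nperseg = max(int(2 * x.size / (n_segments + 1)), 8)
    nfft = max(2048, nperseg)
    freqs_hz, power = sig.welch(x - x.mean(), fs=fs, nperseg=nperseg,
                                noverlap=nperseg // 2, nfft=nfft)
    return freqs_hz * 60.0, power


def band_peak(freqs_bpm: np.ndarray, power: np.ndarray,
              lo_bpm: float = 4.0, hi_bpm: float = 60.0) -> float | None:
    """Frequency (bpm) of the largest peak inside the band.

    Equal maxima break toward the lowest frequency. Returns None when the
    band is empty or the in-band power is all zero/non-finite.
    """
    mask = (freqs_bpm >= lo_bpm) & (freqs_bpm <= hi_bpm)
    if not np.any(mask):
        return None
    p = np.asarray(power, dtype=float)[mask]
    f = np.asarray(freqs_bpm, dtype=float)[mask]
    if not np.any(np.isfinite(p)) or np.nanmax(p) <= 0:
        return None
    return float(f[int(np.argmax(p))])  # argmax takes first (lowest f) tie
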