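"""Beat detection and fiducial measurement.

ECG beats are found with a Pan-Tompkins-style QRS detector (band-pass,
derivative, squaring, moving-window integration, adaptive thresholding);
PPG pulses with an incremental-merge segmentation (IMS) detector that merges
short line segments of common slope direction and accepts up-strokes whose
amplitude exceeds an adaptive threshold.

Fiducial conventions (uniform across signal types): ``trough_idx[i]`` is the
trough immediately preceding ``peak_idx[i]`` — for ECG the minimum within the
0.10 s prior to the R-wave, for PPG the minimum between the previous pulse
peak (or window start) and the current one. Q and S waves are the minima
immediately before and after the R wave (ECG only).
"""
from __future__ import annotations

import numpy as np
from scipy import signal as sig

from .core import BeatAnnotations, Waveform
from .filters import bandpass


def detect_beats(waveform: Waveform) -> BeatAnnotations:
    """Dispatch to the signal-appropriate beat detector."""
    if waveform.signal_type == "ecg":
        return detect_beats_ecg(waveform)
    if waveform.signal_type == "ppg":
        return detect_beats_ppg(waveform)
    raise ValueError(f"no beat detector for {waveform.signal_type!r}")


def _invalid() -> BeatAnnotations:
    return BeatAnnotations(peak_idx=np.array([], dtype=int),
                           trough_idx=np.array([], dtype=int),
                           valid=False)


def detect_beats_ecg(waveform: Waveform) -> BeatAnnotations:
    x = waveform.samples
    fs = waveform.fs
    if x.size < 2 * fs or np.ptp(x) == 0:
        return _invalid()

    # Pan-Tompkins chain: 5-15 Hz band-pass, derivative, square, integrate
    bp = bandpass(x, fs, 5.0, 15.0, order=2)
    der = np.gradient(bp)
    sq = der ** 2
    win = max(int(round(0.15 * fs)), 1)
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    # candidate integration peaks, 200 ms refractory
    cand, _ = sig.find_peaks(mwi, distance=max(int(0.2 * fs), 1))
    if cand.size == 0:
        return _invalid()

    # adaptive signal/noise running estimates (SPKI/NPKI)
    head = mwi[: int(2 * fs)]
    spki = 0.4 * head.max()
    npki = 0.1 * head.max()
    qrs = []
    for p in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[p] > thr:
            qrs.append(p)
            spki = 0.125 * mwi[p] + 0.875 * spki
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
    if len(qrs) < 2:
        return _invalid()

    # refine R as the waveform maximum near each detection
    half = int(round(0.10 * fs))
    r_idx = []
    for p in qrs:
        lo, hi = max(p - half, 0), min(p + half + 1, x.size)
        r_idx.append(lo + int(np.argmax(x[lo:hi])))
    r_idx = np.unique(r_idx)
    # enforce refractory on refined peaks, keeping the larger
    keep = [int(r_idx[0])]
    for r in r_idx[1:]:
        if r - keep[-1] < int(0.2 * fs):
            if x[r] > x[keep[-1]]:
                keep[-1] = int(r)
        else:
            keep.append(int(r))
    r_idx = np.asarray(keep)
    if r_idx.size < 2:
        return _invalid()

    pre = int(round(0.10 * fs))
    q_idx, s_idx, trough_idx = [], [], []
    for r in r_idx:
        lo = max(r - pre, 0)
        seg = x[lo:r] if r > lo else x[lo:lo + 1]
        q = lo + int(np.argmin(seg))
        hi = min(r + pre + 1, x.size)
        s = r + 1 + int(np.argmin(x[r + 1:hi])) if r + 1 < hi else r
        q_idx.append(q)
        s_idx.append(s)
        trough_idx.append(q)  # minimum within 0.10 s prior to R
    return BeatAnnotations(peak_idx=r_idx,
                           trough_idx=np.asarray(trough_idx),
                           q_idx=np.asarray(q_idx),
                           s_idx=np.asarray(s_idx))


def _merge_segments(x: np.ndarray, seg_len: int):
    """IMS line building: join consecutive segments of equal slope sign."""
    idx = np.arange(0, x.size, seg_len)
    if idx[-1] != x.size - 1:
        idx = np.append(idx, x.size - 1)
    y = x[idx]
    slopes = np.sign(np.diff(y))
    lines = []  # (start_idx, end_idx, amplitude, direction)
    start = 0
    for i in range(1, slopes.size + 1):
        if i == slopes.size or slopes[i] != slopes[start]:
            lines.append((int(idx[start]), int(idx[i]),
                          float(y[i] - y[start]), int(slopes[start])))
            start = i
    return lines


def detect_beats_ppg(waveform: Waveform,
                     seg_ms: float = 30.0) -> BeatAnnotations:
    x = waveform.samples
    fs = waveform.fs
    if x.size < 2 * fs or np.ptp(x) == 0:
        return _invalid()

    seg_len = max(int(round(seg_ms / 1000.0 * fs)), 2)
    lines = _merge_segments(x, seg_len)
    up = [ln for ln in lines if ln[3] > 0]
    if not up:
        return _invalid()

    amps = np.array([ln[2] for ln in up])
    thr = 0.5 * np.median(amps[amps > 0]) if np.any(amps > 0) else 0.0
    refractory = 0.27  # s, ~220 beats/min ceiling
    peaks = []
    recent: list[float] = []
    for lo, hi, amp, _ in up:
        if amp < thr:
            continue
        # true local maximum at the end of the accepted up-stroke
        w = min(hi + seg_len, x.size)
        p = lo + int(np.argmax(x[lo:w]))
        if peaks and (p - peaks[-1]) / fs < refractory:
            if x[p] > x[peaks[-1]]:
                peaks[-1] = p
            continue
        peaks.append(p)
        recent.append(amp)
        if len(recent) > 3:
            recent.pop(0)
        thr = 0.5 * float(np.mean(recent))
    if len(peaks) < 2:
        return _invalid()
    peaks = np.asarray(peaks)

    def _troughs(pk: np.ndarray) -> np.ndarray:
        out = []
        for i, p in enumerate(pk):
            lo = pk[i - 1] if i > 0 else 0
            out.append(lo + int(np.argmin(x[lo:p])) if p > lo else int(p))
        return np.asarray(out)

    # reject truncated edge pulses: amplitude well below the typical pulse
    troughs = _troughs(peaks)
    amp = x[peaks] - x[troughs]
    keep = amp >= 0.4 * np.median(amp)
    peaks = peaks[keep]
    if peaks.size < 2:
        return _invalid()
    return BeatAnnotations(peak_idx=peaks, trough_idx=_troughs(peaks))
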