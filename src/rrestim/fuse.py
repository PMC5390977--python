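"""Fusion of simultaneous and successive RR estimates.

Modulation fusion combines the RRs (or spectra, or AR poles) derived from
the three beat-feature respiratory signals that track baseline wander,
amplitude modulation and frequency modulation (``xb1``, ``xb2``, ``xb3``).
Temporal fusion exponentially smooths successive window estimates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RESP_BAND_BPM
from .estimate import SpectrumEstimate

MODULATION_FUSION = ("fm1", "fm2", "fm3", "fm4")
TEMPORAL_FUSION = ("ft1",)

SMART_FUSION_SD_BPM = 4.0  # disagreement gate on the three estimates


@dataclass
class ModulationEstimates:
    """RR values from the BW/AM/FM feature signals; any may be absent."""

    rr_bw: float | None
    rr_am: float | None
    rr_fm: float | None

    def as_tuple(self) -> tuple:
        return (self.rr_bw, self.rr_am, self.rr_fm)


@dataclass
class FusedRR:
    rr: float | None
    method: str

    @property
    def has_output(self) -> bool:
        return self.rr is not None


def _in_band(rr: float) -> bool:
    lo, hi = RESP_BAND_BPM
    return lo <= rr <= hi


def smart_fusion(est: ModulationEstimates,
                 sd_limit: float = SMART_FUSION_SD_BPM) -> FusedRR:
    """Mean of the three modulation RRs when their sample standard
    deviation is <= ``sd_limit`` bpm; otherwise no output (fm1).

    Any absent input estimate also yields no output.
    """
    vals = est.as_tuple()
    if any(v is None for v in vals):
        return FusedRR(rr=None, method="fm1")
    arr = np.asarray(vals, dtype=float)
    if np.std(arr, ddof=1) <= sd_limit:
        return FusedRR(rr=float(arr.mean()), method="fm1")
    return FusedRR(rr=None, method="fm1")


def spectral_peak_conditioned_average(spectra: list[SpectrumEstimate],
                                      peak_fraction: float = 0.4,
                                      half_width_bpm: float = 2.0
                                      ) -> FusedRR:
    """Peak-conditioned averaging of the three Welch spectra (fm2).

    A spectrum qualifies when at least ``peak_fraction`` of its in-band
    power lies within ``half_width_bpm`` of its own peak; qualifying spectra
    are normalised to unit total power and averaged, and RR is the argmax of
    the mean spectrum. No qualifying spectra -> no output.
    """
    usable = [s for s in spectra if s is not None]
    if not usable:
        return FusedRR(rr=None, method="fm2")
    ref = usable[0].freqs
    for s in usable[1:]:
        if s.freqs.shape != ref.shape or not np.allclose(s.freqs, ref):
            raise ValueError("spectra must share a common frequency grid")
    lo, hi = RESP_BAND_BPM
    band = (ref >= lo) & (ref <= hi)
    if not np.any(band):
        return FusedRR(rr=None, method="fm2")
    qualifying = []
    for s in usable:
        p = np.asarray(s.power, dtype=float)[band]
        total = p.sum()
        if total <= 0:
            continue
        f = ref[band]
        fpeak = f[int(np.argmax(p))]
        near = np.abs(f - fpeak) <= half_width_bpm
        if p[near].sum() / total >= peak_fraction:
            qualifying.append(p / total)
    if not qualifying:
        return FusedRR(rr=None, method="fm2")
    mean_spec = np.mean(qualifying, axis=0)
    f = ref[band]
    return FusedRR(rr=float(f[int(np.argmax(mean_spec))]), method="fm2")


def pole_fusion(poles: list[tuple[float, float]],
                criterion: str = "magnitude",
                min_dtheta_bpm: float = 1e-6) -> FusedRR:
    """Select a respiratory frequency from pooled AR poles.

    ``poles`` is a list of (frequency_bpm, magnitude) pairs pooled from the
    AR(8) fits of the three modulation signals, already restricted to the
    respiratory band.

    ``magnitude`` (fm3): the frequency of the highest-magnitude pole.
    ``ranking`` (fm4): over all pole pairs maximise the pole ranking
    criterion ``PRC = mean(m_i, m_j) / |theta_i - theta_j|**2``; RR is the
    mean frequency of the winning pair.  Identical-angle pairs have
    infinite PRC and win outright (the angle difference is floored at
    ``min_dtheta_bpm`` to avoid division error).
    """
    cands = [(f, m) for f, m in poles if _in_band(f)]
    if criterion == "magnitude":
        if not cands:
            return FusedRR(rr=None, method="fm3")
        f, _ = max(cands, key=lambda fm: fm[1])
        return FusedRR(rr=float(f), method="fm3")
    if criterion != "ranking":
        raise ValueError(f"unknown pole-fusion criterion {criterion!r}")
    if len(cands) < 2:
        return FusedRR(rr=None, method="fm4")
    best_prc, best_rr = -np.inf, None
    for i in range(len(cands)):
        for j in range(i + 1, len(cands)):
            fi, mi = cands[i]
            fj, mj = cands[j]
            dtheta = max(abs(fi - fj), min_dtheta_bpm)
            prc = (mi + mj) / 2.0 / dtheta ** 2
            if prc > best_prc:
                best_prc, best_rr = prc, (fi + fj) / 2.0
    return FusedRR(rr=float(best_rr), method="fm4")


class TemporalSmoother:
    """Exponential smoothing of successive RR estimates (ft1).

    ``rr_i = 0.2 * rr_est + 0.8 * rr_{i-1}``. The first estimate passes
    through unsmoothed; a no-output estimate carries the previous smoothed
    value forward.
    """

    WEIGHT_NEW = 0.2

    def __init__(self) -> None:
        self.rr_prev: float | None = None

    def step(self, rr_est: float | None) -> FusedRR:
        if rr_est is None:
            return FusedRR(rr=self.rr_prev, method="ft1")
        if self.rr_prev is None:
            self.rr_prev = float(rr_est)
        else:
            self.rr_prev = (self.WEIGHT_NEW * float(rr_est)
                            + (1.0 - self.WEIGHT_NEW) * self.rr_prev)
        return FusedRR(rr=self.rr_prev, method="ft1")


def temporal_smoothing(rr_est: float | None,
                       rr_prev: float | None) -> FusedRR:
    """One step of the ft1 recursion (stateless form)."""
    s = TemporalSmoother()
    s.rr_prev = rr_prev
    return s.step(rr_est)
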