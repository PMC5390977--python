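"""Extraction: preprocessing, beat detection, features, resampling."""
import numpy as np
import pytest

from conftest import dominant_bpm
from rrestim.beats import detect_beats
from rrestim.core import BeatAnnotations, FeatureSeries, Waveform
from rrestim.extract import (clean_and_resample, extract_filter_based,
                             extract_respiratory, flag_ectopic,
                             measure_feature, preprocess, resample_uniform)
from rrestim.simulate import SimulationConfig, generate_modulated_train


class TestPreprocess:
    def test_dc_offset_removed(self):
        t = np.arange(60 * 500) / 500.0
        wf = Waveform(5.0 + 0.0 * t, 500.0, "ecg")
        out = preprocess(wf).samples
        interior = out[5 * 500:-5 * 500]
        assert np.max(np.abs(interior)) < 1e-6 * 5.0

    def test_mains_interference_suppressed(self):
        t = np.arange(60 * 500) / 500.0
        wf = Waveform(np.sin(2 * np.pi * 50.0 * t), 500.0, "ecg")
        out = preprocess(wf).samples[15 * 500:-15 * 500]
        assert np.max(np.abs(out)) < 0.05

    def test_respiratory_band_preserved(self):
        t = np.arange(120 * 500) / 500.0
        wf = Waveform(np.sin(2 * np.pi * 0.2 * t), 500.0, "ppg")
        out = preprocess(wf).samples[10 * 500:-10 * 500]
        ref = np.sin(2 * np.pi * 0.2 * t)[10 * 500:-10 * 500]
        amp_ratio = np.ptp(out) / np.ptp(ref)
        assert amp_ratio == pytest.approx(1.0, abs=0.05)

    def test_low_rate_lowpass_skipped_with_warning(self):
        t = np.arange(60 * 125) / 125.0
        wf = Waveform(np.sin(2 * np.pi * 1.0 * t), 125.0, "ecg")
        with pytest.warns(UserWarning):
            preprocess(wf)


class TestBeatDetection:
    def test_ecg_beat_count(self, plain_ecg):
        beats = detect_beats(preprocess(plain_ecg.waveform))
        expected = 210 * 80 / 60  # 280
        assert abs(beats.n_beats - expected) <= 1

    def test_fm_beat_times_match_simulator(self, fm_ecg):
        pre = preprocess(fm_ecg.waveform)
        beats = detect_beats(pre)
        det_t = beats.peak_idx / pre.fs
        # ground truth: the R-wave sits at a fixed phase (0.30) of each
        # rendered beat interval
        onsets = fm_ecg.beat_onsets
        intervals = np.diff(np.append(onsets, fm_ecg.config.duration))
        truth = onsets + 0.30 * intervals
        # the final beat is truncated at the record end, where the
        # reconstructed interval (hence R phase) is not defined
        n = min(det_t.size, truth.size) - 1
        assert n >= 279
        assert np.max(np.abs(det_t[:n] - truth[:n])) <= 2.0 / pre.fs

    def test_flat_line_flagged_invalid(self):
        wf = Waveform(np.zeros(30 * 500), 500.0, "ecg")
        beats = detect_beats(wf)
        assert not beats.valid

    def test_ppg_detection(self, am_ppg):
        pre = preprocess(am_ppg.waveform)
        beats = detect_beats(pre)
        assert abs(beats.n_beats - 280) <= 3
        assert np.all(beats.trough_idx <= beats.peak_idx)

    def test_ecg_fiducial_ordering(self, plain_ecg):
        beats = detect_beats(preprocess(plain_ecg.waveform))
        assert np.all(beats.q_idx < beats.peak_idx)
        assert np.all(beats.peak_idx < beats.s_idx)


def _annotations(peaks, troughs, q=None, s=None):
    return BeatAnnotations(peak_idx=np.asarray(peaks),
                           trough_idx=np.asarray(troughs),
                           q_idx=None if q is None else np.asarray(q),
                           s_idx=None if s is None else np.asarray(s))


class TestFeatures:
    def test_interval_feature_constant_spacing(self):
        fs = 100.0
        peaks = np.arange(5) * 75 + 10  # 0.75 s apart
        x = np.zeros(500)
        x[peaks] = 1.0
        wf = Waveform(x, fs, "ecg")
        beats = _annotations(peaks, peaks - 5)
        feats = measure_feature(wf, beats, "xb3")
        assert np.allclose(feats.values, 0.75)

    def test_amplitude_difference_by_definition(self):
        fs = 10.0
        x = np.zeros(40)
        peaks, troughs = [10, 30], [5, 25]
        x[10], x[30] = 1.2, 1.0
        x[5], x[25] = 0.2, 0.4
        wf = Waveform(x, fs, "ppg")
        feats = measure_feature(wf, _annotations(peaks, troughs), "xb2")
        assert np.allclose(feats.values, [1.0, 0.6])

    def test_qrs_area_triangle(self):
        # triangular QRS of height h on base b above a flat baseline
        fs = 500.0
        h, b = 1.0, 0.08  # 40 samples wide
        x = np.zeros(1000)
        half = int(b * fs / 2)
        for r in (300, 700):
            ramp = np.linspace(0, h, half + 1)
            x[r - half:r + 1] = ramp
            x[r:r + half + 1] = ramp[::-1]
        beats = _annotations([300, 700], [280, 680],
                             q=[300 - half, 700 - half],
                             s=[300 + half, 700 + half])
        feats = measure_feature(Waveform(x, fs, "ecg"), beats, "xb8")
        assert np.allclose(feats.values, h * b / 2, rtol=0.02)

    def test_signal_technique_mismatch_rejected(self):
        wf = Waveform(np.random.default_rng(0).normal(size=5000), 500.0,
                      "ppg")
        beats = _annotations([100, 400, 700], [50, 350, 650])
        with pytest.raises(ValueError):
            measure_feature(wf, beats, "xb7")


class TestCleanAndResample:
    def test_uniform_input_is_identity(self):
        times = np.arange(50) / 5.0
        values = np.sin(times)
        grid, out = resample_uniform(times, values, 5.0)
        assert np.allclose(grid, times)
        assert np.allclose(out, values)

    def test_irregular_sampling_recovers_tone(self):
        rng = np.random.default_rng(3)
        beat_t = np.cumsum(rng.uniform(0.6, 0.9, 300))  # ~hr 80
        feats = FeatureSeries(beat_t, np.sin(2 * np.pi * 0.3 * beat_t),
                              "xb1")
        resp = clean_and_resample(feats)
        assert resp is not None
        assert dominant_bpm(resp.values, resp.fs) == pytest.approx(
            18.0, abs=1.0)

    def test_ectopic_interval_flagged(self):
        times = np.arange(30) * 0.8
        times[15:] += 1.6  # one interval 3x the local median
        flags = flag_ectopic(times)
        assert flags[15] and flags[14]
        assert not flags[:14].any() and not flags[16:].any()

    def test_too_few_beats_gives_no_output(self):
        feats = FeatureSeries(np.array([0.0, 1.0]), np.array([1.0, 2.0]),
                              "xb1")
        assert clean_and_resample(feats) is None


class TestFilterBased:
    def test_bandpass_identity_in_passband(self):
        t = np.arange(210 * 500) / 500.0
        wf = Waveform(np.sin(2 * np.pi * 0.3 * t), 500.0, "ppg")
        resp = extract_filter_based(wf, "xa1")
        interior = resp.values[10 * 5:-10 * 5]
        assert dominant_bpm(interior, resp.fs) == pytest.approx(18.0,
                                                                abs=0.5)
        assert np.ptp(interior) == pytest.approx(2.0, rel=0.1)

    def test_cwt_ridge_frequency_tracks_fm(self, fm_ecg):
        resp = extract_respiratory(fm_ecg.waveform, "xa3")
        interior = resp.values[10 * 5:-10 * 5]
        assert dominant_bpm(interior, resp.fs) == pytest.approx(12.0,
                                                                abs=1.0)

    def test_cwt_ridge_amplitude_tracks_am(self, am_ecg):
        resp = extract_respiratory(am_ecg.waveform, "xa2")
        interior = resp.values[10 * 5:-10 * 5]
        assert dominant_bpm(interior, resp.fs) == pytest.approx(18.0,
                                                                abs=1.0)

    def test_unknown_technique_rejected(self):
        t = np.arange(32 * 500) / 500.0
        with pytest.raises(ValueError):
            extract_filter_based(Waveform(np.sin(t), 500.0, "ecg"), "xa9")


class TestEndToEnd:
    @pytest.mark.parametrize("modulation,technique",
                             [("bw", "xb4"), ("am", "xb5"), ("fm", "xb3")])
    def test_matched_extractor_recovers_rate(self, modulation, technique):
        sim = generate_modulated_train(
            SimulationConfig("ecg", modulation, hr=80, rr=18))
        resp = extract_respiratory(sim.waveform, technique)
        assert resp is not None
        assert dominant_bpm(resp.values, resp.fs) == pytest.approx(
            18.0, abs=1.0)

    def test_band_limited_output(self, am_ecg):
        resp = extract_respiratory(am_ecg.waveform, "xb2")
        v = resp.values - resp.values.mean()
        mag2 = np.abs(np.fft.rfft(v)) ** 2
        freqs = np.fft.rfftfreq(v.size, 1.0 / resp.fs) * 60.0
        out_band = mag2[(freqs < 4.0) | (freqs > 60.0)].sum()
        assert out_band / mag2.sum() < 0.05
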