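"""Cleaning chain: detrending, TDDR, zero-phase band-pass, peak picking."""

import numpy as np
import pytest
from scipy import signal as sps

from eegfnirs import (
    bandpass_hemo,
    clean_pipeline,
    detrend_poly1,
    extract_response_peaks,
    make_stroop_schedule,
    nth_peak,
    simulate_hemodynamics,
    tddr,
)
from eegfnirs.containers import HemodynamicSeries
from eegfnirs.errors import InvalidParameterError
from eegfnirs.fnirs_clean import bandpass_sos


class TestDetrend:
    def test_pure_line_removed_completely(self):
        t = np.arange(1000.0)
        x = 3.0 + 0.02 * t
        out, coefs = detrend_poly1(x)
        assert np.max(np.abs(out)) <= 1e-10 * np.max(np.abs(x))
        assert coefs[0] == pytest.approx(3.0)
        assert coefs[1] == pytest.approx(0.02)

    def test_many_period_sinusoid_nearly_unchanged(self):
        t = np.arange(10000.0)
        x = np.sin(2 * np.pi * t / 100.0)  # 100 full periods, zero mean
        out, coefs = detrend_poly1(x)
        assert abs(coefs[1]) < 1e-5
        assert np.allclose(out, x, atol=1e-2)

    def test_output_has_zero_mean_and_slope(self, rng):
        x = rng.normal(0, 1, (3, 500)) + np.linspace(0, 5, 500)
        out, _ = detrend_poly1(x)
        t = np.arange(500.0)
        for ch in range(3):
            assert abs(out[ch].mean()) < 1e-10
            slope = np.polyfit(t, out[ch], 1)[0]
            assert abs(slope) < 1e-12

    def test_too_short_raises(self):
        with pytest.raises(InvalidParameterError):
            detrend_poly1(np.array([1.0]))


class TestTddr:
    def test_constant_signal_unchanged_with_unit_weights(self):
        x = np.full(500, 2.5)
        out, w = tddr(x, 100.0)
        assert np.allclose(out, 2.5)
        assert np.all(w == 1.0)

    def test_weights_bounded_and_near_zero_inside_spike(self):
        rng = np.random.default_rng(0)
        t = np.arange(3000) / 100.0
        x = 0.3 * np.sin(2 * np.pi * 0.1 * t) + 0.01 * rng.standard_normal(len(t))
        spike = 10 * x.std() * np.exp(-0.5 * ((t - 15.0) / 0.15) ** 2)
        out, w = tddr(x + spike, 100.0)
        assert np.all((w >= 0) & (w <= 1))
        spike_region = slice(int(14.7 * 100), int(15.3 * 100))
        assert w[spike_region].min() < 0.05

    def test_artifact_suppression_reduces_rmse_to_ground_truth(self):
        s = make_stroop_schedule(30, seed=1)
        hemo, truth = simulate_hemodynamics(s, seed=1)
        noisy = hemo.hbo2
        t = np.arange(noisy.shape[-1]) / 100.0
        art = 10 * noisy.std() * np.exp(-0.5 * ((t - 45.0) / 0.13) ** 2)[None, :]
        art = art + 3 * noisy.std() * (t >= 55.0)[None, :]
        corrupted = noisy + art
        out, _ = tddr(corrupted, 100.0)
        rmse_pre = np.sqrt(np.mean((corrupted - truth.hbo2_true) ** 2))
        rmse_post = np.sqrt(np.mean((out - truth.hbo2_true) ** 2))
        assert rmse_post < rmse_pre

    def test_baseline_shift_removed(self):
        t = np.arange(6000) / 100.0
        x = 0.2 * np.sin(2 * np.pi * 0.1 * t)
        shifted = x + 2.0 * (t >= 30.0)
        out, _ = tddr(shifted, 100.0)
        # the 2 uM step should be mostly gone: halves differ by far less
        halves_diff = abs(out[3500:].mean() - out[:2500].mean())
        assert halves_diff < 0.4

    def test_too_short_raises(self):
        with pytest.raises(InvalidParameterError):
            tddr(np.array([1.0, 2.0]), 100.0)


class TestBandpass:
    def test_cardiac_sinusoid_rejected(self):
        fs = 10.0
        t = np.arange(int(1000 * fs)) / fs
        x = np.sin(2 * np.pi * 1.0 * t)
        y = bandpass_hemo(x, fs)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        assert np.sqrt(np.mean(y[mid] ** 2)) < 0.01 * np.sqrt(0.5)

    def test_passband_sinusoid_survives(self):
        fs = 10.0
        t = np.arange(int(2000 * fs)) / fs
        x = np.sin(2 * np.pi * 0.04 * t)
        y = bandpass_hemo(x, fs)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        assert np.sqrt(np.mean(y[mid] ** 2)) >= 0.70 * np.sqrt(0.5)

    def test_zero_in_zero_out(self):
        assert np.all(bandpass_hemo(np.zeros(1000), 100.0) == 0)

    def test_invalid_band_raises(self):
        with pytest.raises(InvalidParameterError):
            bandpass_hemo(np.zeros(100), 100.0, low=0.08, high=0.01)

    def test_designed_magnitude_matches_prewarped_closed_form(self):
        """The realized digital Butterworth magnitude equals the analog
        prototype magnitude evaluated at bilinear-prewarped frequencies."""
        fs, low, high, order = 100.0, 0.01, 0.08, 3
        sos = bandpass_sos(fs, low, high, order)

        def warp(f):
            return 2 * fs * np.tan(np.pi * f / fs)

        W1, W2 = warp(low), warp(high)
        for f in (0.04, 1.0):
            _, h = sps.sosfreqz(sos, worN=[f], fs=fs)
            W = warp(f)
            analytic = 1.0 / np.sqrt(1.0 + ((W * W - W1 * W2) / ((W2 - W1) * W)) ** (2 * order))
            assert abs(h[0]) == pytest.approx(analytic, rel=0.01)

    def test_zero_phase_no_lag_on_passband_tone(self):
        fs = 10.0
        t = np.arange(int(2000 * fs)) / fs
        x = np.sin(2 * np.pi * 0.04 * t)
        y = bandpass_hemo(x, fs)
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        xc = np.correlate(y[mid] - y[mid].mean(), x[mid] - x[mid].mean(), "full")
        assert np.argmax(xc) - (len(x[mid]) - 1) == 0


class TestPeaks:
    @staticmethod
    def _hemo(hbo2, hbr, fs=10.0):
        return HemodynamicSeries(hbo2, hbr, fs=fs, channels=("ch",))

    def test_single_bump_found_at_apex(self):
        fs = 10.0
        t = np.arange(int(60 * fs)) / fs
        bump = np.exp(-0.5 * ((t - 30.0) / 3.0) ** 2)
        hemo = self._hemo(bump, -0.25 * bump, fs)
        peaks = extract_response_peaks(hemo, (0.0, 5.0, 40.0, 60.0))
        assert len(peaks["hbo2"][0]) == 1
        assert peaks["hbo2"][0][0][0] == pytest.approx(30.0, abs=1 / fs)

    def test_monotone_series_has_no_peaks(self):
        fs = 10.0
        t = np.arange(int(60 * fs)) / fs
        hemo = self._hemo(t / 60.0, -t / 60.0, fs)
        peaks = extract_response_peaks(hemo, (0.0, 5.0, 40.0, 60.0))
        assert peaks["hbo2"][0] == [] and peaks["hbr"][0] == []

    def test_two_bump_hbr_first_and_second_peaks(self):
        fs = 10.0
        t = np.arange(int(120 * fs)) / fs
        hbr = -np.exp(-0.5 * ((t - 40.0) / 4.0) ** 2) - 0.8 * np.exp(
            -0.5 * ((t - 80.0) / 4.0) ** 2
        )
        hemo = self._hemo(-hbr, hbr, fs)
        peaks = extract_response_peaks(hemo, (0.0, 10.0, 100.0, 120.0))
        p1 = nth_peak(peaks["hbr"][0], 1, "negative")
        p2 = nth_peak(peaks["hbr"][0], 2, "negative")
        assert p1[0] == pytest.approx(40.0, abs=1 / fs)
        assert p2[0] == pytest.approx(80.0, abs=1 / fs)
        assert nth_peak(peaks["hbr"][0], 3, "negative") is None


class TestPipelineOrder:
    def test_full_chain_improves_truth_correlation(self):
        """Default chain (detrend -> TDDR -> band-pass) brings the cleaned
        series closer to the noise-free activation than the raw input."""
        from eegfnirs import forward_mbll, inject_motion_artifacts, recover_hemodynamics

        s = make_stroop_schedule(30, seed=4)
        hemo, truth = simulate_hemodynamics(s, seed=4)
        rng = np.random.default_rng(4)
        hemo.hbo2, _ = inject_motion_artifacts(
            hemo.hbo2, 100.0, [60.0], [8 * hemo.hbo2.std()], [80.0], [3 * hemo.hbo2.std()]
        )
        hemo.hbr, _ = inject_motion_artifacts(
            hemo.hbr, 100.0, [60.0], [4 * hemo.hbo2.std()], [80.0], [1.5 * hemo.hbo2.std()]
        )
        rec = recover_hemodynamics(forward_mbll(hemo))
        cleaned, report = clean_pipeline(rec)
        c_raw = np.corrcoef(rec.hbo2[0], truth.hbo2_true[0])[0, 1]
        c_clean = np.corrcoef(cleaned.hbo2[0], truth.hbo2_true[0])[0, 1]
        assert c_clean > c_raw
        assert report.tddr_iterations >= 1
        lo3db, hi3db = report.realized_minus3db_hz
        assert 0 < lo3db < hi3db < 50.0

    def test_steps_can_be_reordered(self):
        s = make_stroop_schedule(10, seed=0)
        hemo, _ = simulate_hemodynamics(s, seed=0)
        cleaned, _ = clean_pipeline(hemo, steps=("tddr", "detrend", "bandpass"))
        assert cleaned.hbo2.shape == hemo.hbo2.shape
        with pytest.raises(InvalidParameterError):
            clean_pipeline(hemo, steps=("wavelet",))
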