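"""Generator properties: schedules, hemodynamics, artifacts, crosstalk."""

import numpy as np
import pytest
from scipy import signal as sps

from eegfnirs import (
    BackgroundConfig,
    ForearmParams,
    NoiseConfig,
    forearm_closed_form,
    forward_mbll,
    inject_crosstalk,
    inject_motion_artifacts,
    make_erp_template,
    make_stroop_schedule,
    recover_hemodynamics,
    simulate_eeg,
    simulate_forearm_block,
    simulate_hemodynamics,
)
from eegfnirs.containers import HemodynamicSeries
from eegfnirs.errors import AliasingError, InvalidParameterError


class TestStroopSchedule:
    def test_condition_split_rounds_toward_congruent(self):
        s = make_stroop_schedule(30, 1 / 3, seed=0)
        assert np.sum(s.conditions == "congruent") == 10
        assert np.sum(s.conditions == "incongruent") == 20
        # 31 * 1/3 = 10.33 -> rounds up
        s31 = make_stroop_schedule(31, 1 / 3, seed=0)
        assert np.sum(s31.conditions == "congruent") == 11

    @pytest.mark.parametrize("seed", range(5))
    def test_every_gap_inside_isi_bounds(self, seed):
        s = make_stroop_schedule(30, display_s=0.5, isi_low_s=0.35, isi_high_s=0.75, seed=seed)
        assert len(s.gaps) == 29
        assert np.all(s.gaps >= 0.85 - 1e-12)
        assert np.all(s.gaps <= 1.25 + 1e-12)
        assert np.all(np.diff(s.trial_onsets) > 0)

    def test_trials_inside_task_period(self, schedule):
        _, task_start, task_end, _ = schedule.period_boundaries
        assert np.all(schedule.trial_onsets >= task_start)
        assert np.all(schedule.trial_onsets + schedule.display_s <= task_end + 1e-12)

    def test_empty_schedule(self):
        s = make_stroop_schedule(0, seed=0)
        assert s.n_trials == 0
        # zero task duration: task start equals task end
        assert s.period_boundaries[1] == s.period_boundaries[2]

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            make_stroop_schedule(-1, seed=0)
        with pytest.raises(InvalidParameterError):
            make_stroop_schedule(10, display_s=-0.5, seed=0)
        with pytest.raises(InvalidParameterError):
            make_stroop_schedule(10, isi_low_s=0.8, isi_high_s=0.4, seed=0)

    def test_same_seed_bit_identical(self):
        a = make_stroop_schedule(30, seed=3)
        b = make_stroop_schedule(30, seed=3)
        assert np.array_equal(a.trial_onsets, b.trial_onsets)
        assert np.array_equal(a.conditions, b.conditions)


class TestHemodynamics:
    def test_silent_generator_is_identically_zero(self):
        s = make_stroop_schedule(0, seed=0, wait_s=5.0, rest_s=5.0)
        quiet = NoiseConfig(mayer_amp=0, resp_amp=0, cardiac_amp=0, drift_um=0, white_sd=0)
        hemo, truth = simulate_hemodynamics(s, noise_cfg=quiet, seed=0)
        assert np.all(hemo.hbo2 == 0) and np.all(hemo.hbr == 0)
        assert np.all(truth.hbo2_true == 0)

    def test_hbr_smaller_and_opposite(self, schedule):
        hemo, truth = simulate_hemodynamics(schedule, amp_hbo2=1.0, seed=1)
        assert np.max(np.abs(truth.hbr_true)) < np.max(np.abs(truth.hbo2_true))
        peak = np.argmax(truth.hbo2_true[0])
        assert truth.hbr_true[0, peak] < 0 < truth.hbo2_true[0, peak]

    def test_mayer_component_spectral_peak(self):
        """A lone 0.1 Hz component of amplitude a shows a periodogram peak
        at 0.1 Hz with power consistent with a^2/2."""
        s = make_stroop_schedule(0, seed=0, wait_s=200.0, rest_s=200.0)
        a = 0.3
        cfg = NoiseConfig(mayer_amp=a, resp_amp=0, cardiac_amp=0, drift_um=0, white_sd=0)
        hemo, _ = simulate_hemodynamics(s, fs=10.0, noise_cfg=cfg, seed=5)
        f, p = sps.periodogram(hemo.hbo2[0], fs=10.0)
        assert abs(f[np.argmax(p)] - 0.1) <= f[1] - f[0]
        assert np.mean(hemo.hbo2[0] ** 2) == pytest.approx(a**2 / 2, rel=0.05)

    def test_invalid_fs_raises(self, schedule):
        with pytest.raises(InvalidParameterError):
            simulate_hemodynamics(schedule, fs=0.0, seed=0)

    def test_same_seed_bit_identical(self, schedule):
        a, _ = simulate_hemodynamics(schedule, seed=9)
        b, _ = simulate_hemodynamics(schedule, seed=9)
        assert np.array_equal(a.hbo2, b.hbo2)
        assert np.array_equal(a.hbr, b.hbr)

    def test_hbt_is_elementwise_sum(self, schedule):
        hemo, _ = simulate_hemodynamics(schedule, seed=2)
        assert np.max(np.abs(hemo.hbt - (hemo.hbo2 + hemo.hbr))) <= 1e-12


class TestForwardMbll:
    def test_zero_concentration_gives_baseline_intensity(self, geometry):
        hemo = HemodynamicSeries(np.zeros((2, 100)), np.zeros((2, 100)), fs=100.0)
        raw = forward_mbll(hemo, geometry, i0=(1.5, 2.5))
        assert np.allclose(raw.intensity[:, 0, :], 1.5)
        assert np.allclose(raw.intensity[:, 1, :], 2.5)

    def test_round_trip_with_known_reference(self, geometry, rng):
        hemo = HemodynamicSeries(
            rng.normal(0, 1, (2, 500)), rng.normal(0, 0.3, (2, 500)), fs=100.0
        )
        raw = forward_mbll(hemo, geometry)
        rec = recover_hemodynamics(raw, i0=(1.0, 1.0))
        scale = np.abs(hemo.hbo2).max()
        assert np.abs(rec.hbo2 - hemo.hbo2).max() / scale < 1e-9
        assert np.abs(rec.hbr - hemo.hbr).max() / scale < 1e-9

    def test_od_linear_in_pathlength(self, rng):
        from eegfnirs import OptodeGeometry
        from eegfnirs.mbll import optical_density

        hemo = HemodynamicSeries(
            rng.normal(0, 1, (2, 50)), rng.normal(0, 0.3, (2, 50)), fs=100.0
        )
        g1 = OptodeGeometry(separation_mm=30.0)
        g2 = OptodeGeometry(separation_mm=60.0)
        od1 = optical_density(forward_mbll(hemo, g1), i0=(1, 1))
        od2 = optical_density(forward_mbll(hemo, g2), i0=(1, 1))
        assert np.allclose(od2, 2 * od1)

    def test_proportional_extinction_rows_rejected(self, geometry):
        from eegfnirs.containers import ExtinctionTable

        bad = ExtinctionTable(
            eps={
                ("hbo2", 760.0): 0.1,
                ("hbr", 760.0): 0.2,
                ("hbo2", 850.0): 0.2,
                ("hbr", 850.0): 0.4,
            }
        )
        hemo = HemodynamicSeries(np.zeros((2, 10)), np.zeros((2, 10)), fs=100.0)
        from eegfnirs.errors import IllConditionedCoefficientsError

        with pytest.raises(IllConditionedCoefficientsError):
            forward_mbll(hemo, geometry, coeffs=bad)


class TestMotionArtifacts:
    def test_empty_lists_leave_series_untouched(self, rng):
        x = rng.normal(0, 1, (2, 1000))
        out, log = inject_motion_artifacts(x, 100.0)
        assert np.array_equal(out, x)
        assert log == []

    def test_step_is_exact_from_onset(self):
        x = np.zeros((1, 1000))
        out, log = inject_motion_artifacts(x, 100.0, shift_times=[5.0], shift_amps=[2.5])
        assert np.all(out[0, :500] == 0)
        assert np.all(out[0, 500:] == 2.5)
        assert log[0].kind == "shift"

    def test_log_audits_two_spikes(self):
        x = np.zeros((1, 2000))
        out, log = inject_motion_artifacts(
            x, 100.0, spike_times=[3.0, 12.0], spike_amps=[1.0, -2.0]
        )
        spikes = [e for e in log if e.kind == "spike"]
        assert [e.time_s for e in spikes] == [3.0, 12.0]
        assert out[0, 300] == pytest.approx(1.0, rel=1e-9)

    def test_out_of_range_time_raises(self):
        with pytest.raises(InvalidParameterError):
            inject_motion_artifacts(np.zeros((1, 100)), 100.0, spike_times=[99.0], spike_amps=[1.0])


class TestSimulateEeg:
    def test_template_placed_exactly_with_zero_background(self):
        s = make_stroop_schedule(1, seed=0, wait_s=2.0, rest_s=2.0)
        tpl = make_erp_template({"N500": -5.0}, fs=1000.0)
        eeg = simulate_eeg(
            s, erp_templates=tpl, background_cfg=BackgroundConfig(rms_uv=0.0), seed=0
        )
        i0 = int(round(s.trial_onsets[0] * 1000))
        assert np.allclose(eeg.samples[0, i0 : i0 + len(tpl)], tpl)
        assert np.all(eeg.samples[0, :i0] == 0)
        assert np.all(eeg.samples[0, i0 + len(tpl) :] == 0)

    def test_negative_template_recovers_negative_n500(self):
        from eegfnirs import erp_pipeline

        s = make_stroop_schedule(40, display_s=0.5, isi_low_s=0.6, isi_high_s=1.0, seed=2)
        tpl = make_erp_template({"N500": -5.0}, fs=1000.0)
        eeg = simulate_eeg(
            s, erp_templates=tpl, background_cfg=BackgroundConfig(rms_uv=5.0), seed=2
        )
        erp = erp_pipeline(eeg)
        assert np.all(erp.components["N500"] < 0)

    def test_overlapping_template_warns(self):
        s = make_stroop_schedule(5, seed=0)
        tpl = np.ones(1000)  # 1 s template vs ~0.85 s minimum gap
        with pytest.warns(UserWarning, match="overlap"):
            simulate_eeg(s, erp_templates=tpl, seed=0)


class TestCrosstalk:
    def test_zero_amplitude_is_identity(self, schedule):
        eeg = simulate_eeg(schedule, seed=0)
        out = inject_crosstalk(eeg, 125.0, 0.0)
        assert np.array_equal(out.samples, eeg.samples)

    def test_pulse_train_zero_mean(self, schedule):
        eeg = simulate_eeg(schedule, seed=0)
        out = inject_crosstalk(eeg, 125.0, 10.0)
        added = out.samples[0] - eeg.samples[0]
        assert abs(added.mean()) <= 1e-12 * 10.0

    def test_above_nyquist_raises(self, schedule):
        eeg = simulate_eeg(schedule, seed=0)
        with pytest.raises(AliasingError):
            inject_crosstalk(eeg, 500.0, 1.0)

    def test_spectral_location_of_switching_fundamental(self):
        s = make_stroop_schedule(0, seed=0, wait_s=10.0, rest_s=10.0)
        quiet = BackgroundConfig(rms_uv=0.0)
        eeg = simulate_eeg(s, erp_templates=np.zeros(1), background_cfg=quiet, seed=0)
        for f_sw, expect_low in [(125.0, False), (30.0, True)]:
            out = inject_crosstalk(eeg, f_sw, 10.0)
            f, p = sps.periodogram(out.samples[0], fs=1000.0)
            peak_f = f[np.argmax(p)]
            assert peak_f == pytest.approx(f_sw, abs=f[1])
            in_band = p[(f > 1) & (f < 50)].max()
            if expect_low:
                assert in_band == p.max()
            else:
                assert in_band < 1e-6 * p.max()


class TestForearmBlock:
    def test_zero_slopes_give_flat_zero(self):
        p = ForearmParams(hbo2_slope=0, hbr_slope=0, overshoot_hbo2=0, overshoot_hbr=0)
        hemo, truth = simulate_forearm_block(p, noise_sd=0.0, seed=0)
        assert np.all(truth.hbo2_true == 0) and np.all(truth.hbr_true == 0)

    def test_opposite_signs_during_occlusion(self):
        p = ForearmParams()
        hemo, truth = simulate_forearm_block(p, noise_sd=0.0, seed=0)
        fs = 100.0
        occ = slice(int((p.baseline_s + 1) * fs), int((p.baseline_s + p.occlusion_s) * fs))
        assert np.all(truth.hbo2_true[0, occ] < 0)
        assert np.all(truth.hbr_true[0, occ] > 0)

    def test_returns_to_baseline_per_closed_form(self):
        p = ForearmParams()
        hemo, truth = simulate_forearm_block(p, noise_sd=0.0, seed=0)
        t = np.arange(truth.hbo2_true.shape[-1]) / 100.0
        cf_o, cf_r = forearm_closed_form(t, p)
        assert np.allclose(truth.hbo2_true[0], cf_o)
        # final 10 s within a small tolerance of zero baseline
        assert abs(truth.hbo2_true[0, -1000:].mean()) < 0.01
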