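"""End-to-end session runners for the two experiments.

``run_stroop_session`` simulates a cohort of virtual participants and
executes the full chain — task schedule, hemodynamics, forward MBLL,
inversion, cleaning, peak extraction, EEG synthesis with crosstalk,
acquisition chain, ERP analysis — and closes with the coupling
statistics.  ``run_forearm_block`` runs the arterial-occlusion scenario
through the optical round trip and detrending.

Participant-to-participant variability is modeled as one shared cortical
activation gain per participant (scaling both the hemodynamic amplitude
and the ERP template), which is what makes the electrical and
hemodynamic response amplitudes covary across the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import coupling as cpl
from . import eeg_erp, fnirs_clean, io, mbll, synthgen
from .containers import OptodeGeometry
from .errors import EegFnirsError, StageError

logger = logging.getLogger("eegfnirs")


def _participant_seed(base_seed: int, participant: int) -> int:
    """Derive an independent, reproducible sub-stream seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(participant)])
    return int(ss.generate_state(1)[0] % (2**31))


def _stage(name: str, fn, *args, **kwargs):
    try:
        result = fn(*args, **kwargs)
    except EegFnirsError as exc:
        raise StageError(name, exc) from exc
    logger.info("stage=%s ok", name)
    return result


@dataclass
class StroopSessionBundle:
    """Everything a Stroop cohort run produced."""

    config: io.SessionConfig
    participants: list = field(default_factory=list)
    erp_amplitudes: dict = field(default_factory=dict)  # comp -> (n_part, n_ch)
    hbr_first_peak: np.ndarray | None = None  # (n_part, n_ch)
    hbr_second_peak: np.ndarray | None = None
    coupling_results: dict = field(default_factory=dict)
    channel_comparisons: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _simulate_participant(config: io.SessionConfig, p: int, gain: float, geom) -> dict:
    seed_p = _participant_seed(config.seed, p)
    rng = np.random.default_rng(seed_p)

    schedule = _stage(
        "schedule",
        synthgen.make_stroop_schedule,
        config.n_trials,
        config.congruent_fraction,
        config.display_s,
        config.isi_low_s,
        config.isi_high_s,
        seed=seed_p,
        wait_s=config.wait_s,
        rest_s=config.rest_s,
    )

    hemo, truth = _stage(
        "hemodynamics",
        synthgen.simulate_hemodynamics,
        schedule,
        fs=config.fnirs_fs,
        amp_hbo2=config.amp_hbo2 * gain,
        amp_hbr=config.amp_hbo2 * gain * config.hbr_ratio,
        seed=seed_p,
    )

    # motion artifacts inside the task period (key presses and posture
    # changes happen while the task runs), common to both chromophores
    t_lo, t_hi = schedule.period_boundaries[1], schedule.period_boundaries[2]
    spike_times = rng.uniform(t_lo, t_hi, size=config.n_spikes)
    spike_amps = rng.choice([-1, 1], config.n_spikes) * rng.uniform(
        5, 10, config.n_spikes
    ) * max(hemo.hbo2.std(), 1e-12)
    shift_times = rng.uniform(t_lo, t_hi, size=config.n_shifts)
    shift_amps = rng.choice([-1, 1], config.n_shifts) * rng.uniform(
        2, 4, config.n_shifts
    ) * max(hemo.hbo2.std(), 1e-12)
    hemo.hbo2, art_log = _stage(
        "artifacts",
        synthgen.inject_motion_artifacts,
        hemo.hbo2,
        config.fnirs_fs,
        spike_times,
        spike_amps,
        shift_times,
        shift_amps,
        spike_width_s=config.spike_width_s,
    )
    hemo.hbr, _ = synthgen.inject_motion_artifacts(
        hemo.hbr,
        config.fnirs_fs,
        spike_times,
        0.5 * spike_amps,
        shift_times,
        0.5 * shift_amps,
        spike_width_s=config.spike_width_s,
    )
    truth.artifact_log = art_log

    raw = _stage("forward_mbll", synthgen.forward_mbll, hemo, geom)
    recovered = _stage("invert_mbll", mbll.recover_hemodynamics, raw)
    cleaned, report = _stage("clean", fnirs_clean.clean_pipeline, recovered,
                             low=config.hemo_band[0], high=config.hemo_band[1],
                             order=config.hemo_filter_order)
    peaks = _stage(
        "peaks", fnirs_clean.extract_response_peaks, cleaned, schedule.period_boundaries
    )

    template = gain * synthgen.calibrate_erp_template(
        config.erp_amplitudes, fs=config.eeg_fs, band=config.erp_band,
        window=config.epoch_window,
    )
    eeg_clean = _stage(
        "eeg",
        synthgen.simulate_eeg,
        schedule,
        fs=config.eeg_fs,
        erp_templates=template,
        background_cfg=synthgen.BackgroundConfig(rms_uv=config.background_rms_uv),
        seed=seed_p,
    )
    eeg_x = _stage(
        "crosstalk",
        synthgen.inject_crosstalk,
        eeg_clean,
        config.crosstalk_hz,
        config.crosstalk_amp_uv,
    )
    truth.crosstalk_params = {
        "f_switch_hz": config.crosstalk_hz,
        "amplitude_uv": config.crosstalk_amp_uv,
    }
    truth.erp_template = {"all": template}
    acquired = _stage(
        "acquisition",
        eeg_erp.acquisition_chain,
        eeg_x,
        gain=config.gain,
        lpf_cutoff=config.lpf_cutoff_hz,
        noise_rms=config.noise_rms_uv,
        seed=seed_p,
    )
    erp = _stage(
        "erp",
        eeg_erp.erp_pipeline,
        acquired,
        window=config.epoch_window,
        band=config.erp_band,
    )

    return {
        "seed": seed_p,
        "gain": gain,
        "schedule": schedule,
        "truth": truth,
        "hemo_noisy": hemo,
        "raw_optical": raw,
        "recovered": recovered,
        "cleaned": cleaned,
        "cleaning_report": report,
        "peaks": peaks,
        "eeg": acquired,
        "erp": erp,
    }


def run_stroop_session(config: io.SessionConfig | None = None) -> StroopSessionBundle:
    """Simulate and analyze a full Stroop cohort (default: 13 participants)."""
    if config is None:
        config = io.SessionConfig()
    geom = OptodeGeometry(separation_mm=config.separation_mm, dpf=config.dpf)
    cohort_rng = np.random.default_rng(_participant_seed(config.seed, 10**6))
    gains = 1.0 + config.subject_gain_sd * cohort_rng.standard_normal(
        config.n_participants
    )

    bundle = StroopSessionBundle(config=config)
    n_ch = len(geom.channels)
    comps = list(eeg_erp.COMPONENT_WINDOWS)
    amp = {c: np.full((config.n_participants, n_ch), np.nan) for c in comps}
    first_pk = np.full((config.n_participants, n_ch), np.nan)
    second_pk = np.full((config.n_participants, n_ch), np.nan)

    for p in range(config.n_participants):
        part = _simulate_participant(config, p, float(gains[p]), geom)
        bundle.participants.append(part)
        for c in comps:
            amp[c][p] = part["erp"].components[c]
        for ch in range(n_ch):
            # HbR deflections are negative-going, so "first"/"second" peak
            # means the first/second negative extremum after task onset
            pk1 = fnirs_clean.nth_peak(part["peaks"]["hbr"][ch], 1, "negative")
            pk2 = fnirs_clean.nth_peak(part["peaks"]["hbr"][ch], 2, "negative")
            first_pk[p, ch] = np.nan if pk1 is None else pk1[1]
            second_pk[p, ch] = np.nan if pk2 is None else pk2[1]

    bundle.erp_amplitudes = amp
    bundle.hbr_first_peak = first_pk
    bundle.hbr_second_peak = second_pk

    # coupling at the left prefrontal site (channel 0), mirroring the
    # N500-vs-first-peak / P600-vs-second-peak pairings
    for comp, peaks in (("N500", first_pk), ("P600", second_pk)):
        x, y = amp[comp][:, 0], peaks[:, 0]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() >= 3 and np.ptp(x[ok]) > 0 and np.ptp(y[ok]) > 0:
            bundle.coupling_results[comp] = cpl.pearson_coupling(x[ok], y[ok])
    if config.n_participants >= 3:
        for comp in comps:
            bundle.channel_comparisons[comp] = cpl.paired_channel_comparison(
                amp[comp][:, 0], amp[comp][:, 1]
            )

    stages = {}
    for p, part in enumerate(bundle.participants):
        stages[f"participant_{p}"] = {
            "onsets": part["schedule"].trial_onsets,
            "hemo_hbo2": part["hemo_noisy"].hbo2,
            "raw_intensity": part["raw_optical"].intensity,
            "cleaned_hbo2": part["cleaned"].hbo2,
            "eeg": part["eeg"].samples,
            "erp": part["erp"].waveform,
        }
    bundle.manifest = io.build_manifest(config, stages)

    if config.out_dir:
        _persist_stroop(bundle, Path(config.out_dir))
    return bundle


def _persist_stroop(bundle: StroopSessionBundle, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for p, part in enumerate(bundle.participants):
        pdir = out / f"participant_{p:02d}"
        pdir.mkdir(exist_ok=True)
        io.write_events_tsv(part["schedule"], pdir / "events.tsv")
        io.write_optical_csv(part["raw_optical"], pdir / "optical.csv")
        io.write_hemo_csv(part["cleaned"], pdir / "hemo_cleaned.csv")
        io.write_eeg_csv(part["eeg"], pdir / "eeg.csv")
        io.write_json(part["cleaning_report"].to_dict(), pdir / "cleaning_report.json")
        erp = part["erp"]
        io.write_json(
            {
                "components": {k: list(map(float, v)) for k, v in erp.components.items()},
                "channels": list(erp.channels),
                "n_trials": erp.n_trials,
            },
            pdir / "erp.json",
        )
    io.write_json(
        {
            "coupling": {k: v.to_dict() for k, v in bundle.coupling_results.items()},
            "channel_comparisons": {
                k: v.to_dict() for k, v in bundle.channel_comparisons.items()
            },
        },
        out / "coupling.json",
    )
    io.write_json(bundle.manifest, out / "manifest.json")


@dataclass
class ForearmBundle:
    """Arterial-occlusion run: truth, optical round trip, detrended series."""

    params: synthgen.ForearmParams
    truth: object
    hemo_noisy: object
    raw_optical: object
    recovered: object
    detrended: object
    manifest: dict = field(default_factory=dict)


def run_forearm_block(
    params: synthgen.ForearmParams | None = None,
    fs: float = 100.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    out_dir=None,
) -> ForearmBundle:
    """Occlusion scenario -> forward MBLL -> inversion -> detrend."""
    if params is None:
        params = synthgen.ForearmParams()
    hemo, truth = _stage(
        "forearm_sim", synthgen.simulate_forearm_block, params, fs, noise_sd, seed
    )
    geom = OptodeGeometry(channels=tuple(hemo.channels))
    raw = _stage("forward_mbll", synthgen.forward_mbll, hemo, geom)
    recovered = _stage("invert_mbll", mbll.recover_hemodynamics, raw)
    det_hbo2, _ = fnirs_clean.detrend_poly1(recovered.hbo2)
    det_hbr, _ = fnirs_clean.detrend_poly1(recovered.hbr)
    detrended = type(recovered)(det_hbo2, det_hbr, fs, tuple(recovered.channels))

    cfg = io.SessionConfig(seed=seed)
    manifest = io.build_manifest(
        cfg,
        {
            "forearm": {
                "truth_hbo2": truth.hbo2_true,
                "recovered_hbo2": recovered.hbo2,
                "detrended_hbo2": detrended.hbo2,
            }
        },
    )
    bundle = ForearmBundle(
        params=params,
        truth=truth,
        hemo_noisy=hemo,
        raw_optical=raw,
        recovered=recovered,
        detrended=detrended,
        manifest=manifest,
    )
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_optical_csv(raw, out / "optical.csv")
        io.write_hemo_csv(recovered, out / "hemo_recovered.csv")
        io.write_hemo_csv(detrended, out / "hemo_detrended.csv")
        io.write_json(manifest, out / "manifest.json")
    return bundle
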