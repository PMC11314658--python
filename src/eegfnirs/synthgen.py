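"""Synthetic dual-modal acquisition: every input the analysis chain needs.

This module emulates a co-located EEG-fNIRS recording session at the level
of the signals themselves (no photon-transport or circuit modeling):

* Stroop task schedules (30 trials, 500 ms display, 350-750 ms ISI,
  one third congruent) inside a waiting / task / rest block layout;
* hemodynamic responses as a stimulus train convolved with a canonical
  double-gamma HRF, contaminated with respiration (~0.25 Hz), cardiac
  (~1 Hz) and Mayer-wave (~0.1 Hz) oscillations, linear drift and white
  noise;
* raw dual-wavelength optical intensities through the forward modified
  Beer-Lambert law;
* spike and baseline-shift motion artifacts, logged for recovery scoring;
* EEG with 1/f background, optional alpha and 50 Hz mains, and embedded
  ERP templates;
* LED-switching crosstalk as a zero-mean rectangular pulse train;
* a forearm arterial-occlusion scenario with a closed-form recovery curve.

Every random draw flows from one ``numpy.random.default_rng(seed)`` per
call; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .containers import (
    DEFAULT_CHANNELS,
    ArtifactEvent,
    EEGRecording,
    EventSchedule,
    ExtinctionTable,
    GroundTruth,
    HemodynamicSeries,
    OptodeGeometry,
    RawOpticalRecording,
)
from .errors import AliasingError, InvalidParameterError
from .mbll import DEFAULT_EXTINCTION, _UM_TO_MM, extinction_matrix

# ---------------------------------------------------------------------------
# Task schedule
# ---------------------------------------------------------------------------


def make_stroop_schedule(
    n_trials: int = 30,
    congruent_fraction: float = 1.0 / 3.0,
    display_s: float = 0.5,
    isi_low_s: float = 0.35,
    isi_high_s: float = 0.75,
    seed: int = 0,
    *,
    wait_s: float = 30.0,
    rest_s: float = 60.0,
) -> EventSchedule:
    """Build a color-word Stroop trial schedule.

    Trials start after a waiting period of ``wait_s``; each trial shows the
    stimulus for ``display_s`` and is followed by an inter-stimulus
    interval drawn uniformly from ``[isi_low_s, isi_high_s]``.  The number
    of congruent trials is ``n_trials * congruent_fraction`` rounded
    toward congruent (i.e. up), and the condition order is a uniformly
    random permutation under ``seed``.
    """
    if n_trials < 0:
        raise InvalidParameterError("n_trials must be >= 0")
    if not 0.0 <= congruent_fraction <= 1.0:
        raise InvalidParameterError("congruent_fraction must be in [0, 1]")
    if min(display_s, isi_low_s, isi_high_s, wait_s, rest_s) < 0:
        raise InvalidParameterError("durations must be non-negative")
    if isi_low_s > isi_high_s:
        raise InvalidParameterError("isi_low_s must be <= isi_high_s")

    rng = np.random.default_rng(seed)
    n_congruent = min(n_trials, int(math.ceil(congruent_fraction * n_trials - 1e-9)))
    conditions = np.array(
        ["congruent"] * n_congruent + ["incongruent"] * (n_trials - n_congruent),
        dtype=object,
    )
    conditions = conditions[rng.permutation(n_trials)]

    isis = rng.uniform(isi_low_s, isi_high_s, size=max(n_trials - 1, 0))
    onsets = wait_s + np.concatenate([[0.0], np.cumsum(display_s + isis)])[:n_trials]

    task_end = wait_s if n_trials == 0 else float(onsets[-1] + display_s)
    boundaries = (0.0, wait_s, task_end, task_end + rest_s)
    return EventSchedule(
        trial_onsets=onsets,
        conditions=conditions,
        display_s=display_s,
        isi_bounds=(isi_low_s, isi_high_s),
        period_boundaries=boundaries,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Hemodynamics
# ---------------------------------------------------------------------------


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function.

    Response peak at 6 s, undershoot at 16 s, undershoot ratio 1/6,
    normalized to unit peak.
    """
    t = np.asarray(t, dtype=float)
    h = spstats.gamma.pdf(t, 6.0) - spstats.gamma.pdf(t, 16.0) / 6.0
    peak = h.max()
    return h / peak if peak > 0 else h


@dataclass
class NoiseConfig:
    """Physiological-noise settings for the hemodynamic simulator.

    Amplitudes are sinusoid peak amplitudes in uM; ``drift_um`` bounds the
    random linear drift accumulated over the whole session; ``white_sd``
    is the white-noise standard deviation in uM.
    """

    mayer_hz: float = 0.1
    mayer_amp: float = 0.1
    resp_hz: float = 0.25
    resp_amp: float = 0.1
    cardiac_hz: float = 1.0
    cardiac_amp: float = 0.15
    drift_um: float = 0.5
    white_sd: float = 0.03

    def components(self):
        return (
            (self.mayer_hz, self.mayer_amp),
            (self.resp_hz, self.resp_amp),
            (self.cardiac_hz, self.cardiac_amp),
        )


def _activation(schedule: EventSchedule, n: int, fs: float) -> np.ndarray:
    """Unit-peak neural activation: boxcar stimulus train (*) double-gamma HRF."""
    stim = np.zeros(n)
    for onset in schedule.trial_onsets:
        i0 = int(round(onset * fs))
        i1 = min(int(round((onset + schedule.display_s) * fs)), n)
        stim[i0:i1] = 1.0
    hrf = double_gamma_hrf(np.arange(0.0, 32.0, 1.0 / fs))
    act = sps.fftconvolve(stim, hrf)[:n] / fs
    peak = np.max(np.abs(act))
    return act / peak if peak > 0 else act


def simulate_hemodynamics(
    schedule: EventSchedule,
    fs: float = 100.0,
    amp_hbo2: float = 1.0,
    amp_hbr: float | None = None,
    noise_cfg: NoiseConfig | None = None,
    seed: int = 0,
    channels: tuple = DEFAULT_CHANNELS,
) -> tuple[HemodynamicSeries, GroundTruth]:
    """Simulate task-evoked dHbO2/dHbR with physiological noise.

    The noise-free activation (common to all channels) is retained in the
    returned :class:`GroundTruth`.  ``amp_hbr`` defaults to
    ``-0.25 * amp_hbo2``: the deoxygenated change is conventionally
    opposite in sign and smaller in magnitude.
    """
    if fs <= 0:
        raise InvalidParameterError("fs must be > 0")
    if amp_hbr is None:
        amp_hbr = -0.25 * amp_hbo2
    if noise_cfg is None:
        noise_cfg = NoiseConfig()

    rng = np.random.default_rng(seed)
    duration = schedule.session_duration
    n = max(int(round(duration * fs)), 1)
    t = np.arange(n) / fs

    act = _activation(schedule, n, fs)
    hbo2_true = np.tile(amp_hbo2 * act, (len(channels), 1))
    hbr_true = np.tile(amp_hbr * act, (len(channels), 1))

    def noise_block() -> np.ndarray:
        out = np.zeros((len(channels), n))
        for ch in range(len(channels)):
            for f, a in noise_cfg.components():
                phase = rng.uniform(0.0, 2.0 * np.pi)
                out[ch] += a * np.sin(2.0 * np.pi * f * t + phase)
            slope = noise_cfg.drift_um * rng.uniform(-1.0, 1.0) / max(duration, 1e-12)
            out[ch] += slope * t
            out[ch] += noise_cfg.white_sd * rng.standard_normal(n)
        return out

    hemo = HemodynamicSeries(
        hbo2=hbo2_true + noise_block(),
        hbr=hbr_true + 0.5 * noise_block(),
        fs=fs,
        channels=tuple(channels),
    )
    truth = GroundTruth(
        hbo2_true=hbo2_true, hbr_true=hbr_true, fs=fs, channels=tuple(channels)
    )
    return hemo, truth


# ---------------------------------------------------------------------------
# Forward MBLL
# ---------------------------------------------------------------------------


def forward_mbll(
    hemo: HemodynamicSeries,
    geom: OptodeGeometry | None = None,
    coeffs: ExtinctionTable = DEFAULT_EXTINCTION,
    i0: tuple = (1.0, 1.0),
    baseline_window: tuple = (0.0, 10.0),
) -> RawOpticalRecording:
    """Map concentration changes to raw dual-wavelength intensities.

    I(lambda, t) = i0(lambda) * 10**(-dOD(lambda, t)) with
    dOD = [eps_HbO2 * dHbO2 + eps_HbR * dHbR] * d * DPF (concentrations
    converted uM -> mM to match the extinction units).
    """
    if geom is None:
        geom = OptodeGeometry(channels=tuple(hemo.channels))
    i0 = np.asarray(i0, dtype=float)
    if np.any(i0 <= 0):
        raise InvalidParameterError("baseline intensities i0 must be > 0")
    E = extinction_matrix(coeffs, geom.wavelengths_nm)
    conc_mm = np.stack([hemo.hbo2, hemo.hbr], axis=1) * _UM_TO_MM  # (n_ch, 2, n_t)
    od = np.einsum("lc,ncr->nlr", E, conc_mm) * geom.pathlengths_mm[None, :, None]
    intensity = i0[None, :, None] * 10.0 ** (-od)
    return RawOpticalRecording(
        intensity=intensity, fs=hemo.fs, geometry=geom, baseline_window=baseline_window
    )


# ---------------------------------------------------------------------------
# Motion artifacts
# ---------------------------------------------------------------------------


def inject_motion_artifacts(
    series: np.ndarray,
    fs: float,
    spike_times=(),
    spike_amps=(),
    shift_times=(),
    shift_amps=(),
    spike_width_s: float = 0.3,
    seed: int | None = None,
) -> tuple[np.ndarray, list]:
    """Add spike and baseline-shift artifacts to ``series`` (any channel layout).

    Spikes are Gaussian transients (``spike_width_s`` is the full width at
    half maximum); shifts are steps persisting to the end of the record.
    If an amplitude list is empty while the matching time list is not, the
    amplitudes are drawn from ``seed`` as N(0, 1)-scaled multiples of the
    series' standard deviation.  Returns the modified copy and a log of
    :class:`~eegfnirs.containers.ArtifactEvent` for recovery scoring.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float)).copy()
    n = series.shape[-1]
    duration = n / fs
    spike_times = np.asarray(spike_times, dtype=float)
    shift_times = np.asarray(shift_times, dtype=float)
    for tval in np.concatenate([spike_times, shift_times]):
        if not (0.0 <= tval <= duration):
            raise InvalidParameterError(
                f"artifact time {tval} s outside record [0, {duration:.3f}] s"
            )

    rng = np.random.default_rng(seed)
    scale = series.std() if series.std() > 0 else 1.0
    spike_amps = np.asarray(spike_amps, dtype=float)
    if spike_times.size and not spike_amps.size:
        spike_amps = rng.standard_normal(spike_times.size) * 5.0 * scale
    shift_amps = np.asarray(shift_amps, dtype=float)
    if shift_times.size and not shift_amps.size:
        shift_amps = rng.standard_normal(shift_times.size) * 3.0 * scale

    t = np.arange(n) / fs
    log: list[ArtifactEvent] = []
    sigma = spike_width_s / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    for tc, a in zip(spike_times, spike_amps):
        series += a * np.exp(-0.5 * ((t - tc) / sigma) ** 2)[None, :]
        log.append(ArtifactEvent("spike", float(tc), float(a), spike_width_s))
    for tc, a in zip(shift_times, shift_amps):
        series[:, t >= tc] += a
        log.append(ArtifactEvent("shift", float(tc), float(a)))
    return series, log


# ---------------------------------------------------------------------------
# EEG background, ERP templates, crosstalk
# ---------------------------------------------------------------------------


@dataclass
class BackgroundConfig:
    """Spontaneous-EEG background model.

    ``rms_uv`` sets the RMS of the 1/f^exponent-shaped noise; optional
    alpha-band and 50 Hz mains sinusoids are added on top with the given
    peak amplitudes.
    """

    rms_uv: float = 10.0
    exponent: float = 1.0
    alpha_amp_uv: float = 0.0
    alpha_hz: float = 10.0
    mains_amp_uv: float = 0.0
    mains_hz: float = 50.0


def _one_over_f(n: int, fs: float, exponent: float, rms: float, rng) -> np.ndarray:
    white = rng.standard_normal(n)
    if rms == 0:
        return np.zeros(n)
    if exponent == 0:
        return rms * white
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    return rms * x / x.std()


# default ERP component window means, uV (signed; all three components of
# the Stroop response at the prefrontal sites are negative-going)
DEFAULT_ERP_AMPLITUDES = {"P450": -2.7, "N500": -4.0, "P600": -2.0}


def make_erp_template(
    amplitudes: dict | None = None,
    fs: float = 1000.0,
    duration_s: float = 0.75,
) -> np.ndarray:
    """Raised-cosine bump template with prescribed component window means.

    One Hann bump spans each component window (P450 0.400-0.450 s, N500
    0.450-0.550 s, P600 0.600-0.700 s after onset), scaled so the mean of
    the raw template over the window equals the requested amplitude.
    """
    from .eeg_erp import COMPONENT_WINDOWS

    if amplitudes is None:
        amplitudes = DEFAULT_ERP_AMPLITUDES
    n = int(round(duration_s * fs))
    template = np.zeros(n)
    for name, amp in amplitudes.items():
        lo, hi = COMPONENT_WINDOWS[name]
        i0, i1 = int(round(lo * fs)), min(int(round(hi * fs)), n)
        m = i1 - i0
        if m <= 0:
            raise InvalidParameterError(f"component {name} outside the template span")
        bump = np.hanning(m)
        template[i0:i1] += amp * bump / bump.mean()
    return template


def calibrate_erp_template(
    targets: dict | None = None,
    fs: float = 1000.0,
    band: tuple = (0.8, 17.0),
    duration_s: float = 0.75,
    window: tuple = (-0.250, 0.750),
) -> np.ndarray:
    """Template whose *measured* component amplitudes equal ``targets``.

    The ERP measurement chain (epoch, baseline-correct, average, zero-phase
    band-pass, window mean) is linear, so a template built from one basis
    bump per component can be solved exactly against it: the 3x3 matrix of
    measured amplitudes of the basis bumps is inverted to find the bump
    coefficients.  Noise-free recovery through the full chain is then exact
    and noisy recovery converges to the targets as trials accumulate.
    """
    from .eeg_erp import COMPONENT_WINDOWS, _measure_template

    if targets is None:
        targets = DEFAULT_ERP_AMPLITUDES
    names = list(COMPONENT_WINDOWS)
    basis = [make_erp_template({nm: 1.0}, fs=fs, duration_s=duration_s) for nm in names]
    M = np.array(
        [[_measure_template(b, fs, band, window)[nm] for b in basis] for nm in names]
    )
    coef = np.linalg.solve(M, np.array([targets[nm] for nm in names]))
    return np.sum([c * b for c, b in zip(coef, basis)], axis=0)


def simulate_eeg(
    schedule: EventSchedule,
    fs: float = 1000.0,
    erp_templates: dict | np.ndarray | None = None,
    background_cfg: BackgroundConfig | None = None,
    seed: int = 0,
    channels: tuple = DEFAULT_CHANNELS,
    pad_s: float = 1.0,
) -> EEGRecording:
    """Synthesize prefrontal EEG with stimulus-locked ERP templates.

    ``erp_templates`` is either one waveform used for every trial or a
    ``{condition: waveform}`` mapping (uV, sampled at ``fs``, starting at
    stimulus onset).  Background noise is independent per channel; the
    template is added identically to all channels.
    """
    if fs <= 0:
        raise InvalidParameterError("fs must be > 0")
    if background_cfg is None:
        background_cfg = BackgroundConfig()
    if erp_templates is None:
        erp_templates = make_erp_template(fs=fs)
    if isinstance(erp_templates, np.ndarray):
        erp_templates = {None: erp_templates}

    rng = np.random.default_rng(seed)
    duration = schedule.session_duration + pad_s
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    samples = np.zeros((len(channels), n))
    for ch in range(len(channels)):
        samples[ch] = _one_over_f(
            n, fs, background_cfg.exponent, background_cfg.rms_uv, rng
        )
        if background_cfg.alpha_amp_uv:
            samples[ch] += background_cfg.alpha_amp_uv * np.sin(
                2 * np.pi * background_cfg.alpha_hz * t + rng.uniform(0, 2 * np.pi)
            )
        if background_cfg.mains_amp_uv:
            samples[ch] += background_cfg.mains_amp_uv * np.sin(
                2 * np.pi * background_cfg.mains_hz * t + rng.uniform(0, 2 * np.pi)
            )

    max_len = max((len(v) for v in erp_templates.values()), default=0)
    if schedule.n_trials > 1:
        min_gap = float(np.min(schedule.gaps))
        if max_len / fs > min_gap:
            warnings.warn(
                "ERP template longer than the shortest inter-trial gap; "
                "consecutive responses overlap",
                stacklevel=2,
            )

    events = []
    for onset, cond in zip(schedule.trial_onsets, schedule.conditions):
        tpl = erp_templates.get(cond, erp_templates.get(None))
        if tpl is None:
            tpl = next(iter(erp_templates.values()))
        i0 = int(round(onset * fs))
        i1 = min(i0 + len(tpl), n)
        samples[:, i0:i1] += tpl[: i1 - i0][None, :]
        events.append((float(onset), str(cond)))

    return EEGRecording(samples=samples, fs=fs, channels=tuple(channels), events=events)


def inject_crosstalk(
    eeg: EEGRecording, f_switch: float = 125.0, amplitude: float = 10.0
) -> EEGRecording:
    """Add LED-switching crosstalk: a zero-mean rectangular pulse train.

    Models capacitive coupling of the time-division-multiplexed LED drive
    current into the EEG channel.  The coupling is AC (DC removed), so the
    train is forced to zero mean; ``amplitude`` is the peak value in uV.
    """
    if f_switch <= 0:
        raise InvalidParameterError("f_switch must be > 0")
    if f_switch >= eeg.fs / 2:
        raise AliasingError(
            f"switching frequency {f_switch} Hz at or above Nyquist ({eeg.fs / 2} Hz)"
        )
    out = eeg.copy()
    if amplitude == 0:
        return out
    # phase accumulated as k*f mod fs (one rounding) so that switching
    # instants commensurate with the sample grid stay exactly periodic
    k = np.arange(out.samples.shape[-1], dtype=float)
    frac = (k * float(f_switch)) % float(eeg.fs) / float(eeg.fs)
    wave = np.where(frac < 0.5, amplitude, -amplitude)
    wave = wave - wave.mean()
    out.samples += wave[None, :]
    return out


# ---------------------------------------------------------------------------
# Forearm arterial-occlusion scenario
# ---------------------------------------------------------------------------


@dataclass
class ForearmParams:
    """Piecewise occlusion model parameters (uM, seconds).

    During cuff occlusion dHbO2 falls linearly at ``hbo2_slope`` (< 0)
    while dHbR rises at ``hbr_slope`` (> 0).  After release both rebound
    as a fast/slow double exponential that overshoots the baseline by
    ``overshoot_*`` and decays back with ``tau_slow``.
    """

    baseline_s: float = 60.0
    occlusion_s: float = 60.0
    release_s: float = 120.0
    hbo2_slope: float = -0.020
    hbr_slope: float = 0.008
    overshoot_hbo2: float = 0.4
    overshoot_hbr: float = -0.15
    tau_fast: float = 2.0
    tau_slow: float = 12.0

    @property
    def durations(self) -> tuple:
        return (self.baseline_s, self.occlusion_s, self.release_s)


def forearm_closed_form(t: np.ndarray, params: ForearmParams) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (dHbO2, dHbR) of the occlusion model at times ``t``."""
    t = np.asarray(t, dtype=float)
    t1 = params.baseline_s
    t2 = t1 + params.occlusion_s

    def branch(slope: float, overshoot: float) -> np.ndarray:
        depth = slope * params.occlusion_s  # value at end of occlusion
        x = np.zeros_like(t)
        occ = (t >= t1) & (t < t2)
        x[occ] = slope * (t[occ] - t1)
        rel = t >= t2
        u = t[rel] - t2
        x[rel] = (depth - overshoot) * np.exp(-u / params.tau_fast) + overshoot * np.exp(
            -u / params.tau_slow
        )
        return x

    return (
        branch(params.hbo2_slope, params.overshoot_hbo2),
        branch(params.hbr_slope, params.overshoot_hbr),
    )


def simulate_forearm_block(
    params: ForearmParams | None = None,
    fs: float = 100.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    channels: tuple = ("forearm",),
) -> tuple[HemodynamicSeries, GroundTruth]:
    """Simulate the cuff-occlusion hemodynamics (plus white measurement noise)."""
    if params is None:
        params = ForearmParams()
    if min(params.durations) <= 0:
        raise InvalidParameterError("all segment durations must be > 0")
    if fs <= 0:
        raise InvalidParameterError("fs must be > 0")

    rng = np.random.default_rng(seed)
    n = int(round(sum(params.durations) * fs))
    t = np.arange(n) / fs
    hbo2, hbr = forearm_closed_form(t, params)
    hbo2_true = np.tile(hbo2, (len(channels), 1))
    hbr_true = np.tile(hbr, (len(channels), 1))
    hemo = HemodynamicSeries(
        hbo2=hbo2_true + noise_sd * rng.standard_normal(hbo2_true.shape),
        hbr=hbr_true + noise_sd * rng.standard_normal(hbr_true.shape),
        fs=fs,
        channels=tuple(channels),
    )
    truth = GroundTruth(
        hbo2_true=hbo2_true, hbr_true=hbr_true, fs=fs, channels=tuple(channels)
    )
    return hemo, truth
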