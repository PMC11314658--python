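"""EEG acquisition-chain model and ERP component analysis.

The acquisition chain mirrors a pre-amplified dry-electrode front end:
an active 50 Hz low-pass filter, a x1000 voltage gain, and additive
input-referred noise; the output is referred back to input units so the
rest of the analysis stays in microvolts.

The ERP analysis epochs the recording from -250 ms to +750 ms around each
stimulus onset, baseline-corrects on the pre-stimulus interval, averages
across trials, band-passes the average at 0.8-17 Hz (zero phase), and
measures three components as signed window means:

======  ==============  =================================
name    window (s)      conventional description
======  ==============  =================================
P450    0.400 - 0.450   positive component, 400-450 ms
N500    0.450 - 0.550   negative component, 450-550 ms
P600    0.600 - 0.700   positive component, 600-700 ms
======  ==============  =================================

The window mean is reported signed, without forcing the conventional
polarity (prefrontal Stroop responses can show all three components
negative-going).
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .containers import EEGRecording, EpochSet, ErpResult
from .errors import EmptyEpochsError, InvalidParameterError

#: component latency windows in seconds relative to stimulus onset
COMPONENT_WINDOWS = {
    "P450": (0.400, 0.450),
    "N500": (0.450, 0.550),
    "P600": (0.600, 0.700),
}

EPOCH_WINDOW = (-0.250, 0.750)
BASELINE_WINDOW = (-0.250, 0.0)
ERP_BAND = (0.8, 17.0)


def acquisition_chain(
    eeg_in: EEGRecording,
    gain: float = 1000.0,
    lpf_cutoff: float = 50.0,
    noise_rms: float = 0.0,
    seed: int | None = None,
    lpf_order: int = 2,
) -> EEGRecording:
    """Model the analog front end: 50 Hz LPF, x1000 gain, input noise.

    The low-pass is a causal second-order Butterworth (one active op-amp
    stage).  Output = (LPF(x) * gain + gain * noise) / gain, i.e. the
    record is referred back to input microvolts and the additive noise
    appears at its input-referred RMS.
    """
    if gain <= 0:
        raise InvalidParameterError("gain must be > 0")
    if not 0 < lpf_cutoff < eeg_in.fs / 2:
        raise InvalidParameterError(
            f"LPF cutoff {lpf_cutoff} Hz must be below Nyquist ({eeg_in.fs / 2} Hz)"
        )
    sos = sps.butter(lpf_order, lpf_cutoff, btype="lowpass", fs=eeg_in.fs, output="sos")
    filtered = sps.sosfilt(sos, eeg_in.samples, axis=-1)
    if noise_rms > 0:
        rng = np.random.default_rng(seed)
        filtered = filtered + noise_rms * rng.standard_normal(filtered.shape)
    return EEGRecording(
        samples=filtered,
        fs=eeg_in.fs,
        channels=tuple(eeg_in.channels),
        events=list(eeg_in.events),
    )


def epoch(
    eeg: EEGRecording,
    markers: list | None = None,
    window: tuple = EPOCH_WINDOW,
    baseline: tuple = BASELINE_WINDOW,
) -> EpochSet:
    """Cut stimulus-locked epochs; out-of-bounds trials are dropped and counted."""
    if markers is None:
        markers = eeg.events
    if window[0] >= window[1]:
        raise InvalidParameterError("epoch window must have positive length")
    n_samples = int(round((window[1] - window[0]) * eeg.fs))
    n_total = eeg.samples.shape[-1]

    epochs, conditions, dropped = [], [], 0
    for t, cond in markers:
        start = int(round((t + window[0]) * eeg.fs))
        stop = start + n_samples
        if start < 0 or stop > n_total:
            dropped += 1
            continue
        epochs.append(eeg.samples[:, start:stop])
        conditions.append(cond)
    if not epochs:
        raise EmptyEpochsError("no marker has its full epoch window inside the record")
    return EpochSet(
        epochs=np.stack(epochs),
        fs=eeg.fs,
        window=window,
        baseline=baseline,
        channels=tuple(eeg.channels),
        conditions=np.asarray(conditions, dtype=object),
        n_dropped=dropped,
    )


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the per-trial, per-channel mean of the baseline window."""
    times = epochs.times
    sel = (times >= epochs.baseline[0]) & (times < epochs.baseline[1])
    if not np.any(sel):
        raise InvalidParameterError("baseline window selects no samples")
    corrected = epochs.epochs - epochs.epochs[:, :, sel].mean(axis=-1, keepdims=True)
    return EpochSet(
        epochs=corrected,
        fs=epochs.fs,
        window=epochs.window,
        baseline=epochs.baseline,
        channels=tuple(epochs.channels),
        conditions=epochs.conditions,
        n_dropped=epochs.n_dropped,
    )


def _erp_filter(waveform: np.ndarray, fs: float, band: tuple, order: int = 4) -> np.ndarray:
    if not 0 < band[0] < band[1] < fs / 2:
        raise InvalidParameterError(f"ERP band {band} Hz invalid for fs = {fs} Hz")
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    # the waveform (one epoch) is short relative to the high-pass time
    # constant; full-length even-reflection padding keeps zero-phase edge
    # transients out of the component windows (out-of-band residue from
    # e.g. LED-switching crosstalk would otherwise leak into the epoch)
    padlen = max(waveform.shape[-1] - 1, 0)
    return sps.sosfiltfilt(sos, waveform, axis=-1, padtype="even", padlen=padlen)


def average_erp(
    epochs: EpochSet, band: tuple = ERP_BAND, order: int = 4
) -> ErpResult:
    """Average across trials, then band-pass the average (zero phase).

    The averaged waveform is filtered at 0.8-17 Hz (4th-order Butterworth,
    forward-backward); component amplitudes are window means of the
    filtered average.
    """
    if epochs.n_trials < 1:
        raise EmptyEpochsError("cannot average an empty epoch set")
    mean_wave = epochs.epochs.mean(axis=0)
    filtered = _erp_filter(mean_wave, epochs.fs, band, order)
    erp = ErpResult(
        waveform=filtered,
        fs=epochs.fs,
        window=epochs.window,
        channels=tuple(epochs.channels),
        component_windows=dict(COMPONENT_WINDOWS),
        n_trials=epochs.n_trials,
    )
    erp.components = {
        name: component_amplitude(erp, name) for name in COMPONENT_WINDOWS
    }
    return erp


def component_amplitude(erp: ErpResult, component: str) -> np.ndarray:
    """Signed mean amplitude (uV per channel) over the component window."""
    if component not in COMPONENT_WINDOWS:
        raise InvalidParameterError(
            f"unknown component '{component}'; expected one of {list(COMPONENT_WINDOWS)}"
        )
    lo, hi = COMPONENT_WINDOWS[component]
    if not (erp.window[0] <= lo and hi <= erp.window[1]):
        raise InvalidParameterError(
            f"ERP window {erp.window} does not cover component window ({lo}, {hi})"
        )
    i0 = int(round((lo - erp.window[0]) * erp.fs))
    i1 = int(round((hi - erp.window[0]) * erp.fs))
    return erp.waveform[:, i0:i1].mean(axis=-1)


def erp_pipeline(
    eeg: EEGRecording,
    window: tuple = EPOCH_WINDOW,
    baseline: tuple = BASELINE_WINDOW,
    band: tuple = ERP_BAND,
) -> ErpResult:
    """Epoch -> baseline-correct -> average -> filter -> components."""
    return average_erp(baseline_correct(epoch(eeg, window=window, baseline=baseline)), band)


def _measure_template(
    template: np.ndarray, fs: float, band: tuple, window: tuple = EPOCH_WINDOW
) -> dict:
    """Component amplitudes of a single noise-free template through the chain.

    Used to calibrate synthetic templates against the (linear) measurement
    chain; the template is placed at onset inside an otherwise zero epoch.
    """
    n = int(round((window[1] - window[0]) * fs))
    wave = np.zeros((1, n))
    i0 = int(round(-window[0] * fs))
    i1 = min(i0 + len(template), n)
    wave[0, i0:i1] = template[: i1 - i0]
    eset = EpochSet(epochs=wave[None, :, :], fs=fs, window=window, channels=("x",))
    erp = average_erp(baseline_correct(eset), band)
    return {name: float(erp.components[name][0]) for name in COMPONENT_WINDOWS}
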