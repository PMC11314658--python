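"""Signal-quality metrics: noise, distortion, and crosstalk separation.

These realize the standard bench procedures on simulated recordings:
input-referred noise of a zero-input chain, amplitude distortion against
a known test sinusoid, frequency distortion from an interpolated spectral
peak, and the crosstalk residual that quantifies how much of the LED
switching waveform survives the EEG band after the 50 Hz low-pass.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .containers import EEGRecording
from .errors import DegenerateInputError, InvalidParameterError
from .eeg_erp import acquisition_chain


def input_referred_noise(chain_output: EEGRecording, min_duration_s: float = 10.0) -> float:
    """RMS of the mean-removed output of a zero-input chain, in uV.

    The chain output is already referred to input units, so this is the
    input-referred noise directly.
    """
    if chain_output.duration < min_duration_s:
        raise InvalidParameterError(
            f"record of {chain_output.duration:.1f} s too short; "
            f"need >= {min_duration_s} s for a stable noise estimate"
        )
    x = chain_output.samples
    return float(np.sqrt(np.mean((x - x.mean(axis=-1, keepdims=True)) ** 2)))


def _fit_sinusoid_amplitude(x: np.ndarray, t: np.ndarray, freq: float) -> float:
    """Least-squares amplitude of a sinusoid at a known frequency."""
    design = np.column_stack(
        [np.sin(2 * np.pi * freq * t), np.cos(2 * np.pi * freq * t)]
    )
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return float(np.hypot(coef[0], coef[1]))


def amplitude_distortion(
    chain=None,
    test_freq: float = 10.0,
    test_amp: float = 100.0,
    fs: float = 1000.0,
    duration_s: float = 10.0,
    settle_s: float = 1.0,
    passband_hz: float = 50.0,
) -> float:
    """Percent amplitude error of a test sinusoid through the chain.

    ``chain`` maps an :class:`EEGRecording` to an :class:`EEGRecording`
    (default: the noise-free acquisition chain).  The output amplitude is
    estimated by least-squares fit at the known frequency over the
    post-settle portion, matching bench practice against a signal
    generator.
    """
    if chain is None:
        chain = acquisition_chain
    if test_freq >= passband_hz:
        warnings.warn(
            f"test frequency {test_freq} Hz is outside the {passband_hz} Hz passband",
            stacklevel=2,
        )
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    rec = EEGRecording(test_amp * np.sin(2 * np.pi * test_freq * t), fs=fs, channels=("test",))
    out = chain(rec)
    sel = t >= settle_s
    a_meas = _fit_sinusoid_amplitude(out.samples[0, sel], t[sel], test_freq)
    return 100.0 * abs(a_meas - test_amp) / test_amp


def _interpolated_peak_hz(x: np.ndarray, fs: float) -> float:
    """Spectral peak frequency by quadratic interpolation on log magnitude."""
    win = np.hanning(len(x))
    spec = np.abs(np.fft.rfft(x * win))
    k = int(np.argmax(spec))
    if spec[k] == 0:
        raise DegenerateInputError("signal has no spectral peak")
    if 0 < k < len(spec) - 1 and spec[k - 1] > 0 and spec[k + 1] > 0:
        a, b, c = np.log(spec[k - 1]), np.log(spec[k]), np.log(spec[k + 1])
        denom = a - 2 * b + c
        delta = 0.5 * (a - c) / denom if denom != 0 else 0.0
    else:
        delta = 0.0
    return (k + delta) * fs / len(x)


def frequency_distortion(
    chain=None,
    test_freq: float = 10.0,
    fs: float = 1000.0,
    duration_s: float = 100.0,
    resolution_frac: float = 1e-3,
) -> float:
    """Percent frequency error of a test tone through the chain.

    The record must be long enough that the raw spectral resolution is at
    most ``resolution_frac`` of the test frequency (quadratic peak
    interpolation then resolves far below one bin).
    """
    if chain is None:
        chain = acquisition_chain
    if test_freq <= 0:
        raise InvalidParameterError("test_freq must be > 0")
    n = int(round(duration_s * fs))
    if fs / n > resolution_frac * test_freq:
        raise InvalidParameterError(
            f"duration {duration_s} s gives spectral resolution {fs / n:.4g} Hz, "
            f"coarser than {resolution_frac:.0%} of {test_freq} Hz"
        )
    t = np.arange(n) / fs
    rec = EEGRecording(np.sin(2 * np.pi * test_freq * t), fs=fs, channels=("test",))
    out = chain(rec)
    if np.allclose(out.samples, 0.0):
        raise DegenerateInputError("chain output is identically zero")
    f_meas = _interpolated_peak_hz(out.samples[0], fs)
    return 100.0 * abs(f_meas - test_freq) / test_freq


def _bandlimit(x: np.ndarray, fs: float, band: tuple, order: int = 8) -> np.ndarray:
    """Confine ``x`` to ``band`` with zero-phase high-order Butterworth edges."""
    out = np.asarray(x, dtype=float)
    lo, hi = band
    if hi < fs / 2:
        sos = sps.butter(order, hi, btype="lowpass", fs=fs, output="sos")
        out = sps.sosfiltfilt(sos, out, axis=-1)
    if lo > 0:
        sos = sps.butter(order, lo, btype="highpass", fs=fs, output="sos")
        out = sps.sosfiltfilt(sos, out, axis=-1)
    return out


def crosstalk_residual(
    eeg_clean: EEGRecording,
    eeg_xtalk: EEGRecording,
    band: tuple = (0.0, 50.0),
    chain=None,
) -> tuple[float, float]:
    """In-band residual of injected crosstalk after the acquisition chain.

    ``eeg_xtalk`` must be ``eeg_clean`` plus a known crosstalk waveform;
    both are passed through ``chain`` (default: noise-free acquisition
    chain) and the difference, restricted to ``band``, is compared with
    the injected crosstalk before the chain::

        residual_ratio = 100 * RMS(in-band difference) / RMS(injected)
        rejection_db   = -20 * log10(residual_ratio / 100)
    """
    if eeg_clean.samples.shape != eeg_xtalk.samples.shape or eeg_clean.fs != eeg_xtalk.fs:
        raise InvalidParameterError("records must share shape and sampling rate")
    injected = eeg_xtalk.samples - eeg_clean.samples
    rms_injected = float(np.sqrt(np.mean(injected**2)))
    if rms_injected == 0:
        raise DegenerateInputError("no crosstalk was injected; residual undefined")
    if chain is None:
        chain = acquisition_chain
    diff_after = chain(eeg_xtalk).samples - chain(eeg_clean).samples
    inband = _bandlimit(diff_after, eeg_clean.fs, band)
    ratio = 100.0 * float(np.sqrt(np.mean(inband**2))) / rms_injected
    rejection = float("inf") if ratio == 0 else -20.0 * np.log10(ratio / 100.0)
    return ratio, rejection
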