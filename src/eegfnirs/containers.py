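"""In-memory containers shared across the simulation and analysis stages.

All time axes are seconds with t = 0 at session start.  Concentration
changes are micromolar (uM), EEG is microvolts (uV), optical intensities
are arbitrary detector units (positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

#: left / right prefrontal electrode labels of the 10-20 system
DEFAULT_CHANNELS = ("Fp1", "Fp2")


@dataclass
class OptodeGeometry:
    """Source-detector geometry for a set of fNIRS channels.

    Parameters
    ----------
    channels : tuple of str
        Channel identifiers (one per source-detector pair).
    separation_mm : float
        Source-detector separation in millimetres (default 30 mm, the
        standard adult-forehead spacing).
    wavelengths_nm : tuple of float
        The two LED wavelengths, nanometres.
    dpf : tuple of float
        Differential pathlength factor per wavelength (dimensionless).
    """

    channels: tuple = DEFAULT_CHANNELS
    separation_mm: float = 30.0
    wavelengths_nm: tuple = (760.0, 850.0)
    dpf: tuple = (6.0, 6.0)

    def __post_init__(self):
        if self.separation_mm <= 0:
            raise InvalidParameterError("source-detector separation must be > 0")
        if len(self.wavelengths_nm) != 2 or self.wavelengths_nm[0] == self.wavelengths_nm[1]:
            raise InvalidParameterError("exactly two distinct wavelengths required")
        if len(self.dpf) != 2:
            raise InvalidParameterError("one DPF per wavelength required")

    @property
    def pathlengths_mm(self) -> np.ndarray:
        """Effective photon pathlength d*DPF per wavelength (mm)."""
        return self.separation_mm * np.asarray(self.dpf, dtype=float)


@dataclass
class ExtinctionTable:
    """Molar extinction coefficients for HbO2 and HbR.

    ``eps[(chromophore, wavelength_nm)]`` in 1/(mM*mm).  The packaged
    default (see :data:`eegfnirs.mbll.DEFAULT_EXTINCTION`) comes from the
    standard Prahl/Cope compilation.
    """

    eps: dict
    citation: str = ""

    def matrix(self, wavelengths_nm) -> np.ndarray:
        """2x2 matrix E with rows = wavelengths, columns = (HbO2, HbR)."""
        try:
            rows = [
                [self.eps[("hbo2", float(w))], self.eps[("hbr", float(w))]]
                for w in wavelengths_nm
            ]
        except KeyError as exc:
            raise InvalidParameterError(
                f"extinction table lacks an entry for {exc.args[0]}"
            ) from exc
        return np.asarray(rows, dtype=float)


@dataclass
class RawOpticalRecording:
    """Dual-wavelength light-intensity time series.

    ``intensity`` has shape (n_channels, 2, n_times); axis 1 follows
    ``geometry.wavelengths_nm``.  Values are strictly positive detector
    units.  ``baseline_window`` (seconds) selects the samples used to form
    the reference intensity I0 for the optical-density computation.
    """

    intensity: np.ndarray
    fs: float
    geometry: OptodeGeometry
    baseline_window: tuple = (0.0, 10.0)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.fs <= 0:
            raise InvalidParameterError("fs must be > 0")
        if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
            raise InvalidParameterError(
                "intensity must have shape (n_channels, 2, n_times)"
            )

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.intensity.shape[-1]) / self.fs


@dataclass
class HemodynamicSeries:
    """Concentration-change series DeltaHbO2 / DeltaHbR per channel (uM).

    ``hbt`` is always the elementwise sum hbo2 + hbr, which keeps the
    definitional invariant exact.
    """

    hbo2: np.ndarray
    hbr: np.ndarray
    fs: float
    channels: tuple = DEFAULT_CHANNELS

    def __post_init__(self):
        self.hbo2 = np.atleast_2d(np.asarray(self.hbo2, dtype=float))
        self.hbr = np.atleast_2d(np.asarray(self.hbr, dtype=float))
        if self.hbo2.shape != self.hbr.shape:
            raise InvalidParameterError("hbo2 and hbr must have identical shapes")
        if self.fs <= 0:
            raise InvalidParameterError("fs must be > 0")

    @property
    def hbt(self) -> np.ndarray:
        return self.hbo2 + self.hbr

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.hbo2.shape[-1]) / self.fs

    def copy(self) -> "HemodynamicSeries":
        return HemodynamicSeries(
            self.hbo2.copy(), self.hbr.copy(), self.fs, tuple(self.channels)
        )


@dataclass
class EEGRecording:
    """Multi-channel EEG in microvolts with event markers.

    ``events`` is a list of ``(time_s, condition)`` pairs.
    """

    samples: np.ndarray
    fs: float = 1000.0
    channels: tuple = DEFAULT_CHANNELS
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise InvalidParameterError("fs must be > 0")
        dur = self.samples.shape[-1] / self.fs
        for t, _ in self.events:
            if not (0 <= t <= dur):
                raise InvalidParameterError(f"event at {t} s outside record [0, {dur}] s")

    @property
    def duration(self) -> float:
        return self.samples.shape[-1] / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.shape[-1]) / self.fs

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            self.samples.copy(), self.fs, tuple(self.channels), list(self.events)
        )


@dataclass
class EventSchedule:
    """Stroop trial schedule plus the waiting/task/rest period layout."""

    trial_onsets: np.ndarray
    conditions: np.ndarray
    display_s: float
    isi_bounds: tuple
    period_boundaries: tuple  # (t0, task_start, task_end, session_end)
    seed: int

    def __post_init__(self):
        self.trial_onsets = np.asarray(self.trial_onsets, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)

    @property
    def n_trials(self) -> int:
        return len(self.trial_onsets)

    @property
    def gaps(self) -> np.ndarray:
        """Intervals between consecutive onsets (seconds)."""
        return np.diff(self.trial_onsets)

    @property
    def session_duration(self) -> float:
        return self.period_boundaries[-1]


@dataclass
class ArtifactEvent:
    """One injected motion artifact (for recovery scoring)."""

    kind: str  # "spike" | "shift"
    time_s: float
    amplitude: float
    width_s: float = 0.0


@dataclass
class GroundTruth:
    """Noise-free simulation state retained for recovery tests."""

    hbo2_true: np.ndarray
    hbr_true: np.ndarray
    fs: float
    channels: tuple = DEFAULT_CHANNELS
    erp_template: dict | None = None
    artifact_log: list = field(default_factory=list)
    crosstalk_params: dict | None = None

    def __post_init__(self):
        self.hbo2_true = np.atleast_2d(np.asarray(self.hbo2_true, dtype=float))
        self.hbr_true = np.atleast_2d(np.asarray(self.hbr_true, dtype=float))

    @property
    def hbt_true(self) -> np.ndarray:
        return self.hbo2_true + self.hbr_true


@dataclass
class EpochSet:
    """Stimulus-locked EEG epochs, shape (n_trials, n_channels, n_samples)."""

    epochs: np.ndarray
    fs: float
    window: tuple = (-0.250, 0.750)
    baseline: tuple = (-0.250, 0.0)
    channels: tuple = DEFAULT_CHANNELS
    conditions: np.ndarray | None = None
    n_dropped: int = 0

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise InvalidParameterError("epochs must be (n_trials, n_channels, n_samples)")
        if not (self.window[0] <= self.baseline[0] and self.baseline[1] <= self.window[1]):
            raise InvalidParameterError("baseline must lie inside the epoch window")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.epochs.shape[-1]
        return self.window[0] + np.arange(n) / self.fs


@dataclass
class ErpResult:
    """Averaged, band-filtered ERP waveform plus component amplitudes."""

    waveform: np.ndarray  # (n_channels, n_samples)
    fs: float
    window: tuple
    channels: tuple = DEFAULT_CHANNELS
    components: dict = field(default_factory=dict)  # name -> per-channel uV
    component_windows: dict = field(default_factory=dict)
    n_trials: int = 0

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.waveform.shape[-1]) / self.fs


@dataclass
class CleaningReport:
    """Record of what the fNIRS cleaning chain did."""

    trend_coefficients: np.ndarray | None = None  # (n_channels, 2) intercept, slope
    tddr_iterations: int = 0
    tddr_converged: bool = True
    tddr_weight_summary: dict = field(default_factory=dict)
    filter_order: int = 3
    filter_cutoffs_hz: tuple = (0.01, 0.08)
    realized_minus3db_hz: tuple | None = None

    def to_dict(self) -> dict:
        return {
            "trend_coefficients": None
            if self.trend_coefficients is None
            else np.asarray(self.trend_coefficients).tolist(),
            "tddr_iterations": int(self.tddr_iterations),
            "tddr_converged": bool(self.tddr_converged),
            "tddr_weight_summary": {k: float(v) for k, v in self.tddr_weight_summary.items()},
            "filter_order": int(self.filter_order),
            "filter_cutoffs_hz": list(self.filter_cutoffs_hz),
            "realized_minus3db_hz": None
            if self.realized_minus3db_hz is None
            else list(self.realized_minus3db_hz),
        }


@dataclass
class QualityReport:
    """Signal-quality metrics of a simulated acquisition chain."""

    input_referred_noise_uvrms: float | None = None
    amplitude_distortion_pct: float | None = None
    frequency_distortion_pct: float | None = None
    crosstalk_residual_ratio_pct: float | None = None
    crosstalk_rejection_db: float | None = None

    def to_dict(self) -> dict:
        return {
            k: (None if v is None else float(v))
            for k, v in self.__dict__.items()
        }


@dataclass
class CouplingResult:
    """Pearson correlation between ERP amplitudes and hemodynamic peaks."""

    r: float
    p: float
    n: int
    slope: float
    intercept: float

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise InvalidParameterError("r outside [-1, 1]")
        if not 0.0 <= self.p <= 1.0:
            raise InvalidParameterError("p outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "r": float(self.r),
            "p": float(self.p),
            "n": int(self.n),
            "slope": float(self.slope),
            "intercept": float(self.intercept),
        }


@dataclass
class PairedComparisonResult:
    """Two-level repeated-measures ANOVA (equivalently a paired t-test)."""

    F: float
    t: float
    p: float
    n: int

    def to_dict(self) -> dict:
        return {"F": float(self.F), "t": float(self.t), "p": float(self.p), "n": int(self.n)}
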