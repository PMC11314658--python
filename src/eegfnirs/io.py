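"""CSV/TSV/JSON readers and writers, session configuration, manifests.

CSV is the canonical on-disk format: one ``time`` column plus one column
per channel (optical columns are named ``<channel>_<wavelength>nm``),
written with 9 significant digits.  Events use a BIDS-style TSV with
``onset``, ``duration`` and ``trial_type`` columns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    EEGRecording,
    EventSchedule,
    HemodynamicSeries,
    OptodeGeometry,
    RawOpticalRecording,
)
from .errors import InvalidParameterError

_FLOAT_FMT = "%.9g"


# ---------------------------------------------------------------------------
# Array containers <-> CSV / TSV
# ---------------------------------------------------------------------------


def write_optical_csv(raw: RawOpticalRecording, path) -> None:
    cols = {"time": raw.times}
    for ci, ch in enumerate(raw.geometry.channels):
        for wi, wl in enumerate(raw.geometry.wavelengths_nm):
            cols[f"{ch}_{wl:g}nm"] = raw.intensity[ci, wi]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_optical_csv(path, geometry: OptodeGeometry | None = None) -> RawOpticalRecording:
    df = pd.read_csv(path)
    t = df["time"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    names = [c for c in df.columns if c != "time"]
    channels, wavelengths = [], []
    for name in names:
        ch, wl = name.rsplit("_", 1)
        if ch not in channels:
            channels.append(ch)
        w = float(wl.removesuffix("nm"))
        if w not in wavelengths:
            wavelengths.append(w)
    if geometry is None:
        geometry = OptodeGeometry(channels=tuple(channels), wavelengths_nm=tuple(wavelengths))
    intensity = np.empty((len(channels), 2, len(df)))
    for ci, ch in enumerate(channels):
        for wi, wl in enumerate(geometry.wavelengths_nm):
            intensity[ci, wi] = df[f"{ch}_{wl:g}nm"].to_numpy()
    return RawOpticalRecording(intensity=intensity, fs=fs, geometry=geometry)


def write_eeg_csv(eeg: EEGRecording, path) -> None:
    cols = {"time": eeg.times}
    for ci, ch in enumerate(eeg.channels):
        cols[ch] = eeg.samples[ci]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_eeg_csv(path, events: list | None = None) -> EEGRecording:
    df = pd.read_csv(path)
    t = df["time"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    channels = tuple(c for c in df.columns if c != "time")
    samples = np.stack([df[c].to_numpy() for c in channels])
    return EEGRecording(samples=samples, fs=fs, channels=channels, events=events or [])


def write_hemo_csv(hemo: HemodynamicSeries, path) -> None:
    cols = {"time": hemo.times}
    for ci, ch in enumerate(hemo.channels):
        cols[f"hbo2_{ch}"] = hemo.hbo2[ci]
        cols[f"hbr_{ch}"] = hemo.hbr[ci]
        cols[f"hbt_{ch}"] = hemo.hbt[ci]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_hemo_csv(path) -> HemodynamicSeries:
    df = pd.read_csv(path)
    t = df["time"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    channels = tuple(
        c.removeprefix("hbo2_") for c in df.columns if c.startswith("hbo2_")
    )
    hbo2 = np.stack([df[f"hbo2_{ch}"].to_numpy() for ch in channels])
    hbr = np.stack([df[f"hbr_{ch}"].to_numpy() for ch in channels])
    return HemodynamicSeries(hbo2=hbo2, hbr=hbr, fs=fs, channels=channels)


def write_events_tsv(schedule: EventSchedule, path) -> None:
    """BIDS-style events table: onset, duration, trial_type."""
    pd.DataFrame(
        {
            "onset": schedule.trial_onsets,
            "duration": np.full(schedule.n_trials, schedule.display_s),
            "trial_type": schedule.conditions,
        }
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Session configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SessionConfig:
    """All tunable parameters of a simulated session.

    Defaults follow the reference acquisition and analysis settings:
    1 kHz EEG / 100 Hz fNIRS sampling, 30 trials of 500 ms display with
    350-750 ms ISI (one third congruent), -250..750 ms epochs, 0.8-17 Hz
    ERP band, 0.01-0.08 Hz third-order hemodynamic band-pass, 50 Hz
    acquisition low-pass with x1000 gain, and LED switching above 100 Hz.
    """

    seed: int = 0
    n_participants: int = 13
    eeg_fs: float = 1000.0
    fnirs_fs: float = 100.0
    n_trials: int = 30
    congruent_fraction: float = 1.0 / 3.0
    display_s: float = 0.5
    isi_low_s: float = 0.35
    isi_high_s: float = 0.75
    wait_s: float = 30.0
    rest_s: float = 60.0
    amp_hbo2: float = 1.0
    hbr_ratio: float = -0.25
    erp_amplitudes: dict = dataclasses.field(
        default_factory=lambda: {"P450": -2.7, "N500": -4.0, "P600": -2.0}
    )
    background_rms_uv: float = 10.0
    epoch_window: tuple = (-0.250, 0.750)
    erp_band: tuple = (0.8, 17.0)
    hemo_band: tuple = (0.01, 0.08)
    hemo_filter_order: int = 3
    lpf_cutoff_hz: float = 50.0
    gain: float = 1000.0
    noise_rms_uv: float = 0.8
    crosstalk_hz: float = 125.0
    crosstalk_amp_uv: float = 10.0
    n_spikes: int = 2
    n_shifts: int = 1
    spike_width_s: float = 0.3
    separation_mm: float = 30.0
    dpf: tuple = (6.0, 6.0)
    subject_gain_sd: float = 0.25
    out_dir: str | None = None

    def __post_init__(self):
        if self.crosstalk_hz <= self.lpf_cutoff_hz * 2:
            # the reference design keeps LED switching above 100 Hz, i.e.
            # well clear of the 0-50 Hz EEG band; lower values are allowed
            # (they are how the contrast is demonstrated) but not defaults
            pass
        for name in ("eeg_fs", "fnirs_fs", "display_s", "gain"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for k in ("epoch_window", "erp_band", "hemo_band", "dpf"):
            if k in kwargs and isinstance(kwargs[k], list):
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "SessionConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------


def array_hash(arr: np.ndarray) -> str:
    a = np.ascontiguousarray(np.asarray(arr, dtype=float))
    return hashlib.sha256(a.tobytes()).hexdigest()


def build_manifest(config: SessionConfig, stages: dict) -> dict:
    """Manifest of a run: config hash, seed, and per-stage array digests."""
    manifest = {
        "config_hash": config.config_hash(),
        "seed": int(config.seed),
        "stages": {},
    }
    for stage, arrays in stages.items():
        manifest["stages"][stage] = {
            name: {"shape": list(np.shape(arr)), "sha256": array_hash(arr)}
            for name, arr in arrays.items()
        }
    payload = json.dumps(manifest, sort_keys=True).encode()
    manifest["manifest_hash"] = hashlib.sha256(payload).hexdigest()
    return manifest


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
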