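"""Modified Beer-Lambert law (MBLL): optical density and its inversion.

The MBLL relates the change in optical density at wavelength lambda to the
concentration changes of oxygenated and deoxygenated hemoglobin::

    dOD(lambda, t) = [eps_HbO2(lambda) * dHbO2(t) + eps_HbR(lambda) * dHbR(t)]
                     * d * DPF(lambda)

with d the source-detector separation and DPF the differential pathlength
factor.  With two wavelengths this is a 2x2 linear system per time point;
:func:`invert_mbll` solves it for (dHbO2, dHbR) and returns dHbT as their
sum.

Units: extinction coefficients in 1/(mM*mm), pathlength in mm,
concentration changes in micromolar (the 1e-3 uM->mM factor is applied
internally and must match the forward model in
:mod:`eegfnirs.synthgen`).
"""

from __future__ import annotations

import numpy as np

from .containers import ExtinctionTable, HemodynamicSeries, OptodeGeometry, RawOpticalRecording
from .errors import DomainError, IllConditionedCoefficientsError, InvalidParameterError

#: maximum acceptable condition number of the 2x2 extinction matrix
MAX_CONDITION_NUMBER = 1e6

#: uM -> mM, so extinction tables in 1/(mM*mm) pair with uM concentrations
_UM_TO_MM = 1e-3

# Molar extinction coefficients at 760 / 850 nm from the Prahl/Cope
# hemoglobin compilation, converted from 1/(cm*M) to 1/(mM*mm).
DEFAULT_EXTINCTION = ExtinctionTable(
    eps={
        ("hbo2", 760.0): 0.05860,
        ("hbr", 760.0): 0.15485,
        ("hbo2", 850.0): 0.10580,
        ("hbr", 850.0): 0.06913,
    },
    citation="Prahl/Cope tabulated hemoglobin spectra (oregon medical laser center)",
)


def extinction_matrix(
    coeffs: ExtinctionTable, wavelengths_nm, *, check: bool = True
) -> np.ndarray:
    """Return the 2x2 extinction matrix and optionally validate conditioning."""
    E = coeffs.matrix(wavelengths_nm)
    if check:
        cond = np.linalg.cond(E)
        if not np.isfinite(cond) or cond > MAX_CONDITION_NUMBER:
            raise IllConditionedCoefficientsError(
                f"extinction matrix condition number {cond:.3g} exceeds "
                f"{MAX_CONDITION_NUMBER:.0e}; wavelength pair cannot separate HbO2/HbR"
            )
    return E


def optical_density(raw: RawOpticalRecording, i0=None) -> np.ndarray:
    """Convert raw intensities to optical-density change.

    dOD(lambda, t) = -log10(I(lambda, t) / I0(lambda)).  I0 is the mean
    intensity over ``raw.baseline_window`` unless an explicit reference
    (e.g. a bench-calibrated source intensity) is passed as ``i0``
    (per-wavelength, broadcast over channels).

    Returns an array shaped like ``raw.intensity``: (n_channels, 2, n_times).
    """
    if np.any(raw.intensity <= 0):
        raise DomainError("optical intensities must be strictly positive")
    if i0 is None:
        lo, hi = raw.baseline_window
        i0_idx = (raw.times >= lo) & (raw.times < hi)
        if not np.any(i0_idx):
            raise InvalidParameterError(
                f"baseline window {raw.baseline_window} selects no samples"
            )
        i0 = raw.intensity[:, :, i0_idx].mean(axis=-1, keepdims=True)
    else:
        i0 = np.asarray(i0, dtype=float).reshape(1, -1, 1)
        if np.any(i0 <= 0):
            raise DomainError("reference intensities must be strictly positive")
    return -np.log10(raw.intensity / i0)


def invert_mbll(
    od: np.ndarray,
    geom: OptodeGeometry,
    coeffs: ExtinctionTable = DEFAULT_EXTINCTION,
    fs: float = 100.0,
) -> HemodynamicSeries:
    """Solve the MBLL 2x2 system per time point for dHbO2 / dHbR (uM).

    Parameters
    ----------
    od : ndarray, shape (n_channels, 2, n_times)
        Optical-density change per wavelength (axis 1 ordered like
        ``geom.wavelengths_nm``).
    geom : OptodeGeometry
    coeffs : ExtinctionTable
    fs : float
        Sampling rate carried into the returned series.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[1] != 2:
        raise InvalidParameterError("od must have shape (n_channels, 2, n_times)")
    E = extinction_matrix(coeffs, geom.wavelengths_nm)
    pl = geom.pathlengths_mm  # (2,)
    # normalize OD by pathlength, then solve E @ c = od/pl for each sample
    rhs = od / pl[None, :, None]
    conc_mm = np.linalg.solve(E[None, :, :], np.moveaxis(rhs, 1, 2)[..., None])[..., 0]
    conc_um = np.moveaxis(conc_mm, 1, 2) / _UM_TO_MM  # (n_ch, 2, n_t) in uM
    return HemodynamicSeries(
        hbo2=conc_um[:, 0, :], hbr=conc_um[:, 1, :], fs=fs, channels=tuple(geom.channels)
    )


def recover_hemodynamics(
    raw: RawOpticalRecording, coeffs: ExtinctionTable = DEFAULT_EXTINCTION, i0=None
) -> HemodynamicSeries:
    """Convenience chain: optical density then MBLL inversion."""
    od = optical_density(raw, i0=i0)
    return invert_mbll(od, raw.geometry, coeffs, fs=raw.fs)
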