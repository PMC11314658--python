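"""Neurovascular-coupling statistics across sessions.

Sessions (virtual participants) are the unit of analysis: each
contributes one ERP component amplitude and one hemodynamic peak value,
and the association is quantified with a Pearson correlation plus an
ordinary least-squares line.  The left-vs-right prefrontal comparison is
a two-level repeated-measures ANOVA, computed through its exact
paired-t equivalence (F = t^2).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as spstats

from .containers import CouplingResult, PairedComparisonResult
from .errors import DegenerateInputError, InvalidParameterError


def _validate_pair(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("inputs must be 1-D arrays of equal length")
    if len(x) < min_n:
        raise InvalidParameterError(f"need at least {min_n} paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidParameterError("inputs must be finite")
    return x, y


def pearson_coupling(x, y) -> CouplingResult:
    """Pearson r between ERP amplitudes and hemodynamic peak values.

    The p-value comes from the exact t-transform with n - 2 degrees of
    freedom; slope and intercept are the ordinary least-squares line of
    y on x.
    """
    x, y = _validate_pair(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero variance in an input; correlation undefined")
    r, p = spstats.pearsonr(x, y)
    fit = spstats.linregress(x, y)
    return CouplingResult(
        r=float(r), p=float(p), n=len(x), slope=float(fit.slope), intercept=float(fit.intercept)
    )


def paired_channel_comparison(a, b) -> PairedComparisonResult:
    """Two-level repeated-measures ANOVA on paired per-session amplitudes.

    With two within-subject levels the RM-ANOVA F statistic equals the
    square of the paired t statistic, and the two-sided p-values agree
    exactly; that equivalence is used directly.  Identical inputs give
    F = 0, p = 1; a constant non-zero difference has zero within-pair
    variance and raises :class:`DegenerateInputError`.
    """
    a, b = _validate_pair(a, b)
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return PairedComparisonResult(F=0.0, t=0.0, p=1.0, n=n)
        raise DegenerateInputError(
            "constant non-zero paired difference: zero variance, p undefined"
        )
    t = float(d.mean() / (sd / np.sqrt(n)))
    F = t * t
    p = float(spstats.f.sf(F, 1, n - 1))
    return PairedComparisonResult(F=F, t=t, p=p, n=n)
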