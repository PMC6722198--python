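"""Closed-form time-dependent plasma concentration used as boundary forcing.

The plasma profile is evaluated analytically at arbitrary solver times (no
pre-tabulation) so adaptive time-steppers see a smooth forcing. Plasma is
one-way: nothing in the package feeds tissue state back into these
functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import DosingParams

__all__ = ["PlasmaSeries", "cpl_iv", "cpl_oral", "cpl"]

#: relative |ka - ke| threshold below which the removable-singularity limit
#: of the oral profile is used
_DEGENERACY_RTOL = 1e-8


@dataclass(frozen=True)
class PlasmaSeries:
    """Plasma concentration sampled on a time grid (t in s, cpl in µmol/L)."""

    t: np.ndarray
    cpl: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("t must be 1D and strictly increasing")
        if len(self.cpl) != len(t):
            raise ValueError("t and cpl must have equal length")


def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    return t


def cpl_iv(t, dos: DosingParams):
    """IV bolus plasma concentration (Dose/V)·exp(−ke·t), µmol/L."""
    t = _check_times(t)
    out = (dos.Dose / dos.V) * np.exp(-dos.ke * t)
    return out if out.ndim else float(out)


def cpl_oral(t, dos: DosingParams):
    """Oral (two-exponential) plasma concentration, µmol/L.

    F·Dose·ka/(V·(ka−ke)) · (e^{−ke·t} − e^{−ka·t}); when ka and ke agree
    to within a relative tolerance the continuous extension
    F·Dose·ka·t·e^{−ka·t}/V is returned instead (removable singularity).
    """
    t = _check_times(t)
    F, Dose, ka, ke, V = dos.F, dos.Dose, dos.ka, dos.ke, dos.V
    if abs(ka - ke) <= _DEGENERACY_RTOL * max(ka, ke):
        out = F * Dose * ka * t * np.exp(-ka * t) / V
    else:
        out = F * Dose * ka / (V * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
    return out if out.ndim else float(out)


def cpl(t, dos: DosingParams):
    """Plasma concentration dispatched on dos.route ('oral' or 'iv')."""
    if dos.route == "oral":
        return cpl_oral(t, dos)
    if dos.route == "iv":
        return cpl_iv(t, dos)
    raise ValueError(f"unknown route {dos.route!r}")


def oral_peak(dos: DosingParams) -> tuple[float, float]:
    """Analytic (t*, Cpl(t*)) of the oral profile; t* = ln(ka/ke)/(ka−ke)."""
    ka, ke = dos.ka, dos.ke
    if ka <= 0 or ke <= 0:
        raise ValueError("oral peak requires ka > 0 and ke > 0")
    if abs(ka - ke) <= _DEGENERACY_RTOL * max(ka, ke):
        tstar = 1.0 / ka
    else:
        tstar = np.log(ka / ke) / (ka - ke)
    return tstar, cpl_oral(tstar, dos)


def oral_auc(dos: DosingParams) -> float:
    """Exact ∫₀^∞ Cpl dt = F·Dose/(V·ke) for the oral route, µmol·s/L."""
    if dos.ke <= 0:
        raise ValueError("AUC diverges for ke <= 0")
    return dos.F * dos.Dose / (dos.V * dos.ke)
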