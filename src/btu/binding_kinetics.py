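"""Reaction terms for specific and non-specific binding and their equilibria.

Binding sites are immobile and uniformly distributed, so the bound pools
carry no transport terms; their spatial pattern arises only through the
local free concentration. All functions are pure and vectorize over numpy
arrays. No positivity clamping happens here — that would break solver
smoothness; positivity is checked on solver output instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import DrugParams

__all__ = ["BindingState", "binding_rhs", "equilibrium_bound", "occupancy"]


@dataclass(frozen=True)
class BindingState:
    """Free and bound concentrations at one point, µmol/L."""

    C: float
    B1: float
    B2: float


def binding_rhs(C, B1, B2, dp: DrugParams):
    """Reaction rates (dC_binding, dB1, dB2) in µmol/L/s.

    dB1 = k1on·C·(B1max − B1) − k1off·B1 and analogously for dB2;
    dC_binding = −dB1 − dB2 exactly (local mass conservation of the
    reaction terms).
    """
    dB1 = dp.k1on * C * (dp.B1max - B1) - dp.k1off * B1
    dB2 = dp.k2on * C * (dp.B2max - B2) - dp.k2off * B2
    return -(dB1 + dB2), dB1, dB2


def equilibrium_bound(C, Bmax, kon: float, koff: float):
    """Equilibrium bound concentration Bmax·C/(koff/kon + C), µmol/L.

    For kon = 0 (no association) the equilibrium is 0; kon = koff = 0
    leaves the equilibrium undefined and raises.
    """
    if kon < 0 or koff < 0:
        raise ValueError("kon and koff must be >= 0")
    if kon == 0 and koff == 0:
        raise ValueError("equilibrium undefined for kon = koff = 0")
    if kon == 0:
        return np.zeros_like(np.asarray(C, dtype=float)) if np.ndim(C) else 0.0
    Kd = koff / kon
    return Bmax * np.asarray(C) / (Kd + np.asarray(C)) if np.ndim(C) else Bmax * C / (Kd + C)


def occupancy(B, Bmax):
    """Fractional occupancy B/Bmax in [0, 1]; defined as 0 when Bmax = 0."""
    B = np.asarray(B, dtype=float)
    if np.ndim(Bmax) == 0 and Bmax == 0:
        return np.zeros_like(B) if B.ndim else 0.0
    out = B / Bmax
    return out if out.ndim else float(out)
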