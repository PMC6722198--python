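"""Independent reduced models and auditors used as verification oracles.

The well-mixed model is the 0D limit of the tissue unit: boundary exchange
collapses to a single rate k_ex = P·perimeter/area. It shares no spatial
code with the PDE solver, so agreement between the two is a genuine
cross-check. The auditors (mass balance, symmetry) consume solver output
only through its public result types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import plasma_pk
from .binding_kinetics import binding_rhs
from .model_core import Domain, DosingParams, DrugParams
from .pde_solver import Grid, SimulationResult, StateField, SolverError, wall_influx

__all__ = [
    "WellMixedResult",
    "exchange_rate",
    "simulate_well_mixed",
    "oracle_gap",
    "mass_balance_residual",
    "symmetry_error",
]


@dataclass(frozen=True)
class WellMixedResult:
    """0D (spatially uniform) solution series, concentrations in µmol/L."""

    times: np.ndarray
    C: np.ndarray
    B1: np.ndarray
    B2: np.ndarray


def exchange_rate(dp: DrugParams, dom: Domain) -> float:
    """k_ex = P·perimeter/area = 2P(xr+yr)/(xr·yr), s⁻¹."""
    return 2.0 * dp.P * (dom.xr + dom.yr) / (dom.xr * dom.yr)


def simulate_well_mixed(
    dp: DrugParams,
    dos: DosingParams,
    dom: Domain,
    t_end: float,
    output_times: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-13,
    cpl_fn: Callable[[float], float] | None = None,
) -> WellMixedResult:
    """Solve dC/dt = k_ex·(Cpl(t) − C) + binding from the zero state."""
    if cpl_fn is None:
        cpl_fn = lambda t: plasma_pk.cpl(t, dos)
    k_ex = exchange_rate(dp, dom)
    if output_times is None:
        output_times = np.linspace(0.0, t_end, 401)
    output_times = np.asarray(output_times, dtype=float)

    def rhs(t, y):
        C, B1, B2 = y
        dC_bind, dB1, dB2 = binding_rhs(C, B1, B2, dp)
        return [k_ex * (cpl_fn(t) - C) + dC_bind, dB1, dB2]

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [0.0, 0.0, 0.0],
        method="BDF",
        t_eval=output_times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverError(f"well-mixed integration failed: {sol.message}")
    return WellMixedResult(times=sol.t, C=sol.y[0], B1=sol.y[1], B2=sol.y[2])


def oracle_gap(
    pde: SimulationResult,
    wm: WellMixedResult,
    dp: DrugParams,
    dom: Domain,
    floor: float = 1e-6,
) -> float:
    """Max relative deviation of the center C series from the 0D oracle.

    Times before t_burn = 10·(xr²/D_eff) are excluded: the 0D model cannot
    represent the initial diffusion boundary-layer transient.
    """
    if pde.times.shape != wm.times.shape or not np.allclose(pde.times, wm.times):
        raise ValueError("PDE and well-mixed results must share output times")
    t_burn = 10.0 * dom.xr**2 / dp.D_eff
    mask = pde.times > t_burn
    if not np.any(mask):
        raise ValueError(f"no output times beyond burn-in t = {t_burn:.3g} s")
    denom = np.maximum(wm.C[mask], floor)
    return float(np.max(np.abs(pde.center_C[mask] - wm.C[mask]) / denom))


def mass_balance_residual(
    result: SimulationResult,
    dp: DrugParams,
    dos: DosingParams,
    g: Grid | None = None,
    cpl_fn: Callable[[float], float] | None = None,
) -> dict:
    """Conservation audit from spatial snapshots.

    Compares the total content trapz²(C+B1+B2) against the time integral
    of the boundary influx ∮P·(Cpl−C)ds between consecutive snapshots.
    Returns the rate residual series (finite-difference derivative of
    content minus influx, µmol·m²/L/s), the cumulative drift, and the
    drift relative to peak content.
    """
    if len(result.snapshots) < 2:
        raise ValueError("mass balance audit needs at least 2 snapshots")
    if g is None:
        g = result.grid
    if cpl_fn is None:
        cpl_fn = lambda t: plasma_pk.cpl(t, dos)
    w = g.area_weights()
    times = np.array([s.t for s in result.snapshots])
    content = np.array([np.sum(w * (s.C + s.B1 + s.B2)) for s in result.snapshots])
    influx = np.array([wall_influx(s.C, cpl_fn(s.t), dp, g) for s in result.snapshots])

    dcontent = np.gradient(content, times)
    rate_residual = dcontent - influx
    # cumulative: content(t) − content(0) − ∫ influx dt, trapezoid in time
    influx_int = np.concatenate(
        [[0.0], np.cumsum(0.5 * (influx[1:] + influx[:-1]) * np.diff(times))]
    )
    drift = content - content[0] - influx_int
    peak = max(float(np.max(np.abs(content))), 1e-300)
    return {
        "times": times,
        "content": content,
        "influx": influx,
        "rate_residual": rate_residual,
        "cumulative_drift": drift,
        "relative_drift": np.abs(drift) / peak,
        "max_relative_drift": float(np.max(np.abs(drift)) / peak),
    }


def symmetry_error(field: StateField, which: str = "C") -> tuple[float, float]:
    """(x-mirror, y-mirror) max node-wise asymmetry, normalized by the max.

    Requires a square grid so that the mirrored array is comparable
    node-for-node.
    """
    arr = getattr(field, which)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError("symmetry check requires a square grid")
    scale = float(np.max(np.abs(arr)))
    if scale == 0.0:
        return 0.0, 0.0
    ex = float(np.max(np.abs(arr - arr[::-1, :]))) / scale
    ey = float(np.max(np.abs(arr - arr[:, ::-1]))) / scale
    return ex, ey
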