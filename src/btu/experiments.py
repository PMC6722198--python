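"""Scripted scenario suite with machine-checkable qualitative assertions.

Each runner reproduces one family of published-style scenarios (binding
on/off, kinetic sweeps, permeability sweeps, spatial maps) and returns both
the raw simulation results and a list of named checks, so a single failed
assertion is individually reportable rather than folded into an aggregate
pass/fail. All runners are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .binding_kinetics import occupancy
from .model_core import Domain, DosingParams, DrugParams, default_params, spatial_experiment_params
from .pde_solver import SimulationResult, SolverOptions, default_output_times, simulate

__all__ = [
    "Check",
    "SweepSpec",
    "ScenarioSuiteResult",
    "run_binding_scenarios",
    "run_kinetics_sweep",
    "run_permeability_sweep",
    "run_spatial_maps",
    "proportionality_check",
]


@dataclass(frozen=True)
class Check:
    """One named, individually reportable scenario assertion."""

    name: str
    passed: bool
    value: float | None = None
    detail: str = ""


@dataclass(frozen=True)
class SweepSpec:
    """A one-parameter multiplicative sweep relative to the defaults."""

    parameter: str
    multipliers: tuple
    label: str = ""

    def __post_init__(self) -> None:
        import dataclasses

        names = {f.name for f in dataclasses.fields(DrugParams)} | {
            f.name for f in dataclasses.fields(DosingParams)
        }
        if self.parameter not in names:
            raise ValueError(f"unknown sweep parameter {self.parameter!r}")
        if any(m <= 0 for m in self.multipliers):
            raise ValueError("multipliers must be > 0")


@dataclass
class ScenarioSuiteResult:
    results: dict
    checks: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failed(self) -> list:
        return [c for c in self.checks if not c.passed]


def _apply_multipliers(dp: DrugParams, dos: DosingParams, **mult) -> tuple[DrugParams, DosingParams]:
    import dataclasses

    dp_fields = {f.name for f in dataclasses.fields(DrugParams)}
    dp_over = {k: getattr(dp, k) * m for k, m in mult.items() if k in dp_fields}
    dos_over = {k: getattr(dos, k) * m for k, m in mult.items() if k not in dp_fields}
    return dp.with_(**dp_over), dos.with_(**dos_over)


def _default_setup(dom: Domain | None, t_end: float, n_times: int):
    dp, dos, dom0 = default_params()
    if dom is None:
        dom = dom0
    times = default_output_times(t_end, n_times)
    return dp, dos, dom, times


def run_binding_scenarios(
    dom: Domain | None = None,
    t_end: float = 2e5,
    n_times: int = 300,
    opts: SolverOptions | None = None,
) -> ScenarioSuiteResult:
    """No binding / specific only / specific+non-specific on the defaults.

    The checks encode the documented qualitative behaviour: without
    binding, C_ECF lies below the plasma curve through its peak and
    crosses above it afterwards; switching binding on lowers C_ECF early
    and raises it late (ratio < 1 then > 1).
    """
    dp, dos, dom, times = _default_setup(dom, t_end, n_times)
    variants = {
        "no_binding": dp.with_(B1max=0.0, B2max=0.0),
        "specific_only": dp.with_(B2max=0.0),
        "full": dp,
    }
    results = {
        name: simulate(d, dos, dom, t_end=t_end, output_times=times, opts=opts)
        for name, d in variants.items()
    }
    r0, rs, rf = results["no_binding"], results["specific_only"], results["full"]
    floor = 1e-12
    ratio_C_full = rf.center_C / np.maximum(r0.center_C, floor)
    ratio_C_spec = rs.center_C / np.maximum(r0.center_C, floor)
    ratio_B1 = rf.center_B1 / np.maximum(rs.center_B1, floor)

    cpl = r0.cpl
    k_peak = int(np.argmax(cpl))
    t_peak = times[k_peak]
    below_through_peak = bool(np.all(r0.center_C[1 : k_peak + 1] <= cpl[1 : k_peak + 1]))
    above_late = bool(np.any(r0.center_C[k_peak + 1 :] > cpl[k_peak + 1 :]))
    if above_late:
        k_cross = k_peak + 1 + int(np.argmax(r0.center_C[k_peak + 1 :] > cpl[k_peak + 1 :]))
        t_cross = float(times[k_cross])
    else:
        t_cross = float("nan")

    sel = (times > 100.0) & (r0.center_C > 1e-6)
    early = sel & (times < t_peak)
    late = sel & (times > 2 * t_peak)
    ratio_early_low = bool(np.all(ratio_C_full[early] < 1.0))
    ratio_late_high = bool(np.any(ratio_C_full[late] > 1.0))

    checks = [
        Check(
            "no_binding_C_below_cpl_through_peak",
            below_through_peak,
            detail=f"plasma peak at t = {t_peak:.0f} s",
        ),
        Check(
            "no_binding_C_crosses_above_cpl_after_peak",
            above_late,
            value=t_cross,
            detail="first crossing time, s",
        ),
        Check("binding_lowers_C_early", ratio_early_low, value=float(np.min(ratio_C_full[early]))),
        Check("binding_raises_C_late", ratio_late_high, value=float(np.max(ratio_C_full[late]))),
        Check(
            "B2_zero_when_B2max_zero",
            bool(np.all(rs.center_B2 == 0.0)),
        ),
    ]
    return ScenarioSuiteResult(
        results=results,
        checks=checks,
        extras={
            "times": times,
            "ratio_C_full_over_none": ratio_C_full,
            "ratio_C_specific_over_none": ratio_C_spec,
            "ratio_B1_full_over_specific": ratio_B1,
            "t_peak_cpl": t_peak,
        },
    )


def run_kinetics_sweep(
    dom: Domain | None = None,
    t_end: float = 2e5,
    n_times: int = 300,
    opts: SolverOptions | None = None,
    k1on_mult: Sequence[float] = (0.01, 1.0, 10.0),
    k1off_mult: Sequence[float] = (0.1, 1.0, 10.0),
    B1max_mult: Sequence[float] = (0.01, 1.0, 100.0),
) -> ScenarioSuiteResult:
    """3×3×3 sweep of the specific-binding constants around the defaults.

    Monotonicity checks are evaluated at the default run's C_ECF peak time
    (uptake phase) and at 3× that time (decline phase), since the
    qualitative effects differ between the two phases.
    """
    dp, dos, dom, times = _default_setup(dom, t_end, n_times)
    results: dict[tuple[float, float, float], SimulationResult] = {}
    for m_on in k1on_mult:
        for m_off in k1off_mult:
            for m_b in B1max_mult:
                d, _ = _apply_multipliers(dp, dos, k1on=m_on, k1off=m_off, B1max=m_b)
                results[(m_on, m_off, m_b)] = simulate(
                    d, dos, dom, t_end=t_end, output_times=times, opts=opts
                )

    default_key = (1.0, 1.0, 1.0)
    rd = results[default_key]
    k_up = int(np.argmax(rd.center_C))
    t_up = times[k_up]
    k_down = int(np.argmin(np.abs(times - 3.0 * t_up)))

    checks = []
    mb_hi = max(B1max_mult)
    # larger k1on -> faster association -> lower C during uptake; the effect
    # is only resolvable at high B1max (at the default the limited sites
    # saturate long before the peak and the ordering degenerates)
    c_by_on = [results[(m, 1.0, mb_hi)].center_C[k_up] for m in sorted(k1on_mult)]
    checks.append(
        Check(
            "k1on_lowers_C_during_uptake",
            bool(np.all(np.diff(c_by_on) <= 1e-12)),
            value=float(c_by_on[0] - c_by_on[-1]),
        )
    )
    # larger k1off -> faster dissociation -> higher C (most visible at high B1max)
    c_by_off = [results[(1.0, m, mb_hi)].center_C[k_down] for m in sorted(k1off_mult)]
    checks.append(
        Check(
            "k1off_raises_C",
            bool(np.all(np.diff(c_by_off) >= -1e-12)),
            value=float(c_by_off[-1] - c_by_off[0]),
        )
    )
    # larger B1max -> lower C peak
    peaks = [float(np.max(results[(1.0, 1.0, m)].center_C)) for m in sorted(B1max_mult)]
    checks.append(
        Check(
            "B1max_lowers_C_peak",
            bool(np.all(np.diff(peaks) <= 1e-12)),
            value=peaks[0] - peaks[-1],
        )
    )
    # bound caps hold in every run
    cap_ok = all(
        float(np.max(r.diagnostics["max_B1"])) <= dp.B1max * key[2] * (1 + 1e-9)
        for key, r in results.items()
    )
    checks.append(Check("B1_never_exceeds_B1max", cap_ok))
    # faster association saturates the target earlier. Checked at the
    # default B1max, where both runs actually approach saturation; at
    # B1max×100 the retarded binding front starves the center node and no
    # run gets anywhere near full occupancy.
    if 10.0 in k1on_mult:
        t90 = {}
        for m_on in (1.0, 10.0):
            r = results[(m_on, 1.0, 1.0)]
            occ = occupancy(r.center_B1, dp.B1max)
            hit = np.nonzero(occ >= 0.9)[0]
            t90[m_on] = float(times[hit[0]]) if hit.size else float("inf")
        checks.append(
            Check(
                "fast_k1on_saturates_earlier",
                t90[10.0] < t90[1.0],
                value=t90[10.0],
                detail=f"t(occ>=0.9): x10 {t90[10.0]:.0f} s vs x1 {t90[1.0]:.0f} s",
            )
        )
    return ScenarioSuiteResult(
        results=results,
        checks=checks,
        extras={"times": times, "t_uptake": t_up, "t_decline": float(times[k_down])},
    )


def run_permeability_sweep(
    dom: Domain | None = None,
    t_end: float = 2e5,
    n_times: int = 300,
    opts: SolverOptions | None = None,
    multipliers: Sequence[float] = (0.1, 1.0, 10.0),
) -> ScenarioSuiteResult:
    """BBB permeability sweep P × {0.1, 1, 10}.

    High P couples the unit tightly to plasma (C_ECF tracks Cpl); low P
    delays and depresses the C_ECF peak.
    """
    dp, dos, dom, times = _default_setup(dom, t_end, n_times)
    results = {
        m: simulate(dp.with_(P=dp.P * m), dos, dom, t_end=t_end, output_times=times, opts=opts)
        for m in multipliers
    }
    rd = results[1.0]
    burn = times > 500.0

    def tracking_gap(r: SimulationResult) -> float:
        return float(np.max(np.abs(r.center_C[burn] - r.cpl[burn]) / np.max(r.cpl)))

    peaks = {m: float(np.max(r.center_C)) for m, r in results.items()}
    tpeaks = {m: float(r.times[np.argmax(r.center_C)]) for m, r in results.items()}
    ms = sorted(multipliers)

    checks = [
        Check(
            "low_P_peak_later",
            tpeaks[0.1] > tpeaks[1.0],
            value=tpeaks[0.1],
            detail=f"argmax t: x0.1 {tpeaks[0.1]:.0f} s vs x1 {tpeaks[1.0]:.0f} s",
        ),
        Check(
            "low_P_peak_lower",
            peaks[0.1] < peaks[1.0],
            value=peaks[0.1],
        ),
        Check(
            "peak_monotone_in_P",
            bool(np.all(np.diff([peaks[m] for m in ms]) >= -1e-12)),
        ),
        Check(
            "high_P_tracks_cpl",
            tracking_gap(results[10.0]) < tracking_gap(rd),
            value=tracking_gap(results[10.0]),
            detail=f"gap x10 {tracking_gap(results[10.0]):.3f} vs x1 {tracking_gap(rd):.3f}",
        ),
    ]
    return ScenarioSuiteResult(results=results, checks=checks, extras={"times": times})


def run_spatial_maps(
    t_end: float = 1e4,
    snapshot_times: Sequence[float] = (250.0, 1000.0, 5000.0),
    dom: Domain | None = None,
    opts: SolverOptions | None = None,
    n_times: int = 200,
) -> ScenarioSuiteResult:
    """Spatial-distribution experiment with the exaggerated parameter set.

    Snapshot times are {0.5, 2, 10} × the diffusion time xr²/D_eff = 500 s
    of this parameter set. Checks: drug enters from the walls (boundary
    mean exceeds interior mean early), bulk flow tilts the early pattern
    toward the left (inflow) side, and diffusion evens everything out late
    (coefficient of variation < 1%).
    """
    dp, dos, dom0 = spatial_experiment_params()
    if dom is None:
        dom = dom0
    times = default_output_times(t_end, n_times)
    result = simulate(
        dp, dos, dom, t_end=t_end, output_times=times, snapshot_times=snapshot_times, opts=opts
    )
    early, mid, late = result.snapshots[0], result.snapshots[1], result.snapshots[-1]

    def boundary_interior_contrast(C: np.ndarray) -> float:
        boundary = np.concatenate([C[0, :], C[-1, :], C[1:-1, 0], C[1:-1, -1]])
        interior = C[1:-1, 1:-1]
        return float(np.mean(boundary) / np.mean(interior))

    nx = early.C.shape[0]
    left = float(np.mean(early.C[: nx // 2, :]))
    right = float(np.mean(early.C[nx - nx // 2 :, :]))
    cv_late = float(np.std(late.C) / np.mean(late.C))
    occ_mid = occupancy(mid.B1, dp.B1max)
    cv_early = float(np.std(early.C) / np.mean(early.C))

    checks = [
        Check(
            "early_boundary_exceeds_interior",
            boundary_interior_contrast(early.C) > 1.0,
            value=boundary_interior_contrast(early.C),
        ),
        Check("early_left_exceeds_right", left > right, value=left / right),
        Check("late_evenly_distributed", cv_late < 0.01, value=cv_late),
        Check(
            "B1_saturates_while_C_equilibrates",
            bool(np.min(occ_mid) > 0.95 and cv_early > 0.01),
            value=float(np.min(occ_mid)),
            detail="min B1 occupancy at mid snapshot; early C still uneven",
        ),
    ]
    return ScenarioSuiteResult(
        results={"spatial": result},
        checks=checks,
        extras={"snapshot_times": tuple(snapshot_times), "params": dp, "dosing": dos},
    )


def proportionality_check(
    result: SimulationResult,
    dp: DrugParams,
    floor: float = 1e-4,
    t_min: float | None = None,
) -> float:
    """Max relative deviation of B2 from its quasi-equilibrium (B2max/Kd2)·C.

    In the weak, high-capacity regime the non-specific pool tracks the free
    concentration linearly; deviations shrink once t exceeds a few
    non-specific relaxation times, so times before t_min (default
    10/k2off) are excluded. The relative deviation |B2 − slope·C|/C is
    ill-conditioned as C → 0 (the quasi-steady lag term 0.5·dlnC/dt/k2off
    blows up while both concentrations are immeasurably small), so times
    where C is below ``floor`` — default 1e-4 µmol/L, ~0.02% of the default
    peak — are excluded as well.
    """
    if t_min is None:
        if dp.k2off <= 0:
            raise ValueError("t_min required when k2off = 0")
        t_min = 10.0 / dp.k2off
    slope = dp.B2max / dp.Kd2
    mask = (result.times > t_min) & (result.center_C > floor)
    if not np.any(mask):
        raise ValueError("no usable times for proportionality check")
    C = result.center_C[mask]
    B2 = result.center_B2[mask]
    return float(np.max(np.abs(B2 - slope * C) / C))
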