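"""Model parameters, physiological-range validation, and canonical presets.

Units used throughout the package: lengths in m, time in s, concentrations
in µmol/L, dose in µmol, distribution volume in L. Rate constants for
association are in (µmol/L·s)⁻¹, for dissociation in s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Literal

__all__ = [
    "DrugParams",
    "DosingParams",
    "Domain",
    "RangeTable",
    "ValidationReport",
    "ParamCheck",
    "default_params",
    "spatial_experiment_params",
    "physiological_ranges",
    "validate_params",
    "tortuosity_to_Deff",
]


@dataclass(frozen=True)
class DrugParams:
    """Transport and binding constants for a drug in brain ECF.

    Attributes
    ----------
    D_eff : float
        Effective diffusion coefficient in the ECF, m²/s.
    v : float
        Bulk-flow speed of the ECF, directed along +x, m/s.
    P : float
        Blood-brain-barrier permeability, m/s.
    k1on, k1off, B1max : float
        Specific (target) binding: association rate constant (µmol/L·s)⁻¹,
        dissociation rate constant s⁻¹, total binding-site concentration
        µmol/L.
    k2on, k2off, B2max : float
        Non-specific binding analogues, same units.
    """

    D_eff: float = 5e-11
    v: float = 5e-7
    P: float = 1e-9
    k1on: float = 1.0
    k1off: float = 1e-2
    B1max: float = 5e-2
    k2on: float = 1e-2
    k2off: float = 1.0
    B2max: float = 50.0

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if not math.isfinite(val):
                raise ValueError(f"DrugParams.{f.name} must be finite, got {val!r}")
            if val < 0:
                raise ValueError(f"DrugParams.{f.name} must be >= 0, got {val!r}")

    @property
    def Kd1(self) -> float:
        """Specific dissociation constant k1off/k1on, µmol/L."""
        if self.k1on == 0:
            raise ZeroDivisionError("Kd1 undefined for k1on = 0")
        return self.k1off / self.k1on

    @property
    def Kd2(self) -> float:
        """Non-specific dissociation constant k2off/k2on, µmol/L."""
        if self.k2on == 0:
            raise ZeroDivisionError("Kd2 undefined for k2on = 0")
        return self.k2off / self.k2on

    def with_(self, **overrides: float) -> "DrugParams":
        return replace(self, **overrides)


@dataclass(frozen=True)
class DosingParams:
    """Plasma forcing constants.

    route is 'oral' (two-exponential absorption/elimination profile, the
    default used in every scenario) or 'iv' (single-exponential decay from
    C0 = Dose/V).
    """

    route: Literal["oral", "iv"] = "oral"
    F: float = 1.0
    Dose: float = 30.0
    ka: float = 2e-4
    ke: float = 5e-5
    V: float = 20.0

    def __post_init__(self) -> None:
        if self.route not in ("oral", "iv"):
            raise ValueError(f"route must be 'oral' or 'iv', got {self.route!r}")
        if not 0.0 <= self.F <= 1.0:
            raise ValueError(f"F must lie in [0, 1], got {self.F!r}")
        if self.Dose <= 0:
            raise ValueError(f"Dose must be > 0, got {self.Dose!r}")
        if self.V <= 0:
            raise ValueError(f"V must be > 0, got {self.V!r}")
        if self.ka < 0 or self.ke < 0:
            raise ValueError("ka and ke must be >= 0")

    @property
    def C0(self) -> float:
        """Initial plasma concentration Dose/V, µmol/L."""
        return self.Dose / self.V

    def with_(self, **overrides) -> "DosingParams":
        return replace(self, **overrides)


@dataclass(frozen=True)
class Domain:
    """Physical extent and node counts of the square tissue unit.

    The unit spans [0, xr] × [0, yr] with (0, 0) in the lower-left corner;
    capillary walls coincide with all four boundaries.
    """

    xr: float = 50e-6
    yr: float = 50e-6
    nx: int = 51
    ny: int = 51

    def __post_init__(self) -> None:
        if self.xr <= 0 or self.yr <= 0:
            raise ValueError("xr and yr must be > 0")
        if self.nx < 3 or self.ny < 3:
            raise ValueError("nx and ny must be >= 3")

    @property
    def hx(self) -> float:
        return self.xr / (self.nx - 1)

    @property
    def hy(self) -> float:
        return self.yr / (self.ny - 1)

    def with_(self, **overrides) -> "Domain":
        return replace(self, **overrides)


@dataclass(frozen=True)
class RangeTable:
    """Per-parameter physiological (low, high) bounds.

    Entries flagged in ``inconsistent`` are stored exactly as published even
    though low > high (known inconsistency in the source table); they are
    reported but never used to hard-fail validation.
    """

    ranges: dict = field(default_factory=dict)
    inconsistent: frozenset = frozenset()

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if name not in self.inconsistent and lo > hi:
                raise ValueError(f"range for {name} has low > high: ({lo}, {hi})")


def physiological_ranges() -> RangeTable:
    """Literature-based physiological ranges for the checked parameters.

    No ranges exist for the non-specific binding constants (k2on, k2off,
    B2max); those parameters are reported as 'unchecked'. The ke row is
    stored as published — "1e-1 – 5e-3 s⁻¹" — with low > high, and flagged.
    """
    return RangeTable(
        ranges={
            "D_eff": (1e-11, 1e-10),
            "v": (5e-8, 5e-6),
            "P": (1e-10, 1e-5),
            "B1max": (1e-3, 5e-1),
            "k1on": (1e-4, 1e3),
            "k1off": (1e-6, 1e1),
            "F": (0.0, 1.0),
            "Dose": (1e-1, 5e3),
            "ka": (0.0, 2e-3),
            "ke": (1e-1, 5e-3),  # as published; low > high
            "V": (0.01, 50e3),
        },
        inconsistent=frozenset({"ke"}),
    )


@dataclass(frozen=True)
class ParamCheck:
    name: str
    value: float
    status: Literal["in_range", "out_of_range", "unchecked", "range_inconsistent"]
    low: float | None = None
    high: float | None = None


@dataclass(frozen=True)
class ValidationReport:
    checks: tuple

    @property
    def out_of_range(self) -> tuple:
        return tuple(c for c in self.checks if c.status == "out_of_range")

    @property
    def all_in_range(self) -> bool:
        return all(c.status != "out_of_range" for c in self.checks)

    def by_name(self, name: str) -> ParamCheck:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)


def default_params() -> tuple[DrugParams, DosingParams, Domain]:
    """The canonical default parameter set (rat brain, oral dosing)."""
    return DrugParams(), DosingParams(), Domain()


def spatial_experiment_params() -> tuple[DrugParams, DosingParams, Domain]:
    """Defaults overridden for the spatial-distribution experiment.

    Slower diffusion, higher dose/permeability and stronger, more abundant
    binding exaggerate local concentration differences within the unit.
    """
    dp, dos, dom = default_params()
    dp = dp.with_(D_eff=5e-12, P=1e-7, k1on=10.0, B1max=1e-1, B2max=100.0)
    dos = dos.with_(Dose=100.0)
    return dp, dos, dom


def validate_params(
    dp: DrugParams,
    dos: DosingParams,
    ranges: RangeTable | None = None,
) -> ValidationReport:
    """Check every parameter against its physiological range.

    Out-of-range values yield warnings in the report, never a hard failure:
    sensitivity sweeps deliberately exceed the physiological bounds (e.g.
    ×100 multipliers on B1max). Negative values are rejected at dataclass
    construction, so by the time a params object exists it is sign-valid.
    Pure function: identical inputs give identical reports.
    """
    if ranges is None:
        ranges = physiological_ranges()
    values = {
        "D_eff": dp.D_eff,
        "v": dp.v,
        "P": dp.P,
        "B1max": dp.B1max,
        "k1on": dp.k1on,
        "k1off": dp.k1off,
        "k2on": dp.k2on,
        "k2off": dp.k2off,
        "B2max": dp.B2max,
        "F": dos.F,
        "Dose": dos.Dose,
        "ka": dos.ka,
        "ke": dos.ke,
        "V": dos.V,
    }
    checks = []
    for name, value in values.items():
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value!r}")
        if name not in ranges.ranges:
            checks.append(ParamCheck(name, value, "unchecked"))
            continue
        lo, hi = ranges.ranges[name]
        if name in ranges.inconsistent:
            checks.append(ParamCheck(name, value, "range_inconsistent", lo, hi))
        elif lo <= value <= hi:
            checks.append(ParamCheck(name, value, "in_range", lo, hi))
        else:
            checks.append(ParamCheck(name, value, "out_of_range", lo, hi))
    return ValidationReport(checks=tuple(checks))


def tortuosity_to_Deff(D: float, lam: float) -> float:
    """Effective diffusion coefficient D/λ² from free diffusion and tortuosity."""
    if D <= 0:
        raise ValueError(f"D must be > 0, got {D!r}")
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam!r}")
    return D / lam**2
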