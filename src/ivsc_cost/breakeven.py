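"""Break-even analysis: total cost as an affine function of mean weight.

With the cycle structure frozen at the cohort's observed counts, only the
IV drug (and its waste) depends on body weight: each IV cycle delivers a
fixed mg/kg coefficient, so the cohort's IV drug mass is

    total_mg = w_mean * sum(count * mg_per_kg)  over IV cycles,

which makes every scenario's total cost affine in the mean weight w:

    C(w) = slope * w + intercept,
    slope = iv_price * per_kg_dose_total * (1 + waste_fraction),
    intercept = SC drug + preparation + clinic costs (weight-independent).

An all-SC scenario has zero slope (fixed 600 mg dosing).  The crossing of
the all-IV and all-SC lines is the break-even mean weight above which the
fixed-dose SC strategy is the cheaper one.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .costing import UnitCosts
from .dosing import Cadence, DoseSchedule, Role, ScenarioId

__all__ = [
    "CalibrationError",
    "AffineCostCurve",
    "CalibrationResult",
    "CycleStructure",
    "calibrate_per_kg",
    "cost_curve",
    "breakeven_weight",
    "curve_table",
]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationResult:
    """Links cycle counts to administered IV mass via the dose schedule."""

    per_kg_dose_total: float  # sum over IV cycles of mg/kg coefficients
    implied_mean_weight_kg: float  # total IV mg / per_kg_dose_total


@dataclass(frozen=True)
class CycleStructure:
    """Frozen per-scenario cycle counts used to build a cost curve.

    ``iv_counts`` maps (cadence, role) to IV cycle counts; ``sc_cycles``
    is the number of fixed-dose SC cycles.
    """

    iv_counts: Mapping[tuple[Cadence, Role], int] = field(default_factory=dict)
    sc_cycles: int = 0

    def iv_total(self) -> int:
        return sum(self.iv_counts.values())


@dataclass(frozen=True)
class AffineCostCurve:
    scenario: ScenarioId
    slope_eur_per_kg: float
    intercept_eur: float
    validity_range_kg: tuple[float, float] = (40.0, 100.0)

    def __post_init__(self) -> None:
        if self.slope_eur_per_kg < 0:
            raise ValueError("slope must be non-negative")
        lo, hi = self.validity_range_kg
        if lo >= hi:
            raise ValueError("validity range must be ordered")

    def cost_at(self, weight_kg: float) -> float:
        return self.slope_eur_per_kg * weight_kg + self.intercept_eur


def calibrate_per_kg(
    cycle_counts: Mapping[tuple[Cadence, Role], int],
    schedule: DoseSchedule | None = None,
    total_iv_mg: float | None = None,
) -> CalibrationResult:
    """Per-kg dose total from IV cycle counts, and the implied mean weight.

    ``per_kg_dose_total = sum(count * mg_per_kg)``; dividing the observed
    total IV mass by it recovers the (dose-weighted) mean body weight of
    the cohort, which is not reported directly.
    """
    schedule = schedule or DoseSchedule()
    if any(c < 0 for c in cycle_counts.values()):
        raise ValueError("cycle counts must be non-negative")
    per_kg = sum(
        count * schedule.mg_per_kg(Cadence(cad), Role(role))
        for (cad, role), count in cycle_counts.items()
    )
    if per_kg <= 0:
        raise CalibrationError("zero per-kg dose total: no IV cycles to calibrate on")
    if total_iv_mg is None:
        raise CalibrationError("total_iv_mg required")
    if total_iv_mg <= 0:
        raise CalibrationError("total_iv_mg must be positive")
    return CalibrationResult(
        per_kg_dose_total=per_kg,
        implied_mean_weight_kg=total_iv_mg / per_kg,
    )


def _admin_hours(structure: CycleStructure, costs: UnitCosts) -> float:
    minutes = 0.0
    for (cad, role), count in structure.iv_counts.items():
        per = (
            costs.admin_minutes_iv_loading
            if Role(role) is Role.LOADING
            else costs.admin_minutes_iv_maintenance
        )
        minutes += count * per
    minutes += structure.sc_cycles * costs.admin_minutes_sc
    return minutes / 60.0


def cost_curve(
    scenario: ScenarioId | int,
    structure: CycleStructure,
    schedule: DoseSchedule | None = None,
    costs: UnitCosts | None = None,
    validity_range_kg: tuple[float, float] = (40.0, 100.0),
) -> AffineCostCurve:
    """Affine total-cost-vs-mean-weight curve for a frozen cycle structure.

    The weight-dependent part is the IV drug plus its waste; SC drug,
    preparation and clinic occupancy form the intercept.
    """
    scenario = ScenarioId(scenario)
    schedule = schedule or DoseSchedule()
    costs = costs or UnitCosts()

    per_kg = sum(
        count * schedule.mg_per_kg(Cadence(cad), Role(role))
        for (cad, role), count in structure.iv_counts.items()
    )
    slope = costs.iv_eur_per_mg * per_kg * (1.0 + costs.waste_fraction)

    sc_drug = structure.sc_cycles * schedule.sc_fixed_mg * costs.sc_eur_per_mg
    prep = (
        structure.iv_total() * costs.prep_cost_iv_per_cycle_eur
        + structure.sc_cycles * costs.prep_cost_sc_per_cycle_eur
    )
    clinic = _admin_hours(structure, costs) * costs.clinic_eur_per_hour
    return AffineCostCurve(
        scenario=scenario,
        slope_eur_per_kg=slope,
        intercept_eur=sc_drug + prep + clinic,
        validity_range_kg=validity_range_kg,
    )


def breakeven_weight(
    curve_a: AffineCostCurve, curve_b: AffineCostCurve
) -> float | tuple[float, float] | None:
    """Mean weight at which two cost curves intersect.

    Returns ``None`` for parallel curves with unequal intercepts and the
    shared validity range for identical curves.  The intersection is
    returned even if it lies outside the validity range (callers may want
    to know where extrapolated lines cross).
    """
    dslope = curve_a.slope_eur_per_kg - curve_b.slope_eur_per_kg
    dint = curve_b.intercept_eur - curve_a.intercept_eur
    if dslope == 0.0:
        if dint == 0.0:
            lo = max(curve_a.validity_range_kg[0], curve_b.validity_range_kg[0])
            hi = min(curve_a.validity_range_kg[1], curve_b.validity_range_kg[1])
            return (lo, hi)
        return None
    return dint / dslope


def curve_table(
    curves: Sequence[AffineCostCurve], weight_grid: Sequence[float]
) -> pd.DataFrame:
    """Total cost per scenario evaluated on a grid of mean weights."""
    rows = [
        {
            "weight_kg": float(w),
            **{
                f"scenario_{int(c.scenario)}_eur": c.cost_at(float(w)) for c in curves
            },
        }
        for w in weight_grid
    ]
    cols = ["weight_kg"] + [f"scenario_{int(c.scenario)}_eur" for c in curves]
    return pd.DataFrame(rows, columns=cols)
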