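"""Dosing rules and scenario cycle planning.

Trastuzumab is dosed two ways: the intravenous (IV) formulation is
weight-based (mg per kg of body weight, with a larger loading dose at
treatment start), while the subcutaneous (SC) formulation is a fixed
600 mg injection regardless of weight.  Three treatment scenarios are
modelled for a cohort:

  1. all cycles IV at their original cadence;
  2. all cycles SC — weekly IV blocks collapse 3:1 into every-three-weeks
     (q3w) SC cycles, q3w cycles map one-to-one;
  3. IV kept during chemotherapy (the weekly phases), SC afterwards
     (the q3w phases, mapped one-to-one).

This module turns a cohort's schedule phases into per-cycle plans for a
chosen scenario and tallies drug mass by formulation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import Cohort

__all__ = [
    "Cadence",
    "Role",
    "Formulation",
    "ScenarioId",
    "DoseSchedule",
    "CyclePlan",
    "DrugTotals",
    "DEFAULT_ADMIN_MINUTES",
    "iv_dose_mg",
    "convert_weekly_block_to_sc",
    "plan_scenario",
    "tally_drug",
]


class Cadence(str, Enum):
    """Administration cadence: weekly (during chemo) or every 3 weeks."""

    WEEKLY = "weekly"
    Q3W = "q3w"


class Role(str, Enum):
    """Loading (first) dose vs recurring maintenance dose."""

    LOADING = "loading"
    MAINTENANCE = "maintenance"


class Formulation(str, Enum):
    IV = "IV"
    SC = "SC"


class ScenarioId(int, Enum):
    """The three counterfactual treatment scenarios."""

    IV_ONLY = 1
    SC_ONLY = 2
    IV_THEN_SC = 3


#: Chair/administration time per cycle in minutes: IV loading infusions run
#: at least 90 min, IV maintenance 30 min, an SC injection takes 5 min.
DEFAULT_ADMIN_MINUTES: Mapping[tuple[Formulation, Role], float] = {
    (Formulation.IV, Role.LOADING): 90.0,
    (Formulation.IV, Role.MAINTENANCE): 30.0,
    (Formulation.SC, Role.LOADING): 5.0,
    (Formulation.SC, Role.MAINTENANCE): 5.0,
}


@dataclass(frozen=True)
class DoseSchedule:
    """mg/kg coefficients for IV dosing and the fixed SC dose.

    The weekly 2 mg/kg maintenance (4 mg/kg loading) applies during
    chemotherapy; the q3w regimen is the label-standard 8 mg/kg loading
    followed by 6 mg/kg maintenance.  All values are configurable for
    sensitivity analyses.
    """

    weekly_loading_mg_per_kg: float = 4.0
    weekly_maintenance_mg_per_kg: float = 2.0
    q3w_loading_mg_per_kg: float = 8.0
    q3w_maintenance_mg_per_kg: float = 6.0
    sc_fixed_mg: float = 600.0

    def __post_init__(self) -> None:
        for name in (
            "weekly_loading_mg_per_kg",
            "weekly_maintenance_mg_per_kg",
            "q3w_loading_mg_per_kg",
            "q3w_maintenance_mg_per_kg",
            "sc_fixed_mg",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.weekly_loading_mg_per_kg < self.weekly_maintenance_mg_per_kg:
            raise ValueError("weekly loading dose below maintenance dose")
        if self.q3w_loading_mg_per_kg < self.q3w_maintenance_mg_per_kg:
            raise ValueError("q3w loading dose below maintenance dose")

    def mg_per_kg(self, cadence: Cadence, role: Role) -> float:
        table = {
            (Cadence.WEEKLY, Role.LOADING): self.weekly_loading_mg_per_kg,
            (Cadence.WEEKLY, Role.MAINTENANCE): self.weekly_maintenance_mg_per_kg,
            (Cadence.Q3W, Role.LOADING): self.q3w_loading_mg_per_kg,
            (Cadence.Q3W, Role.MAINTENANCE): self.q3w_maintenance_mg_per_kg,
        }
        try:
            return table[(Cadence(cadence), Role(role))]
        except (KeyError, ValueError) as exc:
            raise ValueError(f"unknown cadence/role: {cadence!r}/{role!r}") from exc


@dataclass(frozen=True)
class CyclePlan:
    """One administration event (one preparation + one infusion/injection)."""

    patient_id: str
    formulation: Formulation
    role: Role
    cadence: Cadence
    dose_mg: float
    admin_minutes: float
    prep_seconds_effective: float | None = None

    def __post_init__(self) -> None:
        if self.dose_mg <= 0:
            raise ValueError("dose_mg must be positive")
        if self.admin_minutes < 0:
            raise ValueError("admin_minutes must be non-negative")


@dataclass(frozen=True)
class DrugTotals:
    """Drug mass tallies by formulation with the IV-to-SC dose gap."""

    iv_mg: float
    sc_mg: float
    iv_cycles: int
    sc_cycles: int
    delta_mg: float
    delta_pct: float
    by_quartile: tuple[dict, ...] = field(default_factory=tuple)


def iv_dose_mg(
    weight_kg: float,
    cadence: Cadence,
    role: Role,
    schedule: DoseSchedule | None = None,
) -> float:
    """Weight-based IV dose in mg: weight x the matching mg/kg coefficient.

    Exact arithmetic with no vial rounding — robotic preparation draws the
    exact prescribed amount.
    """
    if weight_kg <= 0:
        raise ValueError("weight_kg must be strictly positive")
    schedule = schedule or DoseSchedule()
    return weight_kg * schedule.mg_per_kg(cadence, role)


def convert_weekly_block_to_sc(n_weekly_cycles: int) -> int:
    """Number of q3w SC cycles replacing a block of weekly IV cycles.

    Three weekly preparations convert into one SC administration given
    every 3 weeks; a partial remainder block still needs one SC cycle,
    hence ceiling division.
    """
    if n_weekly_cycles < 0:
        raise ValueError("n_weekly_cycles must be non-negative")
    return math.ceil(n_weekly_cycles / 3)


def _iv_plan(
    patient_id: str,
    weight_kg: float,
    cadence: Cadence,
    role: Role,
    schedule: DoseSchedule,
    admin_minutes: Mapping[tuple[Formulation, Role], float],
) -> CyclePlan:
    return CyclePlan(
        patient_id=patient_id,
        formulation=Formulation.IV,
        role=role,
        cadence=cadence,
        dose_mg=iv_dose_mg(weight_kg, cadence, role, schedule),
        admin_minutes=admin_minutes[(Formulation.IV, role)],
    )


def _sc_plan(
    patient_id: str,
    role: Role,
    schedule: DoseSchedule,
    admin_minutes: Mapping[tuple[Formulation, Role], float],
) -> CyclePlan:
    # SC has no pharmacological loading dose: every cycle is the fixed
    # 600 mg / 5 min injection; the role label is kept for bookkeeping only.
    return CyclePlan(
        patient_id=patient_id,
        formulation=Formulation.SC,
        role=role,
        cadence=Cadence.Q3W,
        dose_mg=schedule.sc_fixed_mg,
        admin_minutes=admin_minutes[(Formulation.SC, role)],
    )


def plan_scenario(
    cohort: "Cohort",
    scenario: ScenarioId | int,
    schedule: DoseSchedule | None = None,
    admin_minutes: Mapping[tuple[Formulation, Role], float] | None = None,
) -> list[CyclePlan]:
    """Expand a cohort into the per-cycle plans of one scenario.

    Scenario 1 keeps every phase cycle IV at its cadence.  Scenario 2
    converts each weekly phase 3:1 (ceiling) into SC cycles and maps q3w
    cycles 1:1 to SC.  Scenario 3 keeps weekly phases IV and maps q3w
    phases 1:1 to SC.  Loading events are data (part of the phase), never
    synthesized here.
    """
    scenario = ScenarioId(scenario)
    schedule = schedule or DoseSchedule()
    admin = dict(DEFAULT_ADMIN_MINUTES)
    if admin_minutes:
        admin.update(admin_minutes)

    plans: list[CyclePlan] = []
    for patient in cohort.patients:
        for phase in patient.phases:
            roles = [Role.LOADING] * phase.n_loading + [
                Role.MAINTENANCE
            ] * phase.n_maintenance
            if not roles:
                continue
            cadence = Cadence(phase.cadence)
            if scenario is ScenarioId.IV_ONLY:
                to_iv = roles
            elif scenario is ScenarioId.SC_ONLY:
                if cadence is Cadence.WEEKLY:
                    n_sc = convert_weekly_block_to_sc(len(roles))
                    sc_roles = [roles[0]] + [Role.MAINTENANCE] * (n_sc - 1)
                else:
                    sc_roles = roles
                plans.extend(
                    _sc_plan(patient.id, r, schedule, admin) for r in sc_roles
                )
                continue
            else:  # IV_THEN_SC
                if cadence is Cadence.WEEKLY:
                    to_iv = roles
                else:
                    plans.extend(
                        _sc_plan(patient.id, r, schedule, admin) for r in roles
                    )
                    continue
            plans.extend(
                _iv_plan(patient.id, patient.weight_kg, cadence, r, schedule, admin)
                for r in to_iv
            )
    return plans


def tally_drug(
    plans: Sequence[CyclePlan],
    cohort: "Cohort | None" = None,
) -> DrugTotals:
    """Sum drug mass by formulation and compute the IV-vs-SC dose gap.

    ``delta_mg`` is SC minus IV mass; ``delta_pct`` expresses it relative
    to the IV mass.  When a cohort is supplied, per-weight-quartile
    subtotals are attached (patients grouped by the cohort's quartile
    bounds) for the dose-per-quartile table replica.
    """
    if not plans:
        raise ValueError("plans must be non-empty")
    iv_mg = sum(p.dose_mg for p in plans if p.formulation is Formulation.IV)
    sc_mg = sum(p.dose_mg for p in plans if p.formulation is Formulation.SC)
    iv_cycles = sum(1 for p in plans if p.formulation is Formulation.IV)
    sc_cycles = sum(1 for p in plans if p.formulation is Formulation.SC)
    delta_mg = sc_mg - iv_mg
    delta_pct = 100.0 * delta_mg / iv_mg if iv_mg else math.nan

    by_quartile: tuple[dict, ...] = ()
    if cohort is not None:
        by_quartile = _quartile_subtotals(plans, cohort)
    return DrugTotals(
        iv_mg=iv_mg,
        sc_mg=sc_mg,
        iv_cycles=iv_cycles,
        sc_cycles=sc_cycles,
        delta_mg=delta_mg,
        delta_pct=delta_pct,
        by_quartile=by_quartile,
    )


def _quartile_subtotals(
    plans: Iterable[CyclePlan], cohort: "Cohort"
) -> tuple[dict, ...]:
    from .cohort import summarize_cohort

    q1, q2, q3 = summarize_cohort(cohort).weight_quartile_bounds
    wmax = max(p.weight_kg for p in cohort.patients)

    def bucket(w: float) -> int:
        if w <= q1:
            return 0
        if w <= q2:
            return 1
        if w <= q3:
            return 2
        return 3

    weight = {p.id: p.weight_kg for p in cohort.patients}
    rows = [
        {"quartile": lab, "bound_kg": b, "iv_mg": 0.0, "sc_mg": 0.0}
        for lab, b in zip(("Q1", "Q2", "Q3", "Q4"), (q1, q2, q3, wmax))
    ]
    for p in plans:
        row = rows[bucket(weight[p.patient_id])]
        key = "iv_mg" if p.formulation is Formulation.IV else "sc_mg"
        row[key] += p.dose_mg
    for row in rows:
        row["delta_mg"] = row["sc_mg"] - row["iv_mg"]
    return tuple(rows)
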