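"""Pipeline orchestration, configuration, and report serialization.

``run_pipeline`` ties the model together: acquire a cohort (file,
synthetic, or the bundled reference), evaluate the requested scenarios,
emit the table replicas, the break-even analysis, and the ANOVA /
Bonferroni statistics block, and return one structured report document.
All randomness flows from a single seed; the serialized report is
byte-identical across runs with the same config and seed.

Euro amounts are kept unrounded internally; ``round_half_up`` implements
the half-away-from-zero convention used when printing (1,612,274.50
prints as 1,612,275, not banker's 1,612,274).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
import tempfile
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .breakeven import CycleStructure, breakeven_weight, calibrate_per_kg, cost_curve
from .cohort import (
    Cohort,
    SyntheticCohortParams,
    WeightDistribution,
    SchemeMix,
    CourseLengths,
    generate_cohort,
    load_cohort,
    reference_cohort,
    summarize_cohort,
)
from .costing import ScenarioResult, UnitCosts, evaluate_scenario, scenario_tables
from .dosing import Cadence, DoseSchedule, Role, ScenarioId
from .stats import bonferroni_pairwise, one_way_anova

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "round_half_up",
    "run_pipeline",
    "write_report",
    "read_report",
]

logger = logging.getLogger("ivsc_cost")

SCHEMA_VERSION = 1


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    x = float(x)
    if not math.isfinite(x):
        return x
    # pre-round at 6 dp so accumulated float noise cannot flip a .5 boundary
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(round(x, 6))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: cohort source, overrides, scenarios, outputs."""

    cohort_source: str = "reference"  # "reference", "synthetic", or a file path
    synthetic_params: SyntheticCohortParams | None = None
    schedule: DoseSchedule = field(default_factory=DoseSchedule)
    costs: UnitCosts = field(default_factory=UnitCosts)
    scenarios: tuple[int, ...] = (1, 2, 3)
    seed: int = 0
    output_dir: Path | None = None
    report_formats: tuple[str, ...] = ("json",)

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValueError("scenario list must be non-empty")
        if any(s not in (1, 2, 3) for s in self.scenarios):
            raise ValueError("scenarios must be a subset of {1, 2, 3}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config file with sections cohort/dosing/costs/report."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_cfg = raw.get("cohort", {}) or {}
        source = cohort_cfg.get("source", "reference")
        synth = None
        if source == "synthetic":
            sp = dict(cohort_cfg.get("params", {}) or {})
            for key, klass in (
                ("weight_distribution", WeightDistribution),
                ("scheme_mix", SchemeMix),
                ("course_lengths", CourseLengths),
            ):
                if key in sp:
                    sp[key] = klass(**sp[key])
            synth = SyntheticCohortParams(**sp)
        report_cfg = raw.get("report", {}) or {}
        return cls(
            cohort_source=source,
            synthetic_params=synth,
            schedule=DoseSchedule(**(raw.get("dosing", {}) or {})),
            costs=UnitCosts(**(raw.get("costs", {}) or {})),
            scenarios=tuple(raw.get("scenarios", (1, 2, 3))),
            seed=int(raw.get("seed", 0)),
            output_dir=Path(report_cfg["output_dir"]) if "output_dir" in report_cfg else None,
            report_formats=tuple(report_cfg.get("formats", ("json",))),
        )


def _acquire_cohort(config: RunConfig) -> Cohort:
    if config.cohort_source == "reference":
        return reference_cohort()
    if config.cohort_source == "synthetic":
        params = config.synthetic_params or SyntheticCohortParams(seed=config.seed)
        if config.seed and params.seed != config.seed:
            params = dataclasses.replace(params, seed=config.seed)
        return generate_cohort(params)
    return load_cohort(config.cohort_source)


def _breakdown_dict(bd) -> dict[str, float]:
    return {
        "drug_eur": bd.drug_eur,
        "waste_eur": bd.waste_eur,
        "prep_eur": bd.prep_eur,
        "clinic_eur": bd.clinic_eur,
        "global_eur": bd.global_eur,
    }


def _scenario_dict(result: ScenarioResult) -> dict[str, Any]:
    dt = result.drug_totals
    return {
        "scenario": int(result.scenario),
        "n_patients": result.n_patients,
        "totals": _breakdown_dict(result.totals),
        "mean_global_eur": result.mean_global_eur,
        "per_patient": {
            pid: _breakdown_dict(bd) for pid, bd in sorted(result.per_patient.items())
        },
        "time_profile": dataclasses.asdict(result.time_profile),
        "drug_totals": {
            "iv_mg": dt.iv_mg,
            "sc_mg": dt.sc_mg,
            "iv_cycles": dt.iv_cycles,
            "sc_cycles": dt.sc_cycles,
            "delta_mg": dt.delta_mg,
            "delta_pct": dt.delta_pct,
            "by_quartile": [dict(q) for q in dt.by_quartile],
        },
    }


def _iv_cycle_counts(cohort: Cohort) -> dict[tuple[Cadence, Role], int]:
    counts: dict[tuple[Cadence, Role], int] = {}
    for p in cohort.patients:
        for ph in p.phases:
            for role, n in ((Role.LOADING, ph.n_loading), (Role.MAINTENANCE, ph.n_maintenance)):
                if n:
                    key = (Cadence(ph.cadence), role)
                    counts[key] = counts.get(key, 0) + n
    return counts


def _breakeven_block(
    cohort: Cohort,
    results: Mapping[int, ScenarioResult],
    config: RunConfig,
) -> dict[str, Any] | None:
    """Scenario 1 vs 2 break-even from the cohort's frozen cycle structure."""
    if 1 not in results or 2 not in results:
        return None
    counts = _iv_cycle_counts(cohort)
    total_iv_mg = results[1].drug_totals.iv_mg
    calibration = calibrate_per_kg(counts, config.schedule, total_iv_mg)
    curve1 = cost_curve(
        ScenarioId.IV_ONLY,
        CycleStructure(iv_counts=counts, sc_cycles=0),
        config.schedule,
        config.costs,
    )
    curve2 = cost_curve(
        ScenarioId.SC_ONLY,
        CycleStructure(iv_counts={}, sc_cycles=results[2].drug_totals.sc_cycles),
        config.schedule,
        config.costs,
    )
    be = breakeven_weight(curve1, curve2)
    return {
        "calibration": {
            "per_kg_dose_total": calibration.per_kg_dose_total,
            "implied_mean_weight_kg": calibration.implied_mean_weight_kg,
        },
        "curves": [
            {
                "scenario": int(c.scenario),
                "slope_eur_per_kg": c.slope_eur_per_kg,
                "intercept_eur": c.intercept_eur,
            }
            for c in (curve1, curve2)
        ],
        "breakeven_weight_kg": be if isinstance(be, (float, type(None))) else list(be),
    }


def _stats_block(results: Mapping[int, ScenarioResult]) -> dict[str, Any]:
    """ANOVA + Bonferroni across scenarios for each per-patient cost vector."""
    if len(results) < 2:
        return {}
    if any(r.n_patients < 2 for r in results.values()):
        return {"note": "statistics require at least 2 patients per scenario"}
    ordered = [results[s] for s in sorted(results)]
    labels = [int(r.scenario) for r in ordered]
    block: dict[str, Any] = {"scenarios": labels}
    metrics = {
        "direct_cost": lambda bd: bd.drug_eur + bd.waste_eur,
        "prep_cost": lambda bd: bd.prep_eur,
        "clinic_cost": lambda bd: bd.clinic_eur,
        "global_cost": lambda bd: bd.global_eur,
    }
    for name, extract in metrics.items():
        groups = [[extract(bd) for _, bd in sorted(r.per_patient.items())] for r in ordered]
        anova = one_way_anova(groups)
        posthoc = bonferroni_pairwise(groups, omnibus=anova)
        block[name] = {
            "anova": {
                "f": anova.f_statistic,
                "df_between": anova.df_between,
                "df_within": anova.df_within,
                "p": anova.p_value,
                "group_means": list(anova.group_means),
                "group_sds": list(anova.group_sds),
            },
            "posthoc": {
                "ran": posthoc.ran,
                "pairs": [
                    [labels[i], labels[j]] for i, j in posthoc.pairs
                ] if posthoc.ran else [],
                "p_raw": list(posthoc.p_raw) if posthoc.ran else [],
                "p_adjusted": list(posthoc.p_adjusted) if posthoc.ran else [],
                "significant": list(posthoc.significant) if posthoc.ran else [],
            },
        }
    return block


def run_pipeline(config: RunConfig | None = None) -> dict[str, Any]:
    """Run the full model and return the structured report document."""
    config = config or RunConfig()
    cohort = _acquire_cohort(config)
    summary = summarize_cohort(cohort)
    logger.info(
        "cohort acquired: %d patients, %d IV cycles (%s)",
        summary.n_patients,
        summary.total_iv_cycles,
        cohort.label or config.cohort_source,
    )

    results: dict[int, ScenarioResult] = {}
    for s in config.scenarios:
        res = evaluate_scenario(cohort, s, config.schedule, config.costs)
        results[s] = res
        logger.info(
            "scenario %d: %d IV + %d SC cycles, global cost %.2f EUR",
            s,
            res.drug_totals.iv_cycles,
            res.drug_totals.sc_cycles,
            res.totals.global_eur,
        )

    ordered = [results[s] for s in sorted(results)]
    tables = scenario_tables(ordered, config.costs)
    breakeven = _breakeven_block(cohort, results, config)
    if breakeven is not None:
        logger.info("break-even weight: %s kg", breakeven["breakeven_weight_kg"])
    stats = _stats_block(results)

    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "label": cohort.label,
        "seed": config.seed,
        "cohort_summary": dataclasses.asdict(summary),
        "scenarios": {str(s): _scenario_dict(results[s]) for s in sorted(results)},
        "tables": {
            name: df.to_dict(orient="records") for name, df in tables.items()
        },
        "breakeven": breakeven,
        "stats": stats,
    }
    if config.output_dir is not None:
        _emit_outputs(report, tables, config)
    return report


def _emit_outputs(
    report: Mapping[str, Any],
    tables: Mapping[str, pd.DataFrame],
    config: RunConfig,
) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_report(report, outdir / "report.json")
    if "csv" in config.report_formats:
        for name, df in tables.items():
            _atomic_write_text(outdir / f"{name}.csv", df.to_csv(index=False))
    if "txt" in config.report_formats:
        lines = []
        for name, df in tables.items():
            shown = df.copy()
            for col in shown.columns:
                if shown[col].dtype.kind != "f":
                    continue
                # hours print as whole hours, euro/percent columns at 1 dp
                if "hours" in col:
                    fmt = lambda v: f"{round_half_up(v):,.0f}" if pd.notna(v) else ""
                else:
                    fmt = lambda v: f"{round_half_up(v, 1):,.1f}" if pd.notna(v) else ""
                shown[col] = shown[col].map(fmt)
            lines.append(f"== {name} ==\n{shown.to_string(index=False)}\n")
        _atomic_write_text(outdir / "tables.txt", "\n".join(lines))


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------

_NAN_SENTINEL = "NaN"


def _sanitize(obj: Any) -> Any:
    if isinstance(obj, float) and math.isnan(obj):
        return _NAN_SENTINEL
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    return obj


def _restore(obj: Any) -> Any:
    if obj == _NAN_SENTINEL:
        return math.nan
    if isinstance(obj, dict):
        return {k: _restore(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_restore(v) for v in obj]
    return obj


def _atomic_write_text(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_report(report: Mapping[str, Any], path: str | Path) -> None:
    """Serialize a report to JSON (lossless floats, NaN as explicit marker).

    Written via a temporary file and atomic rename so a failed run never
    leaves a truncated report behind.
    """
    path = Path(path)
    text = json.dumps(_sanitize(dict(report)), indent=1, sort_keys=True, allow_nan=False)
    _atomic_write_text(path, text + "\n")


def read_report(path: str | Path) -> dict[str, Any]:
    """Load a report written by :func:`write_report`; checks schema version."""
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported report schema version {version!r} (expected {SCHEMA_VERSION})"
        )
    return _restore(data)
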