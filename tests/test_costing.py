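"""Cost accounting: unit operations, scenario evaluation, table replicas."""
import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivsc_cost import (
    Cohort,
    CostBreakdown,
    DoseSchedule,
    DrugTotals,
    Formulation,
    UnitCosts,
    admin_profile,
    clinic_cost,
    drug_cost,
    evaluate_scenario,
    plan_scenario,
    prep_profile,
    scenario_tables,
    waste_cost,
)


class TestUnitOperations:
    def test_drug_cost_iv(self):
        totals = DrugTotals(372214.0, 0.0, 1292, 0, -372214.0, -100.0)
        assert round(drug_cost(totals)["iv_eur"]) == 1544688

    def test_drug_cost_sc(self):
        totals = DrugTotals(0.0, 562200.0, 0, 937, 562200.0, float("nan"))
        assert round(drug_cost(totals)["sc_eur"]) == 1613514

    def test_drug_cost_zero(self):
        totals = DrugTotals(0.0, 0.0, 0, 0, 0.0, float("nan"))
        assert drug_cost(totals)["total_eur"] == 0.0

    def test_waste_is_fraction_of_iv_cost(self):
        assert round(waste_cost(1544688.0)) == 1699
        assert waste_cost(0.0) == 0.0

    def test_waste_scenario3_iv_portion(self):
        # 0.11% of the scenario-3 IV drug cost; the model yields ~355 EUR
        assert waste_cost(322497.0) == pytest.approx(354.7467)

    def test_waste_rejects_negative(self):
        with pytest.raises(ValueError):
            waste_cost(-1.0)

    def test_clinic_cost_uses_unrounded_hours(self):
        assert round(clinic_cost(731.0)) == 65644
        assert round(clinic_cost(937 * 5 / 60)) == 7012
        assert clinic_cost(0.0) == 0.0

    def test_prep_profile_reference_workloads(self, ref_cohort):
        costs = UnitCosts()
        iv_hours = prep_profile(plan_scenario(ref_cohort, 1), costs)["hours_total"]
        sc_hours = prep_profile(plan_scenario(ref_cohort, 2), costs)["hours_total"]
        mixed = prep_profile(plan_scenario(ref_cohort, 3), costs)["hours_total"]
        assert round(iv_hours) == 120
        assert round(sc_hours) == 34
        assert round(mixed) == 78

    def test_admin_profile_reference_workloads(self, ref_cohort):
        s1 = admin_profile(plan_scenario(ref_cohort, 1))["hours_total"]
        s2 = admin_profile(plan_scenario(ref_cohort, 2))["hours_total"]
        s3 = admin_profile(plan_scenario(ref_cohort, 3))["hours_total"]
        assert s1 == pytest.approx((85 * 90 + 1207 * 30) / 60)  # 731 h
        assert s2 == pytest.approx(937 * 5 / 60)  # 78.083 h
        assert s3 == pytest.approx((53 * 90 + 490 * 30 + 749 * 5) / 60)  # 386.9 h


class TestEvaluateScenario:
    def test_totals_equal_sum_of_per_patient(self, ref_cohort):
        res = evaluate_scenario(ref_cohort, 3)
        for fld in ("drug_eur", "waste_eur", "prep_eur", "clinic_eur"):
            total = getattr(res.totals, fld)
            summed = sum(getattr(bd, fld) for bd in res.per_patient.values())
            assert summed == pytest.approx(total, rel=1e-9)

    def test_additivity_of_global(self, ref_cohort):
        res = evaluate_scenario(ref_cohort, 1)
        bd = res.totals
        assert bd.global_eur == bd.drug_eur + bd.waste_eur + bd.prep_eur + bd.clinic_eur
        for pb in res.per_patient.values():
            assert pb.global_eur == pb.drug_eur + pb.waste_eur + pb.prep_eur + pb.clinic_eur

    def test_brute_force_ledger_equivalence(self, mixed_small_cohort):
        """Hand-rolled per-cycle ledger reproduces evaluate_scenario."""
        costs = UnitCosts()
        schedule = DoseSchedule()
        for scenario in (1, 2, 3):
            res = evaluate_scenario(mixed_small_cohort, scenario, schedule, costs)
            drug = waste = prep = clinic = 0.0
            for p in plan_scenario(
                mixed_small_cohort, scenario, schedule, costs.admin_minutes_map()
            ):
                if p.formulation is Formulation.IV:
                    d = p.dose_mg * costs.iv_eur_per_mg
                    waste += d * costs.waste_fraction
                    prep += costs.prep_cost_iv_per_cycle_eur
                else:
                    d = p.dose_mg * costs.sc_eur_per_mg
                    prep += costs.prep_cost_sc_per_cycle_eur
                drug += d
                clinic += (p.admin_minutes / 60.0) * costs.clinic_eur_per_hour
            assert res.totals.drug_eur == pytest.approx(drug, rel=1e-12)
            assert res.totals.waste_eur == pytest.approx(waste, rel=1e-12)
            assert res.totals.prep_eur == pytest.approx(prep, rel=1e-12)
            assert res.totals.clinic_eur == pytest.approx(clinic, rel=1e-12)

    def test_order_invariance_of_per_patient_sums(self, ref_cohort):
        import numpy as np

        rng = np.random.default_rng(3)
        shuffled = Cohort(
            patients=tuple(
                ref_cohort.patients[i] for i in rng.permutation(len(ref_cohort))
            ),
            label="shuffled",
        )
        a = evaluate_scenario(ref_cohort, 3)
        b = evaluate_scenario(shuffled, 3)
        assert a.per_patient == b.per_patient
        assert a.totals.global_eur == pytest.approx(b.totals.global_eur, rel=1e-12)

    def test_scenario2_invariant_under_weight_permutation(self, ref_cohort):
        import numpy as np

        rng = np.random.default_rng(5)
        weights = [p.weight_kg for p in ref_cohort.patients]
        permuted = Cohort(
            patients=tuple(
                dataclasses.replace(p, weight_kg=weights[j])
                for p, j in zip(ref_cohort.patients, rng.permutation(len(weights)))
            ),
            label="permuted-weights",
        )
        a = evaluate_scenario(ref_cohort, 2)
        b = evaluate_scenario(permuted, 2)
        assert a.totals == b.totals

    def test_cost_homogeneity_in_unit_prices(self, mixed_small_cohort):
        """Scaling every euro rate by k scales costs by k, times unchanged."""
        base = UnitCosts()
        k = 1.7
        scaled = dataclasses.replace(
            base,
            iv_eur_per_mg=base.iv_eur_per_mg * k,
            sc_eur_per_mg=base.sc_eur_per_mg * k,
            prep_cost_iv_per_cycle_eur=base.prep_cost_iv_per_cycle_eur * k,
            prep_cost_sc_per_cycle_eur=base.prep_cost_sc_per_cycle_eur * k,
            clinic_eur_per_hour=base.clinic_eur_per_hour * k,
            technician_eur_per_hour=base.technician_eur_per_hour * k,
            pharmacist_eur_per_hour=base.pharmacist_eur_per_hour * k,
        )
        a = evaluate_scenario(mixed_small_cohort, 1, costs=base)
        b = evaluate_scenario(mixed_small_cohort, 1, costs=scaled)
        assert b.totals.global_eur == pytest.approx(k * a.totals.global_eur, rel=1e-12)
        assert b.time_profile == a.time_profile


class TestScenarioTables:
    def test_reduction_percentages(self, ref_cohort):
        results = [evaluate_scenario(ref_cohort, s) for s in (1, 2)]
        times = scenario_tables(results)["times"]
        s2 = times[times.scenario == 2].iloc[0]
        assert s2.prep_reduction_pct == pytest.approx(71.7, abs=0.05)
        assert s2.admin_reduction_pct == pytest.approx(89.3, abs=0.05)

    def test_identical_scenarios_zero_delta(self, ref_cohort):
        res = evaluate_scenario(ref_cohort, 1)
        times = scenario_tables([res, res])["times"]
        assert (times.prep_reduction_pct == 0).all()
        assert (times.admin_reduction_pct == 0).all()

    def test_quartile_table_totals(self, ref_cohort):
        results = [evaluate_scenario(ref_cohort, s) for s in (1, 2)]
        table = scenario_tables(results)["doses_by_quartile"]
        total = table[table.quartile == "Total"].iloc[0]
        assert round(total.iv_mg) == 372214
        assert total.sc_mg == 562200.0
        assert round(total.delta_mg) == 189986


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    drug=st.floats(0, 1e6),
    waste=st.floats(0, 1e4),
    prep=st.floats(0, 1e5),
    clinic=st.floats(0, 1e5),
)
def test_breakdown_additivity(drug, waste, prep, clinic):
    bd = CostBreakdown(drug, waste, prep, clinic)
    assert bd.global_eur == drug + waste + prep + clinic
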