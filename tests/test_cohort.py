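"""Cohort types, table I/O round-trips, and the synthetic generator."""
import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivsc_cost import (
    Cadence,
    Cohort,
    CohortFormatError,
    CohortValidationError,
    CourseLengths,
    ParameterError,
    Patient,
    SchedulePhase,
    SchemeMix,
    SyntheticCohortParams,
    WeightDistribution,
    generate_cohort,
    load_cohort,
    summarize_cohort,
    write_cohort,
)

CSV_ONE_PATIENT = """id,phase_index,cadence,n_loading,n_maintenance,weight_kg
p1,0,weekly,1,11,63.75
p1,1,q3w,0,13,63.75
"""


class TestDomainTypes:
    def test_phase_rejects_double_loading(self):
        with pytest.raises(CohortValidationError):
            SchedulePhase(Cadence.WEEKLY, n_loading=2, n_maintenance=0)

    def test_phase_rejects_negative_counts(self):
        with pytest.raises(CohortValidationError):
            SchedulePhase(Cadence.Q3W, n_loading=0, n_maintenance=-1)

    def test_patient_weight_bounds(self):
        with pytest.raises(CohortValidationError):
            Patient("p", 20.0, (SchedulePhase(Cadence.Q3W, 1, 5),))

    def test_patient_needs_phases(self):
        with pytest.raises(CohortValidationError):
            Patient("p", 60.0, ())

    def test_cohort_rejects_duplicate_ids(self):
        p = Patient("p", 60.0, (SchedulePhase(Cadence.Q3W, 1, 5),))
        with pytest.raises(CohortValidationError, match="duplicate"):
            Cohort(patients=(p, p))


class TestLoadCohort:
    def test_two_row_patient_merges_into_two_phases(self):
        cohort = load_cohort(io.StringIO(CSV_ONE_PATIENT))
        assert len(cohort) == 1
        patient = cohort.patients[0]
        assert len(patient.phases) == 2
        assert patient.n_cycles == 25
        assert patient.phases[0].cadence is Cadence.WEEKLY

    def test_empty_data_section(self):
        header = "id,phase_index,cadence,n_loading,n_maintenance,weight_kg\n"
        with pytest.raises(CohortValidationError, match="no patients"):
            load_cohort(io.StringIO(header))

    def test_missing_column_named_in_error(self):
        bad = CSV_ONE_PATIENT.replace("weight_kg", "wt")
        with pytest.raises(CohortFormatError, match="weight_kg"):
            load_cohort(io.StringIO(bad))

    def test_non_numeric_weight_reports_line(self):
        bad = CSV_ONE_PATIENT.replace("63.75", "heavy", 1)
        with pytest.raises(CohortValidationError, match="line 2"):
            load_cohort(io.StringIO(bad))

    def test_negative_count_rejected(self):
        bad = CSV_ONE_PATIENT.replace(",1,11,", ",-1,11,")
        with pytest.raises(CohortValidationError, match="n_loading"):
            load_cohort(io.StringIO(bad))

    def test_duplicate_phase_index_rejected(self):
        bad = CSV_ONE_PATIENT.replace("p1,1,q3w", "p1,0,q3w")
        with pytest.raises(CohortValidationError, match="duplicate"):
            load_cohort(io.StringIO(bad))

    def test_inconsistent_weight_rejected(self):
        bad = CSV_ONE_PATIENT.replace("q3w,0,13,63.75", "q3w,0,13,70")
        with pytest.raises(CohortValidationError, match="inconsistent"):
            load_cohort(io.StringIO(bad))


def test_write_load_round_trip(ref_cohort, tmp_path):
    path = tmp_path / "cohort.csv"
    write_cohort(ref_cohort, path)
    back = load_cohort(path, label=ref_cohort.label)
    assert back.patients == ref_cohort.patients


class TestSummarize:
    def test_three_point_quartiles_interpolate(self):
        cohort = Cohort(
            patients=tuple(
                Patient(f"p{i}", w, (SchedulePhase(Cadence.Q3W, 1, 5),))
                for i, w in enumerate((55.0, 63.7, 74.9))
            )
        )
        s = summarize_cohort(cohort)
        assert s.weight_quartile_bounds == pytest.approx((59.35, 63.7, 69.3))

    def test_single_patient_degenerate(self):
        cohort = Cohort(
            patients=(Patient("p", 63.75, (SchedulePhase(Cadence.Q3W, 1, 5),)),)
        )
        s = summarize_cohort(cohort)
        assert s.median_weight_kg == 63.75
        assert s.weight_range == (63.75, 63.75)

    def test_reference_cohort_matches_2014_aggregates(self, ref_cohort):
        s = summarize_cohort(ref_cohort)
        assert s.n_patients == 114
        assert s.total_iv_cycles == 1292
        assert (s.loading_cycles, s.maintenance_cycles) == (85, 1207)
        assert (s.weekly_cycles, s.q3w_cycles) == (543, 749)
        assert s.median_weight_kg == 63.75
        assert s.weight_range == (42.0, 95.0)
        assert s.weight_quartile_bounds == pytest.approx((55.0, 63.75, 74.9))

    def test_tallies_invariant_under_patient_permutation(self, ref_cohort):
        rng = np.random.default_rng(7)
        shuffled = Cohort(
            patients=tuple(
                ref_cohort.patients[i] for i in rng.permutation(len(ref_cohort))
            ),
            label="shuffled",
        )
        a, b = summarize_cohort(ref_cohort), summarize_cohort(shuffled)
        assert (a.loading_cycles, a.maintenance_cycles, a.weekly_cycles, a.q3w_cycles) == (
            b.loading_cycles,
            b.maintenance_cycles,
            b.weekly_cycles,
            b.q3w_cycles,
        )


class TestGenerator:
    def test_seed_determinism(self):
        a = generate_cohort(SyntheticCohortParams(seed=42))
        b = generate_cohort(SyntheticCohortParams(seed=42))
        assert a.patients == b.patients

    def test_different_seeds_differ(self):
        a = generate_cohort(SyntheticCohortParams(seed=1))
        b = generate_cohort(SyntheticCohortParams(seed=2))
        assert a.patients != b.patients

    def test_default_cohort_weight_structure(self):
        cohort = generate_cohort(SyntheticCohortParams(seed=20140101))
        s = summarize_cohort(cohort)
        assert s.n_patients == 114
        assert 60.0 <= s.median_weight_kg <= 68.0
        assert s.weight_range[0] >= 42.0
        assert s.weight_range[1] <= 95.0

    def test_forced_weekly_only_single_patient(self):
        params = SyntheticCohortParams(
            n_patients=1,
            scheme_mix=SchemeMix(weekly_then_q3w=0.0, q3w_only=0.0, weekly_only=1.0),
            discontinuation_probability=0.0,
            carryover_fraction=0.0,
            seed=3,
        )
        cohort = generate_cohort(params)
        (patient,) = cohort.patients
        assert len(patient.phases) == 1
        phase = patient.phases[0]
        assert phase.cadence is Cadence.WEEKLY
        assert phase.n_loading == 1

    def test_loading_cycles_never_exceed_patients(self):
        cohort = generate_cohort(SyntheticCohortParams(seed=11))
        s = summarize_cohort(cohort)
        assert s.loading_cycles <= s.n_patients

    def test_infeasible_truncation_bounds(self):
        with pytest.raises(ParameterError, match="median"):
            WeightDistribution(median_kg=63.75, min_kg=70.0, max_kg=95.0)

    def test_scheme_mix_must_sum_to_one(self):
        with pytest.raises(ParameterError):
            SchemeMix(weekly_then_q3w=0.5, q3w_only=0.2, weekly_only=0.0)

    def test_course_lengths_positive(self):
        with pytest.raises(ParameterError):
            CourseLengths(q3w_only_cycles=0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 40))
def test_generator_invariants_any_seed(seed, n):
    """Every generated patient is valid and loadings never exceed patients."""
    cohort = generate_cohort(SyntheticCohortParams(n_patients=n, seed=seed))
    s = summarize_cohort(cohort)
    assert len(cohort) == n
    assert s.loading_cycles <= n
    for p in cohort.patients:
        assert p.n_cycles >= 1
        assert 42.0 <= p.weight_kg <= 95.0
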