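import pytest

from ivsc_cost import (
    Cadence,
    Cohort,
    Patient,
    SchedulePhase,
    reference_cohort,
)


@pytest.fixture(scope="session")
def ref_cohort() -> Cohort:
    """The bundled 114-patient cohort with the 2014 aggregate structure."""
    return reference_cohort()


@pytest.fixture
def one_patient_q3w() -> Cohort:
    """Single 60-kg patient on a q3w-only course: 1 loading + 16 maintenance."""
    return Cohort(
        patients=(
            Patient(
                id="p1",
                weight_kg=60.0,
                phases=(SchedulePhase(Cadence.Q3W, n_loading=1, n_maintenance=16),),
            ),
        ),
        label="one-q3w",
    )


@pytest.fixture
def mixed_small_cohort() -> Cohort:
    """Three patients mixing weekly and q3w phases, for brute-force checks."""
    return Cohort(
        patients=(
            Patient(
                id="a",
                weight_kg=55.0,
                phases=(
                    SchedulePhase(Cadence.WEEKLY, 1, 11),
                    SchedulePhase(Cadence.Q3W, 0, 13),
                ),
            ),
            Patient(
                id="b",
                weight_kg=74.9,
                phases=(SchedulePhase(Cadence.Q3W, 1, 5),),
            ),
            Patient(
                id="c",
                weight_kg=63.75,
                phases=(
                    SchedulePhase(Cadence.WEEKLY, 1, 9),
                    SchedulePhase(Cadence.Q3W, 0, 4),
                ),
            ),
        ),
        label="mixed-small",
    )
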