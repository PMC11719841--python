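import pytest

from pexen.cohort import Complication, Margin, PatientRecord, UKPENCode
from pexen.costing import ResourceLine
from pexen.proms import PromResponse, toy_crosswalk, toy_valueset_3l, toy_valueset_5l
from pexen.synthetic import default_spec, generate_cohort


@pytest.fixture(scope="session")
def vs5():
    return toy_valueset_5l()


@pytest.fixture(scope="session")
def vs3():
    return toy_valueset_3l()


@pytest.fixture(scope="session")
def crosswalk(vs3):
    return toy_crosswalk(vs3)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-spec synthetic cohort (64 conventional + 255 high-complexity)."""
    return generate_cohort(default_spec(seed=1))


def _codes(*tokens):
    return frozenset(UKPENCode.parse(t) for t in tokens)


@pytest.fixture(scope="session")
def small_cohort():
    """Hand-built 12-patient cohort covering both groups and edge cases."""
    patients = []
    # six conventional
    for i, margin in enumerate(
        [Margin.R0, Margin.R0, Margin.R0, Margin.R1_CONTINUOUS, Margin.R2, Margin.R0]
    ):
        patients.append(
            PatientRecord(
                id=f"c{i}",
                codes=_codes("P1", "C2"),
                margin=margin,
                survival_time=24.0 + 6 * i,
                survival_event=i % 2 == 0,
                resources=[
                    ResourceLine("theatres", "theatre_minute", 500 + 10 * i),
                    ResourceLine("admission", "bed_day", 15 + i),
                ],
                complications=[Complication("2", "index_admission")] if i == 0 else [],
                exenteration_level="infralevator" if i < 3 else "supralevator",
                reconstruction="biological_mesh" if i < 3 else "none",
                proms=[
                    PromResponse("baseline", eq5d=(1, 1, 2, 2, 1), drs_items=(5, 1, 5, 1, 5)),
                    PromResponse("m6", eq5d=(2, 2, 2, 3, 2), drs_items=(4, 2, 4, 1, 5)),
                ],
                prom_participant=True,
                age=60.0 + i,
                sex="female" if i % 2 else "male",
                bmi=26.0,
            )
        )
    # six high-complexity (one benign)
    for i in range(6):
        benign = i == 5
        patients.append(
            PatientRecord(
                id=f"h{i}",
                codes=_codes("P2", "C3") if i % 2 == 0 else _codes("C2", "SV1"),
                margin=Margin.NOT_APPLICABLE if benign else Margin.R0,
                benign_flag=benign,
                survival_time=18.0 + 5 * i,
                survival_event=i % 2 == 1,
                resources=[
                    ResourceLine("theatres", "theatre_minute", 650 + 20 * i),
                    ResourceLine("admission", "bed_day", 20 + i),
                    ResourceLine("unplanned_radiology", "ct_scan", i % 2),
                ],
                complications=(
                    [Complication("3a", "index_admission")]
                    if i < 2
                    else [Complication("3b", "later")] if i == 2 else []
                ),
                exenteration_level="infralevator" if i < 4 else "supralevator",
                reconstruction=(
                    ["myocutaneous_flap", "myocutaneous_flap", "composite", "composite"][i]
                    if i < 4
                    else "none"
                ),
                proms=[
                    PromResponse("baseline", eq5d=(2, 1, 2, 2, 1), drs_items=(5, 1, 5, 1, 4)),
                    PromResponse("m6", eq5d=(3, 2, 3, 4, 2), drs_items=(3, 3, 3, 2, 4)),
                ],
                prom_participant=True,
                age=55.0 + i,
                sex="male" if i % 2 else "female",
                bmi=27.5,
            )
        )
    return patients
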