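import datetime as dt

import pytest

from egfr_discordance import ParameterGrid, PatientSnapshot, build_inverse_index
from egfr_discordance.egfr import Gender, RaceDetail


@pytest.fixture(scope="session")
def full_index():
    """Inverse index over the full enumeration grid (built once per session)."""
    return build_inverse_index()


@pytest.fixture(scope="session")
def reduced_grid():
    """Small grid (ages 18-40, Scr 0.50-2.00) for brute-force comparisons."""
    return ParameterGrid(age_min=18, age_max=40, scr_min=0.50, scr_max=2.00)


@pytest.fixture(scope="session")
def reduced_index(reduced_grid):
    return build_inverse_index(reduced_grid)


def make_snapshot(age=60, female=False, black=False, scr=1.10,
                  lab_date=dt.date(2013, 6, 1), pid="P1"):
    """Snapshot whose completed age at lab_date equals ``age`` exactly."""
    dob = lab_date.replace(year=lab_date.year - age)
    return PatientSnapshot(
        patient_id=pid,
        dob=dob,
        gender=Gender.FEMALE if female else Gender.MALE,
        race_detail=RaceDetail.BLACK if black else RaceDetail.WHITE,
        scr=scr,
        lab_date=lab_date,
    )


@pytest.fixture
def snapshot_factory():
    return make_snapshot
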