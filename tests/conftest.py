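from datetime import datetime, timedelta

import pytest

from wardscore.records import CohortParams, LabObservation, PatientRecord, VitalObservation
from wardscore.scores import Snapshot, load_all_definitions, load_normal_values
from wardscore.synthetic import generate_cohort
from wardscore.windows import static_context


@pytest.fixture(scope="session")
def definitions():
    return load_all_definitions()


@pytest.fixture(scope="session")
def normals():
    return load_normal_values()


@pytest.fixture(scope="session")
def make_snapshot(normals):
    """Factory for a complete snapshot: all components at their documented
    normal, age 35, no comorbidities, ward context; overridable per test."""
    base_record = PatientRecord(
        patient_id="SNAP", admission_time=datetime(2010, 1, 1),
        discharge_time=datetime(2010, 1, 5), age=35, sex="male", race="white")

    def factory(**overrides):
        values = dict(static_context(base_record))
        for comp, info in normals.items():
            values[comp] = info["normal"]
        values.update({"avpu": "A", "gcs": 15, "supplemental_o2": False})
        values.update(overrides)
        return Snapshot(values)

    return factory


@pytest.fixture(scope="session")
def small_cohort():
    """A 240-admission cohort with an enriched case fraction, shared across tests."""
    return generate_cohort(CohortParams(n_admissions=240, case_fraction=0.25,
                                        n_days=30, seed=11))


@pytest.fixture(scope="session")
def study_sized_cohort():
    """A cohort at the scale of the source study (5188 admissions, ~6% cases)."""
    return generate_cohort(CohortParams(n_admissions=5188, case_fraction=328 / 5188,
                                        seed=1))


def make_record(pid="T0", admission=datetime(2010, 1, 1, 8, 0), los_hours=120.0,
                age=60, vitals=(), labs=(), events=None, **kwargs):
    """Hand-built patient record for window/design tests."""
    return PatientRecord(
        patient_id=pid, admission_time=admission,
        discharge_time=admission + timedelta(hours=los_hours),
        age=age, sex="female", race="white",
        vitals=list(vitals), labs=list(labs),
        event_times=events or {}, **kwargs)


def vital(t, **kw):
    defaults = dict(heart_rate=75, respiratory_rate=14, systolic_bp=115,
                    diastolic_bp=70, temperature=37.0, spo2=98.0)
    defaults.update(kw)
    return VitalObservation(timestamp=t, **defaults)


def lab(t, analyte, value):
    return LabObservation(timestamp=t, analyte=analyte, value=value)
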