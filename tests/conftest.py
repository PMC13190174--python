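import pytest

from trialfit.demographics import PatientRecord, default_schema, MissingPolicy


def make_record(pid, **kwargs):
    defaults = dict(
        age=55.0,
        gender="Male",
        ethnicity="WHITE",
        weight=80.0,
        language="ENGLISH",
        religion="CATHOLIC",
        marital_status="MARRIED",
    )
    defaults.update(kwargs)
    return PatientRecord(patient_id=str(pid), **defaults)


@pytest.fixture
def schema():
    return default_schema()


@pytest.fixture
def policy():
    return MissingPolicy()


@pytest.fixture
def complete_cohort():
    """Six fully observed patients spanning several categories."""
    return [
        make_record("A1"),
        make_record("A2", age=0.5, gender="Female", weight=45.0),
        make_record("A3", age=72.0, ethnicity="BLACK/AFRICAN AMERICAN"),
        make_record("A4", age=85.0, gender="Female", language="SPANISH"),
        make_record("A5", age=30.0, weight=130.0, marital_status="SINGLE"),
        make_record("A6", age=12.0, weight=55.0, religion="JEWISH"),
    ]


@pytest.fixture
def target_cohort():
    """A target population sharing the complete cohort's category universe."""
    return [
        make_record(f"T{i}", age=a, gender=g, weight=w)
        for i, (a, g, w) in enumerate(
            [(60, "Male", 78), (0.8, "Female", 48), (70, "Male", 95),
             (82, "Female", 62), (33, "Male", 125), (15, "Female", 52),
             (55, "Male", 88), (45, "Female", 70)]
        )
    ]
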