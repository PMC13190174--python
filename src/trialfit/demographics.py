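"""Demographic schema: feature definitions, binning, consolidation, missingness.

Seven features are assessed per patient: age group, gender, ethnicity,
weight group, religion, language and marital status.  Age and weight are
recorded as numbers and binned into clinically motivated groups; the other
five are categorical and taken as observed (upper-cased, trimmed).

Interval convention
-------------------
Age and weight bins are half-open, ``[lower, upper)``: age 1 falls in
Child/Adolescent, 18 in Young Adult, 40 in Middle-aged, 65 in Older Adult,
80 in Elderly; weight 50 kg is Normal, 70 Overweight, 90 Obese, 120
Severely Obese.  This makes the bins exhaustive and mutually exclusive on
``[0, inf)`` for age and ``(0, inf)`` for weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyCohortError, InvalidValueError, UnmappedCategoryError

MISSING = pd.NA  # sentinel used in assignment tables


class Feature(str, Enum):
    """The seven demographic dimensions."""

    AGE_GROUP = "AGE_GROUP"
    GENDER = "GENDER"
    ETHNICITY = "ETHNICITY"
    WEIGHT_GROUP = "WEIGHT_GROUP"
    RELIGION = "RELIGION"
    LANGUAGE = "LANGUAGE"
    MARITAL_STATUS = "MARITAL_STATUS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# (label, lower, upper) with half-open [lower, upper) intervals
AGE_BINS: tuple[tuple[str, float, float], ...] = (
    ("Neonate/Infant", 0.0, 1.0),
    ("Child/Adolescent", 1.0, 18.0),
    ("Young Adult", 18.0, 40.0),
    ("Middle-aged", 40.0, 65.0),
    ("Older Adult", 65.0, 80.0),
    ("Elderly", 80.0, math.inf),
)
AGE_GROUPS: tuple[str, ...] = tuple(b[0] for b in AGE_BINS)

WEIGHT_BINS: tuple[tuple[str, float, float], ...] = (
    ("Underweight", 0.0, 50.0),
    ("Normal", 50.0, 70.0),
    ("Overweight", 70.0, 90.0),
    ("Obese", 90.0, 120.0),
    ("Severely Obese", 120.0, math.inf),
)
WEIGHT_GROUPS: tuple[str, ...] = tuple(b[0] for b in WEIGHT_BINS)

ETHNICITY_GROUPS: tuple[str, ...] = (
    "White",
    "Black/African American",
    "Hispanic/Latino",
    "Asian",
    "Other",
    "Multiple",
    "Unknown",
)

GENDERS: tuple[str, ...] = ("MALE", "FEMALE")  # stored case-normalised

#: Default consolidation of EHR-style ethnicity labels into the seven major
#: groups.  Matching is on the upper-cased, trimmed label: exact entries are
#: tried first, then each prefix (longest first).  Mirrors the granular
#: "HEAD - QUALIFIER" label style used by large critical-care EHR exports.
DEFAULT_ETHNICITY_MAPPING: dict[str, str] = {
    # exact labels
    "UNKNOWN/NOT SPECIFIED": "Unknown",
    "PATIENT DECLINED TO ANSWER": "Unknown",
    "UNABLE TO OBTAIN": "Unknown",
    "UNKNOWN": "Unknown",
    "MULTI RACE ETHNICITY": "Multiple",
    "MULTIPLE": "Multiple",
    "OTHER": "Other",
    # head-label prefixes
    "WHITE": "White",
    "BLACK": "Black/African American",
    "AFRICAN AMERICAN": "Black/African American",
    "HISPANIC": "Hispanic/Latino",
    "LATINO": "Hispanic/Latino",
    "SOUTH AMERICAN": "Hispanic/Latino",
    "ASIAN": "Asian",
    "AMERICAN INDIAN": "Other",
    "ALASKA NATIVE": "Other",
    "NATIVE HAWAIIAN": "Other",
    "PACIFIC ISLANDER": "Other",
    "CARIBBEAN ISLAND": "Other",
    "MIDDLE EASTERN": "Other",
    "PORTUGUESE": "Other",
}

#: Explicit data values counted as incomplete alongside nulls.
DEFAULT_UNKNOWN_DESIGNATIONS: frozenset[str] = frozenset(
    {
        "",
        "UNKNOWN",
        "UNKNOWN/NOT SPECIFIED",
        "PATIENT DECLINED",
        "PATIENT DECLINED TO ANSWER",
        "UNABLE TO OBTAIN",
        "NOT SPECIFIED",
    }
)


@dataclass(frozen=True)
class MissingPolicy:
    """Which raw values are treated as incomplete.

    Matching is case-insensitive and whitespace-trimmed; absent values
    (None/NaN) are always incomplete.  The consolidated ``Unknown``
    ethnicity group is likewise counted as incomplete when
    ``unknown_ethnicity_is_incomplete`` is true (the default), so that
    "ethnicity recorded as unknown" degrades completeness rather than
    entering the coverage distribution.
    """

    unknown_designations: frozenset[str] = DEFAULT_UNKNOWN_DESIGNATIONS
    unknown_ethnicity_is_incomplete: bool = True

    def __post_init__(self) -> None:
        norm = frozenset(s.strip().upper() for s in self.unknown_designations)
        object.__setattr__(self, "unknown_designations", norm)


@dataclass(frozen=True)
class FeatureSpec:
    """One demographic dimension: its kind and (if fixed) category inventory.

    ``categories`` is None for features whose inventory is taken as
    observed in the data (religion, language, marital status).
    """

    name: Feature
    kind: str  # "binned-numeric" | "categorical"
    categories: tuple[str, ...] | None = None


def default_schema() -> tuple[FeatureSpec, ...]:
    """The seven-feature schema used throughout."""
    return (
        FeatureSpec(Feature.AGE_GROUP, "binned-numeric", AGE_GROUPS),
        FeatureSpec(Feature.GENDER, "categorical", GENDERS),
        FeatureSpec(Feature.ETHNICITY, "categorical", ETHNICITY_GROUPS),
        FeatureSpec(Feature.WEIGHT_GROUP, "binned-numeric", WEIGHT_GROUPS),
        FeatureSpec(Feature.RELIGION, "categorical", None),
        FeatureSpec(Feature.LANGUAGE, "categorical", None),
        FeatureSpec(Feature.MARITAL_STATUS, "categorical", None),
    )


@dataclass
class PatientRecord:
    """One row of raw demographics; any field but patient_id may be absent."""

    patient_id: str
    age: float | None = None  # years
    gender: str | None = None
    ethnicity: str | None = None
    weight: float | None = None  # kg
    language: str | None = None
    religion: str | None = None
    marital_status: str | None = None

    def __post_init__(self) -> None:
        if not str(self.patient_id):
            raise InvalidValueError("patient_id must be non-empty")
        if self.age is not None and not math.isnan(self.age) and self.age < 0:
            raise InvalidValueError(f"age must be >= 0, got {self.age}")
        if self.weight is not None and not math.isnan(self.weight) and self.weight <= 0:
            raise InvalidValueError(f"weight must be > 0, got {self.weight}")


def bin_age(age: float) -> str:
    """Assign an age in years to one of the six age groups.

    Bins are half-open ``[lower, upper)``; the Elderly bin is unbounded
    above.  Raises :class:`InvalidValueError` for negative or non-numeric
    input.
    """
    if not isinstance(age, (int, float, np.integer, np.floating)) or math.isnan(age):
        raise InvalidValueError(f"age must be a number, got {age!r}")
    if age < 0:
        raise InvalidValueError(f"age must be >= 0, got {age}")
    for label, lo, hi in AGE_BINS:
        if lo <= age < hi:
            return label
    raise InvalidValueError(f"age {age} matched no bin")  # pragma: no cover


def bin_weight(weight: float) -> str:
    """Assign a weight in kg to one of the five dosing-relevant groups.

    Bins are half-open ``[lower, upper)`` on ``(0, inf)``.  Raises
    :class:`InvalidValueError` for non-positive or non-numeric input.
    """
    if not isinstance(weight, (int, float, np.integer, np.floating)) or math.isnan(weight):
        raise InvalidValueError(f"weight must be a number, got {weight!r}")
    if weight <= 0:
        raise InvalidValueError(f"weight must be > 0, got {weight}")
    for label, lo, hi in WEIGHT_BINS:
        if lo <= weight < hi:
            return label
    raise InvalidValueError(f"weight {weight} matched no bin")  # pragma: no cover


def consolidate_ethnicity(
    raw_label: str,
    mapping: Mapping[str, str] | None = None,
    fallback: str | None = None,
) -> str:
    """Consolidate a granular ethnicity label into one of the 7 major groups.

    Exact (normalised) matches are tried first, then prefixes longest-first,
    so "WHITE - RUSSIAN" maps to White.  Labels already equal to a major
    group are returned unchanged (the consolidation is idempotent).  An
    unmatched label raises :class:`UnmappedCategoryError` unless a
    ``fallback`` group is given.
    """
    if mapping is None:
        mapping = DEFAULT_ETHNICITY_MAPPING
    label = str(raw_label).strip()
    if label in ETHNICITY_GROUPS:
        return label
    norm = label.upper()
    if norm in mapping:
        return mapping[norm]
    for prefix in sorted(mapping, key=len, reverse=True):
        if norm.startswith(prefix):
            return mapping[prefix]
    if fallback is not None:
        if fallback not in ETHNICITY_GROUPS:
            raise InvalidValueError(f"fallback {fallback!r} is not a major group")
        return fallback
    raise UnmappedCategoryError(label)


def is_missing(value: Any, policy: MissingPolicy | None = None) -> bool:
    """True iff a raw cell is absent or carries an explicit unknown designation."""
    if policy is None:
        policy = MissingPolicy()
    if value is None or value is pd.NA:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str):
        return value.strip().upper() in policy.unknown_designations
    return False


def _normalise_category(value: str) -> str:
    return str(value).strip().upper()


def featurize(
    records: Sequence[PatientRecord],
    schema: Sequence[FeatureSpec] | None = None,
    policy: MissingPolicy | None = None,
    ethnicity_mapping: Mapping[str, str] | None = None,
    ethnicity_fallback: str | None = None,
) -> pd.DataFrame:
    """Turn raw patient records into a per-feature category assignment table.

    Returns a DataFrame indexed by patient_id with one column per feature;
    cells hold category labels, or ``pd.NA`` where the input was absent or
    flagged by the missing-value policy.  Row count always equals the input
    record count.
    """
    if len(records) == 0:
        raise EmptyCohortError("cannot featurize an empty record list")
    if schema is None:
        schema = default_schema()
    if policy is None:
        policy = MissingPolicy()

    ids = [str(r.patient_id) for r in records]
    if len(set(ids)) != len(ids):
        raise InvalidValueError("patient_id values must be unique within a table")

    raw_getters = {
        Feature.AGE_GROUP: lambda r: r.age,
        Feature.GENDER: lambda r: r.gender,
        Feature.ETHNICITY: lambda r: r.ethnicity,
        Feature.WEIGHT_GROUP: lambda r: r.weight,
        Feature.RELIGION: lambda r: r.religion,
        Feature.LANGUAGE: lambda r: r.language,
        Feature.MARITAL_STATUS: lambda r: r.marital_status,
    }
    binners = {Feature.AGE_GROUP: bin_age, Feature.WEIGHT_GROUP: bin_weight}

    columns: dict[str, list] = {}
    for spec in schema:
        getter = raw_getters[spec.name]
        col: list = []
        for rec in records:
            raw = getter(rec)
            if is_missing(raw, policy):
                col.append(MISSING)
            elif spec.name in binners:
                col.append(binners[spec.name](raw))
            elif spec.name is Feature.ETHNICITY:
                group = consolidate_ethnicity(raw, ethnicity_mapping, ethnicity_fallback)
                if group == "Unknown" and policy.unknown_ethnicity_is_incomplete:
                    col.append(MISSING)
                else:
                    col.append(group)
            else:
                col.append(_normalise_category(raw))
        columns[spec.name.value] = col

    return pd.DataFrame(columns, index=pd.Index(ids, name="patient_id"), dtype=object)


def load_ethnicity_mapping(entries: Iterable[tuple[str, str]] | Mapping[str, str]) -> dict[str, str]:
    """Build a normalised label->group mapping, validating the target groups."""
    items = entries.items() if isinstance(entries, Mapping) else entries
    mapping: dict[str, str] = {}
    for label, group in items:
        if group not in ETHNICITY_GROUPS:
            raise InvalidValueError(
                f"mapping target {group!r} for {label!r} is not one of the seven major groups"
            )
        mapping[str(label).strip().upper()] = group
    return mapping
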