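"""Core EHR domain types and elementary date/age computations.

The package works on a cross-sectional cohort anchored at a single index
date (default 1 September 2019).  Primary-care records carry only the year
of birth, so all age arithmetic uses the year-difference convention:
``age = index year - birth year``.  The one-year uncertainty this creates
is absorbed downstream by the extra slack year built into age-eligibility
lookback windows.

All date intervals in the package are half-open ``[start, end)``: an event
on ``start`` is inside, an event on ``end`` is not.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SOURCES",
    "CONSULTATION_TYPES",
    "EPOCH",
    "DEFAULT_INDEX_DATE",
    "ConfigError",
    "DataError",
    "DateInterval",
    "Patient",
    "CodedEvent",
    "Cohort",
    "age_at_index",
    "date_turning",
    "build_cohort",
    "read_patients",
    "read_events",
    "write_patients",
    "write_events",
]

#: Recognised event sources: CPRD Aurum clinical ("medcode") events,
#: prescriptions, HES APC diagnoses (ICD-10-style, positioned) and
#: procedures (OPCS-style), and primary-care consultation records.
SOURCES = ("clinical", "prescription", "hes_diagnosis", "hes_procedure", "consultation")

CONSULTATION_TYPES = ("gp", "nurse", "out_of_hours", "other")

#: Lower bound used for "ever before index" windows.  "Ever" is bounded
#: only by the data (records transferred from previous practices predate
#: registration), so any date before plausible EHR content works.
EPOCH = dt.date(1900, 1, 1)

DEFAULT_INDEX_DATE = dt.date(2019, 9, 1)


class ConfigError(ValueError):
    """Invalid configuration (bad schema, distribution, or parameter)."""


class DataError(ValueError):
    """Invalid or inconsistent input data."""


@dataclass(frozen=True)
class DateInterval:
    """Half-open calendar-date interval ``[start, end)``."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} after end {self.end}")

    def __contains__(self, d: dt.date) -> bool:
        return self.start <= d < self.end

    @property
    def is_empty(self) -> bool:
        return self.start >= self.end

    def days(self) -> int:
        return (self.end - self.start).days


@dataclass(frozen=True)
class Patient:
    patient_id: str
    year_of_birth: int
    sex: str  # "male" | "female"
    reg_start: dt.date


@dataclass(frozen=True)
class CodedEvent:
    patient_id: str
    date: dt.date
    source: str
    code: str
    diag_position: int | None = None  # hes_diagnosis only; 1 = primary
    consultation_type: str | None = None  # consultation only


@dataclass
class Cohort:
    """An index-date-anchored set of included patients.

    ``patients`` is a DataFrame with columns ``patient_id``,
    ``year_of_birth``, ``sex``, ``reg_start`` and the derived ``age``
    (year-difference at index).  Exclusion counts record how many input
    patients each inclusion rule removed.
    """

    index_date: dt.date
    patients: pd.DataFrame
    n_excluded_age: int = 0
    n_excluded_registration: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> pd.Index:
        return pd.Index(self.patients["patient_id"])


def age_at_index(year_of_birth: int, index_date: dt.date) -> int:
    """Age in whole years by the year-difference convention.

    Only the year of birth is recorded, so this is the age the patient
    attains at some point during the index year, not necessarily the age
    on the index date itself.
    """
    age = index_date.year - int(year_of_birth)
    if age < 0:
        raise DataError(
            f"year_of_birth {year_of_birth} is after index year {index_date.year}"
        )
    return age


def date_turning(year_of_birth: int, age: int) -> dt.date:
    """Earliest date the patient could have attained ``age``.

    With year-of-birth-only recording the attainment date is unknown
    within the year, so 1 January of ``year_of_birth + age`` is the
    generous (earliest-possible) choice.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    return dt.date(int(year_of_birth) + int(age), 1, 1)


def _years_before(d: dt.date, years: float) -> dt.date:
    """``d`` minus a (possibly fractional) number of years.

    Whole years shift the calendar year (29 Feb maps to 28 Feb); the
    fractional remainder is applied as days at 365.25 days/year.
    """
    whole = int(years)
    frac = float(years) - whole
    year = d.year - whole
    try:
        out = d.replace(year=year)
    except ValueError:  # 29 Feb in a non-leap year
        out = d.replace(year=year, day=28)
    if frac:
        out -= dt.timedelta(days=round(frac * 365.25))
    return out


def build_cohort(
    patients: pd.DataFrame,
    index_date: dt.date = DEFAULT_INDEX_DATE,
    min_registration_years: float = 1.0,
    min_age: int = 66,
) -> Cohort:
    """Apply the two inclusion rules and return the cohort.

    A patient is included iff ``age_at_index >= min_age`` and their GP
    registration started strictly before ``index_date`` minus
    ``min_registration_years`` (the minimum pre-index period available
    for marker ascertainment).
    """
    if min_registration_years < 0 or min_age < 0:
        raise ConfigError("min_registration_years and min_age must be non-negative")
    df = patients.copy()
    required = {"patient_id", "year_of_birth", "sex", "reg_start"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"patients table missing columns: {sorted(missing)}")
    df["age"] = index_date.year - df["year_of_birth"].astype(int)
    if (df["age"] < 0).any():
        raise DataError("patient with year_of_birth after the index year")

    old_enough = df["age"] >= min_age
    reg_cutoff = _years_before(index_date, min_registration_years)
    reg_start = pd.to_datetime(df["reg_start"]).dt.date
    registered = reg_start < reg_cutoff

    n_excl_age = int((~old_enough).sum())
    # count registration exclusions among the age-eligible, as an extraction
    # flowchart would
    n_excl_reg = int((old_enough & ~registered).sum())
    out = df[old_enough & registered].reset_index(drop=True)
    if out.empty:
        warnings.warn("cohort is empty after applying inclusion rules", stacklevel=2)
    return Cohort(
        index_date=index_date,
        patients=out,
        n_excluded_age=n_excl_age,
        n_excluded_registration=n_excl_reg,
    )


# ---------------------------------------------------------------------------
# CSV readers / writers

_EVENT_COLUMNS = ["patient_id", "date", "source", "code", "diag_position", "consultation_type"]


def read_patients(path) -> pd.DataFrame:
    """Read a patients.csv (patient_id, year_of_birth, sex M/F, reg_start)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "year_of_birth", "sex", "reg_start"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"patients file missing columns: {sorted(missing)}")
    sex_map = {"M": "male", "F": "female", "male": "male", "female": "female"}
    bad = ~df["sex"].isin(sex_map)
    if bad.any():
        raise DataError(f"unknown sex code at row {int(bad.idxmax()) + 2}")
    df["sex"] = df["sex"].map(sex_map)
    df["year_of_birth"] = df["year_of_birth"].astype(int)
    df["reg_start"] = pd.to_datetime(df["reg_start"], format="%Y-%m-%d").dt.date
    return df


def write_patients(df: pd.DataFrame, path) -> None:
    out = df[["patient_id", "year_of_birth", "sex", "reg_start"]].copy()
    out["sex"] = out["sex"].map({"male": "M", "female": "F"})
    out.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    """Read an events.csv; diag_position and consultation_type may be blank."""
    df = pd.read_csv(path, dtype={"patient_id": str, "code": str})
    missing = set(_EVENT_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise DataError(f"events file missing columns: {sorted(missing)}")
    bad = ~df["source"].isin(SOURCES)
    if bad.any():
        raise DataError(f"unknown event source at row {int(bad.idxmax()) + 2}")
    df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
    if "diag_position" not in df.columns:
        df["diag_position"] = pd.NA
    if "consultation_type" not in df.columns:
        df["consultation_type"] = pd.NA
    df["diag_position"] = df["diag_position"].astype("Int64")
    if ((df["diag_position"].dropna()) < 1).any():
        raise DataError("diag_position must be >= 1 when present")
    ct = df["consultation_type"].dropna()
    if (~ct.isin(CONSULTATION_TYPES)).any():
        raise DataError("unknown consultation_type value")
    return df[_EVENT_COLUMNS]


def write_events(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.reindex(columns=_EVENT_COLUMNS).to_csv(path, index=False)
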