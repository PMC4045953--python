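"""Dispensing-registry file formats, validation and ATC drug-class tagging.

A dispensing registry is a long table with one row per redeemed
prescription.  Sex and birth year are denormalised onto every row so a
single CSV file is self-contained.  Population denominators are January-1
head counts per (year, sex, single-year age), as published by national
statistics offices.

Drug classes follow the ATC hierarchy for blood glucose-lowering drugs:
A10A are insulins and analogues, A10B are oral antidiabetic drugs (OAD),
anything else under A10 is counted only toward the "any A10" class, and
non-A10 codes are retained but ignored by the cohort classifier.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd

DISPENSING_COLUMNS = ["person_id", "dispense_date", "atc_code", "sex", "birth_year"]
POPULATION_COLUMNS = ["year", "sex", "age", "count"]
SEXES = ("female", "male")

#: full 7-character ATC code: letter, 2 digits, 2 letters, 2 digits
_ATC_FULL = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")


class RegistryError(ValueError):
    """Base class for registry file problems."""


class SchemaError(RegistryError):
    """File header does not name the expected columns."""


class ParseError(RegistryError):
    """A cell could not be parsed (named by row)."""


class CoverageError(RegistryError):
    """A record falls outside the declared registry coverage."""


class IntegrityError(RegistryError):
    """Cross-row constraint violated (e.g. duplicate population stratum)."""


class DrugClass(str, Enum):
    """ATC-prefix drug class of a dispensing record."""

    INSULIN = "insulin"    # A10A
    OAD = "oad"            # A10B
    ANY_A10 = "any_a10"    # other A10 (class query: any A10 code)
    OTHER = "other"        # not a blood glucose-lowering drug


def classify_atc(atc_code: str) -> DrugClass:
    """Classify an ATC code (or prefix) by its leading characters.

    Pure function of the first four characters for A10-prefixed codes.
    Non-A10 codes map to ``DrugClass.OTHER``; no code is rejected.
    """
    if not atc_code:
        raise ValueError("empty ATC code")
    if atc_code.startswith("A10A"):
        return DrugClass.INSULIN
    if atc_code.startswith("A10B"):
        return DrugClass.OAD
    if atc_code.startswith("A10"):
        return DrugClass.ANY_A10
    return DrugClass.OTHER


def in_class(atc_code: str, drug_class: DrugClass) -> bool:
    """True when *atc_code* belongs to *drug_class* as a class query.

    ``ANY_A10`` is the union class: it matches every A10 code including
    insulins and OAD.  ``INSULIN``/``OAD``/``OTHER`` match exactly.
    """
    c = classify_atc(atc_code)
    if drug_class is DrugClass.ANY_A10:
        return c in (DrugClass.INSULIN, DrugClass.OAD, DrugClass.ANY_A10)
    return c is drug_class


@dataclass(frozen=True)
class RegistryCoverage:
    """Closed interval of complete registry data capture."""

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if not self.start < self.end:
            raise ValueError(f"coverage start {self.start.date()} must precede end {self.end.date()}")

    @classmethod
    def from_years(cls, first_year: int, last_year: int) -> "RegistryCoverage":
        return cls(pd.Timestamp(first_year, 1, 1), pd.Timestamp(last_year, 12, 31))

    @property
    def years(self) -> range:
        """Calendar years intersecting the coverage interval."""
        return range(self.start.year, self.end.year + 1)

    def contains(self, date) -> bool:
        ts = pd.Timestamp(date)
        return self.start <= ts <= self.end


def _require_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    extra = [c for c in df.columns if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{path}: expected columns {expected}, missing {missing or 'none'}, "
            f"unknown {extra or 'none'}"
        )


def read_dispensings(path, coverage: RegistryCoverage) -> pd.DataFrame:
    """Read and validate a dispensing CSV.

    Returns a DataFrame with columns person_id, dispense_date (datetime),
    atc_code, sex, birth_year, sorted by (person_id, dispense_date,
    atc_code).  Records outside *coverage* raise :class:`CoverageError`;
    malformed cells raise :class:`ParseError` naming the offending row
    (1-based data row number).
    """
    df = pd.read_csv(path, dtype={"person_id": str, "atc_code": str, "sex": str})
    _require_columns(df, DISPENSING_COLUMNS, path)
    if df.empty:
        df = df.assign(dispense_date=pd.to_datetime(df["dispense_date"]))
        return df[DISPENSING_COLUMNS]

    dates = pd.to_datetime(df["dispense_date"], format="%Y-%m-%d", errors="coerce")
    if dates.isna().any():
        row = int(dates.index[dates.isna()][0])
        raise ParseError(
            f"{path}: row {row + 1}: malformed date {df['dispense_date'].iloc[row]!r}"
        )
    df = df.assign(dispense_date=dates)

    bad_atc = ~df["atc_code"].str.match(_ATC_FULL)
    if bad_atc.any():
        row = int(df.index[bad_atc][0])
        raise ParseError(f"{path}: row {row + 1}: invalid ATC code {df['atc_code'].iloc[row]!r}")

    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        row = int(df.index[bad_sex][0])
        raise ParseError(f"{path}: row {row + 1}: sex must be one of {SEXES}")

    try:
        df["birth_year"] = df["birth_year"].astype(int)
    except (TypeError, ValueError) as err:
        raise ParseError(f"{path}: birth_year must be integer years: {err}") from None

    outside = (df["dispense_date"] < coverage.start) | (df["dispense_date"] > coverage.end)
    if outside.any():
        row = int(df.index[outside][0])
        raise CoverageError(
            f"{path}: row {row + 1}: dispense_date {df['dispense_date'].iloc[row].date()} "
            f"outside coverage {coverage.start.date()}..{coverage.end.date()}"
        )

    df = df.sort_values(["person_id", "dispense_date", "atc_code"], kind="stable")
    return df[DISPENSING_COLUMNS].reset_index(drop=True)


def write_dispensings(records: pd.DataFrame, path) -> None:
    """Write dispensing records as CSV with ISO-8601 day-resolution dates."""
    out = records[DISPENSING_COLUMNS].copy()
    out["dispense_date"] = pd.to_datetime(out["dispense_date"]).dt.strftime("%Y-%m-%d")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


def read_population(path) -> pd.DataFrame:
    """Read January-1 population counts per (year, sex, age).

    Duplicate strata raise :class:`IntegrityError`; negative counts raise
    :class:`ParseError`.
    """
    df = pd.read_csv(path, dtype={"sex": str})
    _require_columns(df, POPULATION_COLUMNS, path)
    if df.empty:
        return df[POPULATION_COLUMNS]
    try:
        df = df.astype({"year": int, "age": int, "count": int})
    except (TypeError, ValueError) as err:
        raise ParseError(f"{path}: year/age/count must be integers: {err}") from None
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        row = int(df.index[bad_sex][0])
        raise ParseError(f"{path}: row {row + 1}: sex must be one of {SEXES}")
    if (df["count"] < 0).any():
        row = int(df.index[df["count"] < 0][0])
        raise ParseError(f"{path}: row {row + 1}: negative population count")
    dup = df.duplicated(subset=["year", "sex", "age"])
    if dup.any():
        key = df.loc[df.index[dup][0], ["year", "sex", "age"]].tolist()
        raise IntegrityError(f"{path}: duplicate population stratum {tuple(key)}")
    return df.sort_values(["year", "sex", "age"]).reset_index(drop=True)[POPULATION_COLUMNS]


def write_population(pop: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pop[POPULATION_COLUMNS].to_csv(path, index=False)
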