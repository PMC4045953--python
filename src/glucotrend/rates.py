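"""Person-year denominators, incidence rates, prevalence, report tables.

Person-years per (year, stratum) are the arithmetic mean of the January-1
population of the year and of the following year (the "mean population"
approximation for a fully covered national registry).  Incidence-rate
confidence intervals use the normal approximation on the rate scale
(Wald), ``rate * (1 +/- z / sqrt(count))``; a log-scale Wald variant is
available behind a flag.  Zero counts fall back to the rule of three for
the upper bound.  The engine keeps full precision; rounding (half away
from zero) happens only in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    WindowConfig,
    incidence_observable,
    insulin_only_observable,
    prevalence_observable,
)
from .io import RegistryCoverage


class DataError(ValueError):
    """Requested stratum/year not present in the denominator table."""


@dataclass(frozen=True)
class RateEstimate:
    """Incidence rate per 100,000 person-years with a 95% (or other) CI."""

    count: int
    person_years: float
    rate: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PrevalenceEstimate:
    count: int
    population: float
    percent: float


DEFAULT_AGE_BANDS = ["0-9", "10-19", "20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+"]


def age_band(age: int, width: int = 10, top: int = 80) -> str:
    """10-year age band label ('0-9', ..., '80+') for an attained age."""
    if age < 0:
        raise ValueError(f"negative age {age}")
    if age >= top:
        return f"{top}+"
    lo = (age // width) * width
    return f"{lo}-{lo + width - 1}"


def band_bounds(label: str) -> tuple[int, int]:
    if label.endswith("+"):
        return int(label[:-1]), 200
    lo, hi = label.split("-")
    return int(lo), int(hi)


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (display convention for report tables)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def person_years(
    pop: pd.DataFrame,
    year: int,
    sex: str | None = None,
    ages: tuple[int, int] | None = None,
) -> float:
    """Mean of the Jan-1 populations of *year* and *year + 1* for a stratum.

    *pop* has columns year, sex, age, count.  *ages* is an inclusive
    age range applied identically at both reference dates (the usual
    mean population of an age group, not a birth cohort).
    """
    desc = f"year={year}, sex={sex or 'all'}, ages={ages or 'all'}"

    def _total(y: int) -> float:
        sub = pop[pop["year"] == y]
        if sub.empty:
            raise DataError(f"population counts missing for Jan 1 {y} ({desc})")
        if sex is not None:
            sub = sub[sub["sex"] == sex]
        if ages is not None:
            sub = sub[(sub["age"] >= ages[0]) & (sub["age"] <= ages[1])]
        return float(sub["count"].sum())

    return (_total(year) + _total(year + 1)) / 2.0


def incidence_rate(
    count: int,
    py: float,
    alpha: float = 0.05,
    scale: float = 1e5,
    method: str = "wald",
) -> RateEstimate:
    """Incidence rate per *scale* person-years with a Wald CI.

    ``method="wald"`` (default) builds the CI on the rate scale,
    ``method="log"`` on the log-rate scale.  ``count == 0`` yields a zero
    lower bound and the rule-of-three upper bound ``3 / py * scale``.
    """
    if py <= 0:
        raise ValueError(f"person-years must be positive, got {py}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    z = stats.norm.ppf(1 - alpha / 2)
    rate = count / py * scale
    if count == 0:
        return RateEstimate(0, py, 0.0, 0.0, 3.0 / py * scale)
    if method == "wald":
        half = z / math.sqrt(count)
        lo, hi = max(0.0, rate * (1 - half)), rate * (1 + half)
    elif method == "log":
        half = z / math.sqrt(count)
        lo, hi = rate * math.exp(-half), rate * math.exp(half)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return RateEstimate(count, py, rate, lo, hi)


def prevalence(count: int, population: float) -> PrevalenceEstimate:
    """Prevalence proportion in percent."""
    if population <= 0:
        raise ValueError(f"population must be positive, got {population}")
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return PrevalenceEstimate(count, population, count / population * 100.0)


_OUTCOMES = {
    "any": ("prevalent_any", "incident_any"),
    "oad": ("prevalent_oad", "incident_oad"),
    "insulin_only": ("prevalent_insulin_only", "incident_insulin_only"),
}
_STRATA_SEX = [("women", "female"), ("men", "male"), ("total", None)]


def make_table(
    statuses: pd.DataFrame,
    pop: pd.DataFrame,
    coverage: RegistryCoverage,
    windows: WindowConfig | None = None,
    years=None,
    alpha: float = 0.05,
    by_age: bool = False,
) -> pd.DataFrame:
    """Report-style long table of incidence and prevalence cells.

    One row per (year, stratum, outcome, measure).  Strata are women,
    men and total (optionally crossed with 10-year age bands).
    Unobservable (year, outcome) combinations are emitted with
    ``observable == False`` and missing estimates, never dropped, so a
    report can mark them explicitly.
    """
    windows = windows or WindowConfig()
    years = list(years) if years is not None else list(coverage.years)
    age = statuses["year"] - statuses["birth_year"] if len(statuses) else pd.Series(dtype=int)
    bands = statuses.assign(age_band=age.map(age_band) if len(statuses) else None)

    strata: list[tuple[str, str | None, tuple[int, int] | None]] = [
        (label, sexval, None) for label, sexval in _STRATA_SEX
    ]
    if by_age:
        for label, sexval in _STRATA_SEX:
            for b in DEFAULT_AGE_BANDS:
                strata.append((f"{label} {b}", sexval, band_bounds(b)))

    rows = []
    for year in years:
        obs = {
            ("any", "prevalence"): prevalence_observable(year, coverage),
            ("oad", "prevalence"): prevalence_observable(year, coverage),
            ("insulin_only", "prevalence"): insulin_only_observable(year, coverage, windows),
            ("any", "incidence"): incidence_observable(year, coverage, windows),
            ("oad", "incidence"): incidence_observable(year, coverage, windows),
            ("insulin_only", "incidence"): insulin_only_observable(year, coverage, windows),
        }
        in_year = bands[bands["year"] == year] if len(bands) else bands
        for label, sexval, ages in strata:
            try:
                py = person_years(pop, year, sex=sexval, ages=ages)
            except DataError:
                py = np.nan
            sub = in_year
            if len(sub) and sexval is not None:
                sub = sub[sub["sex"] == sexval]
            if len(sub) and ages is not None:
                a = sub["year"] - sub["birth_year"]
                sub = sub[(a >= ages[0]) & (a <= ages[1])]
            for outcome, (prev_col, inc_col) in _OUTCOMES.items():
                for measure, col in (("prevalence", prev_col), ("incidence", inc_col)):
                    observable = obs[(outcome, measure)] and np.isfinite(py) and py > 0
                    count = int(sub[col].sum()) if observable and len(sub) else (0 if observable else None)
                    if not observable:
                        est = lo = hi = None
                    elif measure == "incidence":
                        r = incidence_rate(count, py, alpha=alpha)
                        est, lo, hi = r.rate, r.ci_low, r.ci_high
                    else:
                        est, lo, hi = prevalence(count, py).percent, None, None
                    rows.append(
                        {
                            "year": year,
                            "stratum": label,
                            "outcome": outcome,
                            "measure": measure,
                            "observable": observable,
                            "count": count,
                            "denominator": py,
                            "estimate": est,
                            "ci_low": lo,
                            "ci_high": hi,
                        }
                    )
    return pd.DataFrame(rows)
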