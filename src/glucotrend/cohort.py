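"""Windowed prevalent/incident user classification for dispensing histories.

Definitions (per calendar year, per person):

* prevalent user of any A10 / of OAD: at least one fill of that class in
  the year;
* prevalent user of insulins only: at least one insulin (A10A) fill in
  the year and no OAD (A10B) fill in the closed window
  ``[anchor - washout, anchor + lookforward]`` around the first insulin
  fill of the year (the anchor).  An OAD fill on the anchor date itself
  counts: same-day insulin+OAD is combination therapy, not insulins only;
* incident user: the first fill of the class in the year is preceded by a
  washout free of ANY blood glucose-lowering drug, i.e. no A10 fill in
  ``[anchor - washout, anchor)`` (the anchor fill itself never
  disqualifies).  Incident insulins-only users additionally have no OAD
  fill in ``[anchor, anchor + lookforward]``;
* windows are calendar-month shifts of the anchor date (same day of
  month, clamped to month end), defaults 24 months washout and 12 months
  lookforward.

A year is *observable* for a measure only when every possible window in
that year lies inside registry coverage; e.g. with coverage 2004-2011 and
default windows, incidence is observable 2006-2011 and insulins-only
measures 2006-2010.  Flags for unobservable (year, measure) pairs are
left False and the corresponding observability column is False, so
consumers can distinguish "not a user" from "cannot be assessed".

Re-incidence is permitted: a person whose fills resume after a gap
longer than the washout is incident again in the year of resumption.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DrugClass, RegistryCoverage

STATUS_FLAG_COLUMNS = [
    "prevalent_any",
    "prevalent_oad",
    "prevalent_insulin_only",
    "incident_any",
    "incident_oad",
    "incident_insulin_only",
]
STATUS_ANCHOR_COLUMNS = ["anchor_any", "anchor_oad", "anchor_insulin"]
STATUS_OBS_COLUMNS = [
    "observable_prevalence",
    "observable_incidence",
    "observable_insulin_only",
]
STATUS_COLUMNS = (
    ["person_id", "sex", "birth_year", "year"]
    + STATUS_FLAG_COLUMNS
    + STATUS_ANCHOR_COLUMNS
    + STATUS_OBS_COLUMNS
)


@dataclass(frozen=True)
class WindowConfig:
    """Washout and lookforward window lengths in calendar months."""

    washout_months: int = 24
    lookforward_months: int = 12

    def __post_init__(self) -> None:
        if self.washout_months < 1 or self.lookforward_months < 1:
            raise ValueError("window lengths must be at least one month")


def shift_months(date, months: int) -> pd.Timestamp:
    """Shift a date by whole calendar months, clamping to month end.

    ``shift_months("2010-01-31", 1) == 2010-02-28``.  This is the window
    arithmetic used throughout: "24 months prior" means the same day of
    month two years earlier, not 730 days.
    """
    ts = pd.Timestamp(date)
    total = ts.year * 12 + (ts.month - 1) + months
    year, month0 = divmod(total, 12)
    day = min(ts.day, calendar.monthrange(year, month0 + 1)[1])
    return pd.Timestamp(year=year, month=month0 + 1, day=day)


# ---------------------------------------------------------------------------
# observability

def prevalence_observable(year: int, coverage: RegistryCoverage) -> bool:
    """The whole calendar year lies inside coverage."""
    return coverage.start <= pd.Timestamp(year, 1, 1) and pd.Timestamp(year, 12, 31) <= coverage.end


def incidence_observable(year: int, coverage: RegistryCoverage, windows: WindowConfig) -> bool:
    """Every washout window anchored in the year lies inside coverage."""
    if not prevalence_observable(year, coverage):
        return False
    return shift_months(pd.Timestamp(year, 1, 1), -windows.washout_months) >= coverage.start


def insulin_only_observable(year: int, coverage: RegistryCoverage, windows: WindowConfig) -> bool:
    """Washout and lookforward both observable for any anchor in the year."""
    if not incidence_observable(year, coverage, windows):
        return False
    return shift_months(pd.Timestamp(year, 12, 31), windows.lookforward_months) <= coverage.end


def observable_years(coverage: RegistryCoverage, windows: WindowConfig) -> dict[str, list[int]]:
    """Reportable years per measure given coverage and windows."""
    ys = list(coverage.years)
    return {
        "prevalence": [y for y in ys if prevalence_observable(y, coverage)],
        "incidence": [y for y in ys if incidence_observable(y, coverage, windows)],
        "insulin_only": [y for y in ys if insulin_only_observable(y, coverage, windows)],
    }


# ---------------------------------------------------------------------------
# per-person engine (int64 nanosecond timestamps, searchsorted windows)

def _i8(ts) -> int:
    return pd.Timestamp(ts).value


def _count_between(arr: np.ndarray, lo: int, hi: int, lo_closed=True, hi_closed=True) -> int:
    left = np.searchsorted(arr, lo, side="left" if lo_closed else "right")
    right = np.searchsorted(arr, hi, side="right" if hi_closed else "left")
    return int(max(0, right - left))


def _first_in(arr: np.ndarray, lo: int, hi: int):
    i = np.searchsorted(arr, lo, side="left")
    if i < len(arr) and arr[i] <= hi:
        return int(arr[i])
    return None


def _status_for_year(
    any_d: np.ndarray,
    oad_d: np.ndarray,
    ins_d: np.ndarray,
    year: int,
    windows: WindowConfig,
    coverage: RegistryCoverage,
) -> dict:
    y0, y1 = _i8(pd.Timestamp(year, 1, 1)), _i8(pd.Timestamp(year, 12, 31))
    obs_prev = prevalence_observable(year, coverage)
    obs_inc = incidence_observable(year, coverage, windows)
    obs_io = insulin_only_observable(year, coverage, windows)

    a_any = _first_in(any_d, y0, y1)
    a_oad = _first_in(oad_d, y0, y1)
    a_ins = _first_in(ins_d, y0, y1)

    w, lf = windows.washout_months, windows.lookforward_months

    prevalent_any = obs_prev and a_any is not None
    prevalent_oad = obs_prev and a_oad is not None

    prevalent_io = False
    if obs_io and a_ins is not None:
        lo = _i8(shift_months(a_ins, -w))
        hi = _i8(shift_months(a_ins, lf))
        prevalent_io = _count_between(oad_d, lo, hi) == 0

    incident_any = False
    if obs_inc and a_any is not None:
        lo = _i8(shift_months(a_any, -w))
        incident_any = _count_between(any_d, lo, a_any, hi_closed=False) == 0

    incident_oad = False
    if obs_inc and a_oad is not None:
        lo = _i8(shift_months(a_oad, -w))
        incident_oad = _count_between(any_d, lo, a_oad, hi_closed=False) == 0

    incident_io = False
    if obs_io and a_ins is not None:
        lo = _i8(shift_months(a_ins, -w))
        hi = _i8(shift_months(a_ins, lf))
        incident_io = (
            _count_between(any_d, lo, a_ins, hi_closed=False) == 0
            and _count_between(oad_d, a_ins, hi) == 0
        )

    return {
        "year": year,
        "prevalent_any": prevalent_any,
        "prevalent_oad": prevalent_oad,
        "prevalent_insulin_only": prevalent_io,
        "incident_any": incident_any,
        "incident_oad": incident_oad,
        "incident_insulin_only": incident_io,
        "anchor_any": pd.Timestamp(a_any) if a_any is not None else pd.NaT,
        "anchor_oad": pd.Timestamp(a_oad) if a_oad is not None else pd.NaT,
        "anchor_insulin": pd.Timestamp(a_ins) if a_ins is not None else pd.NaT,
        "observable_prevalence": obs_prev,
        "observable_incidence": obs_inc,
        "observable_insulin_only": obs_io,
    }


def _class_arrays(history: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    codes = history["atc_code"].to_numpy(dtype=object)
    dates = pd.to_datetime(history["dispense_date"]).to_numpy(dtype="datetime64[ns]").view("int64")
    prefix4 = np.array([c[:4] for c in codes], dtype=object)
    prefix3 = np.array([c[:3] for c in codes], dtype=object)
    ins = dates[prefix4 == "A10A"]
    oad = dates[prefix4 == "A10B"]
    any_ = dates[prefix3 == "A10"]
    return any_, oad, ins


def _require_sorted(history: pd.DataFrame) -> None:
    d = pd.to_datetime(history["dispense_date"]).to_numpy()
    if len(d) > 1 and (np.diff(d.view("int64")) < 0).any():
        raise ValueError("history must be sorted by dispense_date")


# ---------------------------------------------------------------------------
# public per-person operations

def first_fill_in_year(history: pd.DataFrame, year: int, drug_class: DrugClass):
    """Earliest fill of *drug_class* within the calendar year, or None.

    *history* holds one person's records sorted by date, with columns
    ``dispense_date`` and ``atc_code``.
    """
    _require_sorted(history)
    any_d, oad_d, ins_d = _class_arrays(history)
    arr = {DrugClass.ANY_A10: any_d, DrugClass.OAD: oad_d, DrugClass.INSULIN: ins_d}.get(drug_class)
    if arr is None:
        raise ValueError(f"unsupported class query {drug_class}")
    hit = _first_in(arr, _i8(pd.Timestamp(year, 1, 1)), _i8(pd.Timestamp(year, 12, 31)))
    return pd.Timestamp(hit) if hit is not None else None


def classify_prevalent(
    history: pd.DataFrame,
    year: int,
    windows: WindowConfig,
    coverage: RegistryCoverage,
) -> dict:
    """Prevalence flags for one person-year (see module docstring)."""
    _require_sorted(history)
    row = _status_for_year(*_class_arrays(history), year, windows, coverage)
    keys = (
        ["year", "prevalent_any", "prevalent_oad", "prevalent_insulin_only"]
        + STATUS_ANCHOR_COLUMNS
        + ["observable_prevalence", "observable_insulin_only"]
    )
    return {k: row[k] for k in keys}


def classify_incident(
    history: pd.DataFrame,
    year: int,
    windows: WindowConfig,
    coverage: RegistryCoverage,
) -> dict:
    """Incidence flags for one person-year (see module docstring)."""
    _require_sorted(history)
    row = _status_for_year(*_class_arrays(history), year, windows, coverage)
    keys = (
        ["year", "incident_any", "incident_oad", "incident_insulin_only"]
        + STATUS_ANCHOR_COLUMNS
        + ["observable_incidence", "observable_insulin_only"]
    )
    return {k: row[k] for k in keys}


# ---------------------------------------------------------------------------
# registry-level operations

def classify_registry(
    records: pd.DataFrame,
    coverage: RegistryCoverage,
    windows: WindowConfig | None = None,
    years=None,
) -> pd.DataFrame:
    """Classify every person with at least one A10 fill, per calendar year.

    Returns one row per (person, evaluated year) with prevalence and
    incidence flags, anchor dates and observability indicators.  Persons
    whose records are all non-A10 contribute no rows.  Output is
    deterministic and independent of input record order.
    """
    windows = windows or WindowConfig()
    years = list(years) if years is not None else list(coverage.years)
    if records.empty:
        return pd.DataFrame(columns=STATUS_COLUMNS).astype({"year": int})

    recs = records.sort_values(["person_id", "dispense_date", "atc_code"], kind="stable")
    rows: list[dict] = []
    has_attrs = "sex" in recs.columns and "birth_year" in recs.columns
    for pid, sub in recs.groupby("person_id", sort=True):
        any_d, oad_d, ins_d = _class_arrays(sub)
        if len(any_d) == 0:
            continue
        sex = sub["sex"].iloc[0] if has_attrs else None
        by = int(sub["birth_year"].iloc[0]) if has_attrs else -1
        for year in years:
            row = _status_for_year(any_d, oad_d, ins_d, year, windows, coverage)
            row["person_id"] = pid
            row["sex"] = sex
            row["birth_year"] = by
            rows.append(row)
    out = pd.DataFrame(rows, columns=STATUS_COLUMNS)
    return out.reset_index(drop=True)


def write_statuses(statuses: pd.DataFrame, path) -> None:
    out = statuses[STATUS_COLUMNS].copy()
    for c in STATUS_ANCHOR_COLUMNS:
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_statuses(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str, "sex": str})
    for c in STATUS_ANCHOR_COLUMNS:
        df[c] = pd.to_datetime(df[c], format="%Y-%m-%d", errors="coerce")
    for c in STATUS_FLAG_COLUMNS + STATUS_OBS_COLUMNS:
        df[c] = df[c].astype(bool)
    return df[STATUS_COLUMNS]


def sensitivity_sweep(
    records: pd.DataFrame,
    year: int,
    windows_list,
    coverage: RegistryCoverage,
) -> pd.DataFrame:
    """Counts for one target year under alternative window configurations.

    One row per :class:`WindowConfig` with the prevalent insulins-only
    count and the incident counts.  Unobservable combinations carry an
    explicit False observability flag and missing counts rather than
    being silently dropped.  Counts are non-increasing in the washout.
    """
    rows = []
    for wc in windows_list:
        st = classify_registry(records, coverage, wc, years=[year])
        obs_inc = incidence_observable(year, coverage, wc)
        obs_io = insulin_only_observable(year, coverage, wc)

        def _n(col, ok):
            return int(st[col].sum()) if ok and len(st) else (0 if ok else pd.NA)

        rows.append(
            {
                "washout_months": wc.washout_months,
                "lookforward_months": wc.lookforward_months,
                "observable_incidence": obs_inc,
                "observable_insulin_only": obs_io,
                "prevalent_insulin_only": _n("prevalent_insulin_only", obs_io),
                "incident_any": _n("incident_any", obs_inc),
                "incident_oad": _n("incident_oad", obs_inc),
                "incident_insulin_only": _n("incident_insulin_only", obs_io),
            }
        )
    return pd.DataFrame(rows)


def _class_dates_by_person(records: pd.DataFrame, drug_class: DrugClass) -> dict[str, np.ndarray]:
    recs = records.sort_values(["person_id", "dispense_date"], kind="stable")
    mask = recs["atc_code"].map(lambda c: in_class_fast(c, drug_class))
    sub = recs[mask]
    dates = pd.to_datetime(sub["dispense_date"]).to_numpy(dtype="datetime64[ns]").view("int64")
    out: dict[str, np.ndarray] = {}
    for pid, idx in sub.groupby("person_id", sort=False).indices.items():
        out[pid] = dates[idx]
    return out


def in_class_fast(code: str, drug_class: DrugClass) -> bool:
    if drug_class is DrugClass.ANY_A10:
        return code.startswith("A10")
    if drug_class is DrugClass.INSULIN:
        return code.startswith("A10A")
    if drug_class is DrugClass.OAD:
        return code.startswith("A10B")
    return not code.startswith("A10")


_OUTCOME_FLAG = {
    "any": ("incident_any", "anchor_any", DrugClass.ANY_A10),
    "oad": ("incident_oad", "anchor_oad", DrugClass.OAD),
    "insulin_only": ("incident_insulin_only", "anchor_insulin", DrugClass.INSULIN),
}


def persistence_fraction(
    statuses: pd.DataFrame,
    records: pd.DataFrame,
    coverage: RegistryCoverage,
    months: int = 12,
    outcome: str = "oad",
    years=None,
):
    """Fraction of incident users redeeming more than one prescription.

    Among incident users of *outcome* whose ``[anchor, anchor + months]``
    window lies within coverage, the fraction with at least two fills of
    the defining drug class in that window (the anchor fill counts as the
    first).  Returns None when no user is evaluable.
    """
    flag, anchor_col, cls = _OUTCOME_FLAG[outcome]
    users = statuses[statuses[flag].astype(bool)]
    if years is not None:
        users = users[users["year"].isin(list(years))]
    dates_by_person = _class_dates_by_person(records, cls)
    n_eval = n_persist = 0
    for _, row in users.iterrows():
        anchor = row[anchor_col]
        hi = shift_months(anchor, months)
        if hi > coverage.end:
            continue
        arr = dates_by_person.get(row["person_id"], np.empty(0, dtype="int64"))
        n_eval += 1
        if _count_between(arr, _i8(anchor), _i8(hi)) >= 2:
            n_persist += 1
    return n_persist / n_eval if n_eval else None


def discontinuation_fraction(
    statuses: pd.DataFrame,
    records: pd.DataFrame,
    coverage: RegistryCoverage,
    horizon_months: int = 24,
    stop_window_months: int = 12,
    years=None,
    sex: str | None = None,
    age_range: tuple[int, int] | None = None,
):
    """Fraction of incident insulins-only users who stop within a horizon.

    "Stopped" means no insulin fill in the final *stop_window_months* of
    the *horizon_months* window after the anchor, i.e. in
    ``(anchor + horizon - stop_window, anchor + horizon]``.  Only users
    whose full horizon lies within coverage are evaluated.  Optional
    filters restrict to incident years, sex, and attained-age range
    (age = year - birth_year).  Returns None for an empty stratum.
    """
    users = statuses[statuses["incident_insulin_only"].astype(bool)]
    if years is not None:
        users = users[users["year"].isin(list(years))]
    if sex is not None:
        users = users[users["sex"] == sex]
    if age_range is not None:
        age = users["year"] - users["birth_year"]
        users = users[(age >= age_range[0]) & (age <= age_range[1])]
    ins_by_person = _class_dates_by_person(records, DrugClass.INSULIN)
    n_eval = n_stop = 0
    for _, row in users.iterrows():
        anchor = row["anchor_insulin"]
        hi = shift_months(anchor, horizon_months)
        if hi > coverage.end:
            continue
        lo = shift_months(anchor, horizon_months - stop_window_months)
        arr = ins_by_person.get(row["person_id"], np.empty(0, dtype="int64"))
        n_eval += 1
        if _count_between(arr, _i8(lo), _i8(hi), lo_closed=False) == 0:
            n_stop += 1
    return n_stop / n_eval if n_eval else None
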