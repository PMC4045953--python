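"""Brute-force reference classifier used only by the test suite.

For every (person, year, class) this oracle scans the person's entire
fill history against the literal window definitions, using
``pandas.tseries.offsets.DateOffset`` for calendar-month arithmetic —
an implementation independent of the package's searchsorted engine and
hand-rolled month shift.
"""

from __future__ import annotations

import pandas as pd
from pandas.tseries.offsets import DateOffset


def _is_ins(code: str) -> bool:
    return code.startswith("A10A")


def _is_oad(code: str) -> bool:
    return code.startswith("A10B")


def _is_any(code: str) -> bool:
    return code.startswith("A10")


def _minus_months(d: pd.Timestamp, m: int) -> pd.Timestamp:
    return d - DateOffset(months=m)


def _plus_months(d: pd.Timestamp, m: int) -> pd.Timestamp:
    return d + DateOffset(months=m)


def oracle_person_year(fills, year, washout, lookforward, cov_start, cov_end):
    """Classify one person-year from a list of (date, atc_code) tuples."""
    y0, y1 = pd.Timestamp(year, 1, 1), pd.Timestamp(year, 12, 31)

    obs_prev = cov_start <= y0 and y1 <= cov_end
    obs_inc = obs_prev and _minus_months(y0, washout) >= cov_start
    obs_io = obs_inc and _plus_months(y1, lookforward) <= cov_end

    def first_of(pred):
        in_year = [d for d, c in fills if pred(c) and y0 <= d <= y1]
        return min(in_year) if in_year else None

    a_any, a_oad, a_ins = first_of(_is_any), first_of(_is_oad), first_of(_is_ins)

    out = {
        "prevalent_any": obs_prev and a_any is not None,
        "prevalent_oad": obs_prev and a_oad is not None,
        "prevalent_insulin_only": False,
        "incident_any": False,
        "incident_oad": False,
        "incident_insulin_only": False,
        "anchor_any": a_any, "anchor_oad": a_oad, "anchor_insulin": a_ins,
        "observable_prevalence": obs_prev,
        "observable_incidence": obs_inc,
        "observable_insulin_only": obs_io,
    }

    if obs_io and a_ins is not None:
        lo, hi = _minus_months(a_ins, washout), _plus_months(a_ins, lookforward)
        out["prevalent_insulin_only"] = not any(
            _is_oad(c) and lo <= d <= hi for d, c in fills
        )

    def clean_washout(anchor):
        lo = _minus_months(anchor, washout)
        return not any(_is_any(c) and lo <= d < anchor for d, c in fills)

    if obs_inc and a_any is not None:
        out["incident_any"] = clean_washout(a_any)
    if obs_inc and a_oad is not None:
        out["incident_oad"] = clean_washout(a_oad)
    if obs_io and a_ins is not None:
        hi = _plus_months(a_ins, lookforward)
        no_oad_after = not any(_is_oad(c) and a_ins <= d <= hi for d, c in fills)
        out["incident_insulin_only"] = clean_washout(a_ins) and no_oad_after
    return out


def oracle_classify(records: pd.DataFrame, years, washout, lookforward, cov_start, cov_end):
    """Full-registry oracle: {(person_id, year): status dict} for A10 users."""
    cov_start, cov_end = pd.Timestamp(cov_start), pd.Timestamp(cov_end)
    out = {}
    for pid, sub in records.groupby("person_id"):
        fills = [
            (pd.Timestamp(d), c)
            for d, c in zip(sub["dispense_date"], sub["atc_code"])
        ]
        if not any(_is_any(c) for _, c in fills):
            continue
        for year in years:
            out[(pid, year)] = oracle_person_year(
                fills, year, washout, lookforward, cov_start, cov_end
            )
    return out
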