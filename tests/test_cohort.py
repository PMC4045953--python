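import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from pandas.tseries.offsets import DateOffset

from glucotrend import (
    DrugClass,
    RegistryCoverage,
    WindowConfig,
    classify_incident,
    classify_prevalent,
    classify_registry,
    discontinuation_fraction,
    first_fill_in_year,
    observable_years,
    persistence_fraction,
    sensitivity_sweep,
    shift_months,
)
from glucotrend.cohort import read_statuses, write_statuses

from conftest import make_records, random_registry
from naive_oracle import oracle_classify


# ---------------------------------------------------------------------------
# month arithmetic

@given(
    st.dates(min_value=pd.Timestamp("1995-01-01").date(), max_value=pd.Timestamp("2030-12-31").date()),
    st.integers(min_value=-80, max_value=80),
)
@settings(max_examples=300, deadline=None)
def test_shift_months_matches_pandas_dateoffset(date, months):
    """Calendar-month shift (clamped to month end) agrees with pandas."""
    expected = pd.Timestamp(date) + DateOffset(months=months)
    assert shift_months(date, months) == expected


def test_shift_months_clamps_to_month_end():
    assert shift_months("2010-01-31", 1) == pd.Timestamp("2010-02-28")
    assert shift_months("2008-02-29", -24) == pd.Timestamp("2006-02-28")
    assert shift_months("2010-05-01", -24) == pd.Timestamp("2008-05-01")


# ---------------------------------------------------------------------------
# first fill / prevalence / incidence single-person examples

def test_first_fill_in_year_picks_class_minimum():
    hist = make_records(
        [("P1", "2010-03-01", "A10BA02"), ("P1", "2010-07-01", "A10BA02"),
         ("P1", "2010-02-01", "A10BA02"), ("P1", "2010-05-01", "A10AB01")]
    )
    assert first_fill_in_year(hist, 2010, DrugClass.OAD) == pd.Timestamp("2010-02-01")
    assert first_fill_in_year(hist, 2010, DrugClass.INSULIN) == pd.Timestamp("2010-05-01")
    assert first_fill_in_year(hist, 2009, DrugClass.OAD) is None


def test_unsorted_history_rejected(coverage, windows):
    hist = make_records([("P1", "2010-07-01", "A10BA02"), ("P1", "2010-03-01", "A10BA02")])
    hist = hist.iloc[::-1].reset_index(drop=True)
    with pytest.raises(ValueError, match="sorted"):
        classify_prevalent(hist, 2010, windows, coverage)


def test_prevalent_insulin_only_without_oad(coverage, windows):
    hist = make_records([("P1", "2010-05-01", "A10AB01")])
    out = classify_prevalent(hist, 2010, windows, coverage)
    assert out["prevalent_any"] and out["prevalent_insulin_only"]
    assert not out["prevalent_oad"]


def test_prevalent_insulin_only_blocked_by_oad_in_window(coverage, windows):
    """OAD 2009-01-15 lies inside [2008-05-01, 2011-05-01] around the anchor."""
    hist = make_records([("P1", "2009-01-15", "A10BA02"), ("P1", "2010-05-01", "A10AB01")])
    out = classify_prevalent(hist, 2010, windows, coverage)
    assert out["prevalent_any"] and not out["prevalent_insulin_only"]


def test_same_day_insulin_plus_oad_is_combination_therapy(coverage, windows):
    hist = make_records([("P1", "2010-05-01", "A10AB01"), ("P1", "2010-05-01", "A10BA02")])
    prev = classify_prevalent(hist, 2010, windows, coverage)
    inc = classify_incident(hist, 2010, windows, coverage)
    assert not prev["prevalent_insulin_only"]
    assert not inc["incident_insulin_only"]
    assert inc["incident_any"] and inc["incident_oad"]


def test_insulin_only_unobservable_when_lookforward_leaves_coverage(coverage, windows):
    hist = make_records([("P1", "2011-06-01", "A10AB01")])
    out = classify_prevalent(hist, 2011, windows, coverage)
    assert not out["observable_insulin_only"]
    assert not out["prevalent_insulin_only"]
    assert out["prevalent_any"]


def test_reincidence_after_long_gap(coverage, windows):
    hist = make_records([("P1", "2006-03-01", "A10BA02"), ("P1", "2010-06-01", "A10BA02")])
    inc2006 = classify_incident(hist, 2006, windows, coverage)
    inc2010 = classify_incident(hist, 2010, windows, coverage)
    assert inc2006["incident_oad"] and inc2010["incident_oad"]


def test_insulin_fill_blocks_oad_washout_and_oad_blocks_lookforward(coverage, windows):
    hist = make_records([("P1", "2010-05-01", "A10AB01"), ("P1", "2010-08-01", "A10BA02")])
    out = classify_incident(hist, 2010, windows, coverage)
    assert out["incident_any"]
    assert not out["incident_oad"]           # insulin inside the OAD washout
    assert not out["incident_insulin_only"]  # OAD inside the lookforward


def test_run_in_year_not_observable_for_incidence(coverage, windows):
    hist = make_records([("P1", "2005-06-01", "A10BA02")])
    out = classify_incident(hist, 2005, windows, coverage)
    assert not out["observable_incidence"]
    assert not out["incident_oad"]


# ---------------------------------------------------------------------------
# observability ranges

def test_observable_years_match_reporting_ranges(coverage, windows):
    obs = observable_years(coverage, windows)
    assert obs["prevalence"] == list(range(2004, 2012))
    assert obs["incidence"] == list(range(2006, 2012))
    assert obs["insulin_only"] == list(range(2006, 2011))


# ---------------------------------------------------------------------------
# registry-level classification

def test_empty_registry(coverage):
    assert classify_registry(pd.DataFrame(columns=["person_id", "dispense_date", "atc_code"]), coverage).empty


def test_single_fill_registry_rows_and_incidence(coverage, windows):
    recs = make_records([("P1", "2008-04-01", "A10BA02")])
    st_ = classify_registry(recs, coverage, windows)
    assert len(st_) == 8  # one row per coverage year
    assert st_.loc[st_["year"] == 2008, "incident_oad"].item()
    assert st_["incident_oad"].sum() == 1
    assert st_.loc[st_["year"] == 2008, "prevalent_oad"].item()
    assert st_["prevalent_oad"].sum() == 1


def test_other_only_person_contributes_no_rows(coverage):
    recs = make_records([("P1", "2008-04-01", "C10AA05")])
    assert classify_registry(recs, coverage).empty


def _assert_matches_oracle(recs, coverage, windows, years):
    got = classify_registry(recs, coverage, windows, years=years)
    want = oracle_classify(
        recs, years, windows.washout_months, windows.lookforward_months,
        coverage.start, coverage.end,
    )
    assert len(got) == len(want)
    flags = [
        "prevalent_any", "prevalent_oad", "prevalent_insulin_only",
        "incident_any", "incident_oad", "incident_insulin_only",
        "observable_prevalence", "observable_incidence", "observable_insulin_only",
    ]
    for _, row in got.iterrows():
        ref = want[(row["person_id"], row["year"])]
        for f in flags:
            assert bool(row[f]) == bool(ref[f]), (row["person_id"], row["year"], f)
        for a in ("anchor_any", "anchor_oad", "anchor_insulin"):
            lhs = row[a] if pd.notna(row[a]) else None
            assert lhs == ref[a], (row["person_id"], row["year"], a)


def test_three_person_toy_registry_matches_oracle(coverage, windows):
    recs = make_records(
        [
            ("A", "2006-02-10", "A10BA02"), ("A", "2007-11-01", "A10AB01"),
            ("B", "2009-03-03", "A10AB01"), ("B", "2009-06-03", "A10AB01"),
            ("C", "2004-05-05", "A10XA01"), ("C", "2008-01-31", "A10BA02"),
        ]
    )
    _assert_matches_oracle(recs, coverage, windows, list(coverage.years))


def test_random_registries_match_oracle(coverage, windows):
    rng = np.random.default_rng(20260926)
    for _ in range(30):
        recs = random_registry(rng, int(rng.integers(1, 25)), coverage)
        _assert_matches_oracle(recs, coverage, windows, list(coverage.years))


def test_classification_is_order_invariant(coverage, windows):
    rng = np.random.default_rng(7)
    recs = random_registry(rng, 30, coverage)
    shuffled = recs.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a = classify_registry(recs, coverage, windows).reset_index(drop=True)
    b = classify_registry(shuffled, coverage, windows).reset_index(drop=True)
    pd.testing.assert_frame_equal(a, b)


def test_translation_invariance_by_whole_years(windows):
    rng = np.random.default_rng(11)
    cov = RegistryCoverage.from_years(2004, 2011)
    recs = random_registry(rng, 25, cov)  # days 1-28 only: safe to shift
    k = 3
    shifted = recs.copy()
    shifted["dispense_date"] = shifted["dispense_date"].map(
        lambda d: d.replace(year=d.year + k)
    )
    cov_k = RegistryCoverage.from_years(2004 + k, 2011 + k)
    a = classify_registry(recs, cov, windows)
    b = classify_registry(shifted, cov_k, windows)
    assert (b["year"].to_numpy() == a["year"].to_numpy() + k).all()
    flags = ["prevalent_any", "prevalent_oad", "prevalent_insulin_only",
             "incident_any", "incident_oad", "incident_insulin_only"]
    for f in flags:
        assert (a[f].to_numpy() == b[f].to_numpy()).all(), f


def test_partition_bounds_and_invariants(coverage, windows):
    rng = np.random.default_rng(13)
    for _ in range(20):
        recs = random_registry(rng, 40, coverage)
        st_ = classify_registry(recs, coverage, windows)
        # incident implies prevalent, per outcome
        assert not (st_["incident_any"] & ~st_["prevalent_any"]).any()
        assert not (st_["incident_oad"] & ~st_["prevalent_oad"]).any()
        assert not (st_["incident_insulin_only"] & ~st_["prevalent_insulin_only"]).any()
        # insulins-only excludes OAD use in the same year
        assert not (st_["prevalent_insulin_only"] & st_["prevalent_oad"]).any()
        # incident flags only where observable
        assert not (st_["incident_any"] & ~st_["observable_incidence"]).any()
        assert not (st_["incident_insulin_only"] & ~st_["observable_insulin_only"]).any()
        per_year = st_.groupby("year")[
            ["incident_any", "incident_oad", "incident_insulin_only",
             "prevalent_any", "prevalent_oad", "prevalent_insulin_only"]
        ].sum()
        assert (per_year["incident_any"] >= per_year["incident_oad"] + per_year["incident_insulin_only"]).all()
        assert (per_year["prevalent_any"] >= per_year[["prevalent_oad", "prevalent_insulin_only"]].max(axis=1)).all()


def test_status_csv_roundtrip(tmp_path, coverage, windows):
    rng = np.random.default_rng(5)
    st_ = classify_registry(random_registry(rng, 10, coverage), coverage, windows)
    path = tmp_path / "statuses.csv"
    write_statuses(st_, path)
    back = read_statuses(path)
    pd.testing.assert_frame_equal(back, st_.reset_index(drop=True), check_dtype=False)


# ---------------------------------------------------------------------------
# sensitivity sweep

def test_sweep_counts_non_increasing_in_washout(coverage):
    rng = np.random.default_rng(17)
    recs = random_registry(rng, 40, coverage)
    sweep = sensitivity_sweep(
        recs, 2010, [WindowConfig(w, 12) for w in (24, 36, 48, 60, 72)], coverage
    )
    for col in ("prevalent_insulin_only", "incident_any", "incident_oad", "incident_insulin_only"):
        vals = sweep[col].to_numpy(dtype=float)
        assert (np.diff(vals) <= 0).all(), col


def test_sweep_planted_switchers_strictly_decrease(coverage):
    rows = []
    for i in range(5):  # OAD in 2005, insulin-only from mid-2010
        rows += [
            (f"S{i}", "2005-03-01", "A10BA02"), (f"S{i}", "2005-09-01", "A10BA02"),
            (f"S{i}", "2010-06-01", "A10AB01"), (f"S{i}", "2010-09-01", "A10AB01"),
        ]
    rows += [("T0", "2010-04-01", "A10AB01")]  # clean insulin starter
    recs = make_records(rows)
    sweep = sensitivity_sweep(recs, 2010, [WindowConfig(24, 12), WindowConfig(72, 12)], coverage)
    assert sweep["prevalent_insulin_only"].tolist() == [6, 1]
    assert sweep["incident_insulin_only"].tolist() == [6, 1]
    assert sweep["incident_any"].tolist() == [6, 1]


def test_sweep_unobservable_window_flagged_not_dropped(coverage):
    recs = make_records([("P1", "2010-06-01", "A10AB01")])
    sweep = sensitivity_sweep(recs, 2010, [WindowConfig(24, 12), WindowConfig(96, 12)], coverage)
    assert len(sweep) == 2
    row = sweep.iloc[1]
    assert not row["observable_incidence"] and not row["observable_insulin_only"]
    assert pd.isna(row["incident_any"]) and pd.isna(row["prevalent_insulin_only"])


def test_sweep_single_insulin_only_person_counted_at_every_washout(coverage):
    recs = make_records([("P1", "2009-06-01", "A10AB01"), ("P1", "2010-02-01", "A10AB01")])
    sweep = sensitivity_sweep(recs, 2010, [WindowConfig(w, 12) for w in (24, 48, 72)], coverage)
    assert sweep["prevalent_insulin_only"].tolist() == [1, 1, 1]


# ---------------------------------------------------------------------------
# follow-up metrics

def test_persistence_fraction_enumerated_fixture(coverage, windows):
    rows = []
    # four incident OAD users in 2008; three refill within 12 months
    for i, refill in enumerate([True, True, True, False]):
        rows.append((f"P{i}", "2008-03-01", "A10BA02"))
        if refill:
            rows.append((f"P{i}", "2008-08-01", "A10BA02"))
    recs = make_records(rows)
    st_ = classify_registry(recs, coverage, windows)
    assert persistence_fraction(st_, recs, coverage, months=12, outcome="oad") == pytest.approx(0.75)


def test_persistence_fraction_degenerate_values(coverage, windows):
    one_fill = make_records([("P1", "2008-03-01", "A10BA02")])
    st_ = classify_registry(one_fill, coverage, windows)
    assert persistence_fraction(st_, one_fill, coverage, outcome="oad") == 0.0
    monthly = make_records(
        [("P1", f"2008-{m:02d}-01", "A10BA02") for m in range(3, 13)]
    )
    st2 = classify_registry(monthly, coverage, windows)
    assert persistence_fraction(st2, monthly, coverage, outcome="oad") == 1.0
    empty = classify_registry(make_records([("P1", "2008-01-01", "A10AB01")]), coverage, windows)
    assert persistence_fraction(empty, one_fill, coverage, outcome="oad") is None


def test_discontinuation_fraction_enumerated_fixture(coverage, windows):
    rows = []
    for i in range(10):
        pid = f"W{i}"
        rows.append((pid, "2008-02-01", "A10AB01", "female", 1975))
        if i >= 6:  # four continue through the horizon; six stop early
            for m in (8, 14, 20, 26):
                rows.append((pid, f"{2008 + m // 12}-{m % 12 + 1:02d}-01", "A10AB01", "female", 1975))
        else:
            rows.append((pid, "2008-06-01", "A10AB01", "female", 1975))
    recs = make_records(rows)
    st_ = classify_registry(recs, coverage, windows)
    frac = discontinuation_fraction(
        st_, recs, coverage, horizon_months=24, years=[2008], sex="female", age_range=(30, 39)
    )
    assert frac == pytest.approx(0.6)


def test_discontinuation_fraction_degenerate_values(coverage, windows):
    cont = make_records([("P1", f"2008-{m:02d}-01", "A10AB01") for m in range(1, 13)]
                        + [("P1", f"2009-{m:02d}-01", "A10AB01") for m in range(1, 13)]
                        + [("P1", "2010-01-05", "A10AB01")])
    st_ = classify_registry(cont, coverage, windows)
    assert discontinuation_fraction(st_, cont, coverage, years=[2008]) == 0.0
    single = make_records([("P2", "2008-03-01", "A10AB01")])
    st2 = classify_registry(single, coverage, windows)
    assert discontinuation_fraction(st2, single, coverage, years=[2008]) == 1.0
    assert discontinuation_fraction(st2, single, coverage, years=[2008], sex="male") is None
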