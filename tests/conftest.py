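import numpy as np
import pandas as pd
import pytest

from glucotrend import RegistryCoverage, WindowConfig

ATC_POOL = [
    "A10AB01", "A10AE04",          # insulins
    "A10BA02", "A10BB12", "A10BX99",  # oral antidiabetics
    "A10XA01",                     # other A10
    "C10AA05", "N02BE01",          # non-A10 (ignored by the classifier)
]


@pytest.fixture
def coverage() -> RegistryCoverage:
    return RegistryCoverage.from_years(2004, 2011)


@pytest.fixture
def windows() -> WindowConfig:
    return WindowConfig()


def make_records(rows) -> pd.DataFrame:
    """Build a dispensing frame from (person_id, date, atc) or 5-tuples."""
    full = []
    for r in rows:
        if len(r) == 3:
            pid, date, atc = r
            full.append((pid, date, atc, "female", 1960))
        else:
            full.append(tuple(r))
    df = pd.DataFrame(full, columns=["person_id", "dispense_date", "atc_code", "sex", "birth_year"])
    df["dispense_date"] = pd.to_datetime(df["dispense_date"])
    return df.sort_values(["person_id", "dispense_date", "atc_code"]).reset_index(drop=True)


def random_registry(rng: np.random.Generator, n_persons: int, coverage: RegistryCoverage) -> pd.DataFrame:
    """Small random registry with dates inside coverage (day 1-28 only,
    so year-shift invariance tests avoid leap-day clamping)."""
    rows = []
    start_y, end_y = coverage.start.year, coverage.end.year
    for i in range(n_persons):
        sex = "female" if rng.random() < 0.5 else "male"
        birth_year = int(rng.integers(1920, 2005))
        for _ in range(int(rng.integers(0, 9))):
            date = pd.Timestamp(
                int(rng.integers(start_y, end_y + 1)),
                int(rng.integers(1, 13)),
                int(rng.integers(1, 29)),
            )
            atc = ATC_POOL[int(rng.integers(len(ATC_POOL)))]
            rows.append((f"R{i:03d}", date, atc, sex, birth_year))
    if not rows:
        rows = [("R000", pd.Timestamp(start_y, 6, 1), "A10BA02", "female", 1960)]
    return make_records(rows)
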