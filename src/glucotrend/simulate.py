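"""Synthetic dispensing-registry simulator with known ground truth.

The generator emulates a nationwide pharmacy registry of blood
glucose-lowering drug fills over a fixed coverage window:

* a closed population with an age/sex pyramid, observed at every Jan 1;
* drug-treatment onset as an exponential waiting time with
  piecewise-constant yearly hazards by age band and sex, multiplied by a
  calendar trend ``annual_irr ** (year - start_year)``;
* onsets are also drawn for a configurable number of years *before*
  coverage, so baseline prevalent users enter with left-truncated fill
  streams and exercise the run-in behaviour of the classifier;
* a treatment-modality mix: OAD only, insulins only, or OAD with a later
  switch to insulin (exponential switch delay);
* refill streams with gamma-distributed intervals from onset until
  attrition, discontinuation or coverage end;
* transient insulin episodes in women of reproductive age (gestational
  diabetes): a configurable share of female insulin starters aged 20-44
  stop after 4-9 months;
* metformin use without diabetes in women 18-45 (PCOS), emitted as
  A10BA02 fills with no diabetes truth record.

All randomness flows from one ``numpy`` generator seeded from the
config, so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .rates import age_band

INSULIN_CODES = ("A10AB01", "A10AC01", "A10AD01", "A10AE04")
OAD_CODES = ("A10BA02", "A10BB12", "A10BG03", "A10BH02")
METFORMIN = "A10BA02"

MODALITIES = ("oad_only", "oad_then_insulin", "insulin_only")

#: baseline treatment-onset rates per 100,000 person-years, rising with
#: age, women slightly higher before 40 and men after (per-sex values
#: chosen once as plausible national-scale magnitudes)
DEFAULT_ONSET_RATE: dict[str, dict[str, float]] = {
    "0-9": {"female": 5.0, "male": 5.0},
    "10-19": {"female": 20.0, "male": 20.0},
    "20-29": {"female": 45.0, "male": 30.0},
    "30-39": {"female": 95.0, "male": 75.0},
    "40-49": {"female": 170.0, "male": 220.0},
    "50-59": {"female": 380.0, "male": 480.0},
    "60-69": {"female": 600.0, "male": 750.0},
    "70-79": {"female": 650.0, "male": 820.0},
    "80+": {"female": 480.0, "male": 600.0},
}


def _default_mix() -> dict[str, float]:
    return {"oad_only": 0.73, "oad_then_insulin": 0.17, "insulin_only": 0.10}


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic registry."""

    seed: int = 0
    start_year: int = 2004
    end_year: int = 2011
    n_persons: int = 50_000
    pre_coverage_years: int = 10
    max_age: int = 89
    onset_rate: dict[str, dict[str, float]] = field(default_factory=lambda: {
        b: dict(v) for b, v in DEFAULT_ONSET_RATE.items()
    })
    annual_irr: float = 1.0
    modality_mix: dict[str, float] = field(default_factory=_default_mix)
    switch_delay_years: float = 4.0
    refill_interval_days: float = 90.0
    refill_cv: float = 0.3
    gestational_fraction: float = 0.6
    gestational_age_range: tuple[int, int] = (20, 44)
    gestational_duration_months: tuple[float, float] = (4.0, 9.0)
    pcos_rate: float = 50.0
    pcos_age_range: tuple[int, int] = (18, 45)
    pcos_duration_years: float = 2.0
    attrition_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.start_year >= self.end_year:
            raise ValueError("start_year must precede end_year")
        if self.n_persons < 1:
            raise ValueError("n_persons must be positive")
        total = sum(self.modality_mix.get(m, 0.0) for m in MODALITIES)
        if abs(total - 1.0) > 1e-9 or set(self.modality_mix) - set(MODALITIES):
            raise ValueError(f"modality_mix must assign probabilities to {MODALITIES} summing to 1")
        for name in ("gestational_fraction",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("annual_irr", "refill_interval_days", "refill_cv", "switch_delay_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("pcos_rate", "attrition_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for band, by_sex in self.onset_rate.items():
            for s, r in by_sex.items():
                if r < 0:
                    raise ValueError(f"onset_rate[{band}][{s}] must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gestational_age_range"] = list(self.gestational_age_range)
        d["gestational_duration_months"] = list(self.gestational_duration_months)
        d["pcos_age_range"] = list(self.pcos_age_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("gestational_age_range", "gestational_duration_months", "pcos_age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _pyramid_weights(max_age: int) -> np.ndarray:
    ages = np.arange(max_age + 1, dtype=float)
    w = np.where(ages < 50, 1.0, np.exp(-(ages - 50) / 15.0))
    return w / w.sum()


def _draw_persons(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_persons
    ages0 = rng.choice(config.max_age + 1, size=n, p=_pyramid_weights(config.max_age))
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    width = len(str(n))
    return pd.DataFrame(
        {
            "person_id": [f"P{i:0{width}d}" for i in range(n)],
            "sex": sex,
            "birth_year": config.start_year - ages0,
        }
    )


def simulate_population(config: SimulationConfig) -> pd.DataFrame:
    """Jan-1 head counts per (year, sex, single-year age).

    Covers ``start_year .. end_year + 1`` so mean-population person-years
    can be formed for every coverage year.  The population is closed: the
    same persons age through the window (no births, deaths or migration).
    """
    rng = np.random.default_rng(config.seed)
    persons = _draw_persons(config, rng)
    rows = []
    for year in range(config.start_year, config.end_year + 2):
        age = year - persons["birth_year"]
        ok = (age >= 0) & (age <= 120)
        grp = (
            pd.DataFrame({"sex": persons["sex"][ok], "age": age[ok]})
            .groupby(["sex", "age"])
            .size()
            .reset_index(name="count")
        )
        grp.insert(0, "year", year)
        rows.append(grp)
    return pd.concat(rows, ignore_index=True)[["year", "sex", "age", "count"]]


def _rate_lookup(config: SimulationConfig, ages: np.ndarray, sexes: np.ndarray) -> np.ndarray:
    """Onset hazard per person-year for attained ages (vectorised).

    *ages* is (n_persons, n_years); *sexes* is (n_persons,).  Bands in
    the config must partition the non-negative ages (they do by default).
    """
    from .rates import band_bounds

    bands = sorted(config.onset_rate.keys(), key=band_bounds)
    lowers = np.array([band_bounds(b)[0] for b in bands])
    per_sex = {
        s: np.array([config.onset_rate[b][s] for b in bands]) / 1e5 for s in ("female", "male")
    }
    idx = np.clip(np.digitize(ages, lowers[1:], right=False), 0, len(bands) - 1)
    female = sexes == "female"
    out = np.where(female[:, None], per_sex["female"][idx], per_sex["male"][idx])
    out[(ages < 0) | (ages > 120)] = 0.0
    return out


def _fill_times(rng: np.random.Generator, start: float, stop: float,
                mean_days: float, cv: float) -> list[float]:
    """Refill instants (days) from *start* until *stop*, gamma intervals."""
    if start > stop:
        return []
    shape = 1.0 / (cv * cv)
    scale = mean_days / shape
    times = [start]
    t = start
    while True:
        t += rng.gamma(shape, scale)
        if t > stop:
            break
        times.append(t)
    return times


def simulate_dispensings(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a dispensing registry and its ground-truth table.

    Returns ``(records, truth)``.  Records are truncated to coverage
    (``start_year-01-01 .. end_year-12-31``); truth keeps one row per
    person with a treatment onset (PCOS metformin episodes produce fills
    but no truth row).
    """
    rng = np.random.default_rng(config.seed)
    persons = _draw_persons(config, rng)
    n = config.n_persons
    sexes = persons["sex"].to_numpy()
    birth_years = persons["birth_year"].to_numpy()

    epoch = pd.Timestamp(config.start_year, 1, 1)
    cov_start_day = 0.0
    cov_end_day = float((pd.Timestamp(config.end_year, 12, 31) - epoch).days)

    hazard_years = np.arange(config.start_year - config.pre_coverage_years, config.end_year + 1)
    year_start_day = np.array(
        [(pd.Timestamp(y, 1, 1) - epoch).days for y in hazard_years], dtype=float
    )
    year_len_day = np.array(
        [(pd.Timestamp(y + 1, 1, 1) - pd.Timestamp(y, 1, 1)).days for y in hazard_years],
        dtype=float,
    )

    ages_mat = hazard_years[None, :] - birth_years[:, None]
    rate_mat = _rate_lookup(config, ages_mat, sexes)
    rate_mat *= config.annual_irr ** (hazard_years - config.start_year)[None, :]

    p_mat = 1.0 - np.exp(-rate_mat)
    u = rng.random((n, len(hazard_years)))
    event = u < p_mat
    has_onset = event.any(axis=1)
    first_idx = np.argmax(event, axis=1)

    frac_u = rng.random(n)
    mix = np.array([config.modality_mix[m] for m in MODALITIES])
    modality_idx = np.searchsorted(np.cumsum(mix), rng.random(n), side="right")
    gest_u = rng.random(n)
    attr_e = rng.standard_exponential(n)
    switch_e = rng.standard_exponential(n)
    gest_months = rng.uniform(*config.gestational_duration_months, size=n)

    # PCOS episodes: women in the age range, same hazard-grid mechanism
    pcos_rate_mat = np.zeros_like(rate_mat)
    lo_a, hi_a = config.pcos_age_range
    eligible = (sexes == "female")[:, None] & (ages_mat >= lo_a) & (ages_mat <= hi_a)
    pcos_rate_mat[eligible] = config.pcos_rate / 1e5
    pcos_event = rng.random((n, len(hazard_years))) < (1.0 - np.exp(-pcos_rate_mat))
    pcos_has = pcos_event.any(axis=1)
    pcos_first = np.argmax(pcos_event, axis=1)
    pcos_frac = rng.random(n)
    pcos_dur_e = rng.standard_exponential(n)

    rec_pid: list[str] = []
    rec_day: list[float] = []
    rec_code: list[str] = []
    truth_rows: list[dict] = []

    def _emit(pid: str, days: list[float], code: str) -> None:
        for d in days:
            if cov_start_day <= d <= cov_end_day:
                rec_pid.append(pid)
                rec_day.append(d)
                rec_code.append(code)

    for i in np.nonzero(has_onset)[0]:
        k = first_idx[i]
        r = rate_mat[i, k]
        # waiting time within the onset year: exponential conditioned on < 1 year
        tau = -np.log(1.0 - frac_u[i] * (1.0 - np.exp(-r))) / r
        onset_day = year_start_day[k] + tau * year_len_day[k]
        onset_year = int(hazard_years[k])
        modality = MODALITIES[modality_idx[i]]
        pid = persons["person_id"].iloc[i]

        stop_day = cov_end_day
        if config.attrition_rate > 0:
            stop_day = min(stop_day, onset_day + attr_e[i] / config.attrition_rate * 365.25)

        ins_code = INSULIN_CODES[int(rng.integers(len(INSULIN_CODES)))]
        oad_code = OAD_CODES[int(rng.integers(len(OAD_CODES)))]
        disc_day: float | None = None

        if modality == "insulin_only":
            age_at_onset = onset_year - birth_years[i]
            gestational = (
                sexes[i] == "female"
                and config.gestational_age_range[0] <= age_at_onset <= config.gestational_age_range[1]
                and gest_u[i] < config.gestational_fraction
            )
            if gestational:
                gest_stop = onset_day + gest_months[i] * 30.44
                stop_day = min(stop_day, gest_stop)
                disc_day = gest_stop  # true stop, even when past coverage
            _emit(pid, _fill_times(rng, onset_day, stop_day,
                                   config.refill_interval_days, config.refill_cv), ins_code)
        elif modality == "oad_only":
            _emit(pid, _fill_times(rng, onset_day, stop_day,
                                   config.refill_interval_days, config.refill_cv), oad_code)
        else:  # oad_then_insulin
            switch_day = onset_day + switch_e[i] * config.switch_delay_years * 365.25
            oad_stop = min(switch_day, stop_day)
            _emit(pid, _fill_times(rng, onset_day, oad_stop,
                                   config.refill_interval_days, config.refill_cv), oad_code)
            if switch_day < stop_day:
                _emit(pid, _fill_times(rng, switch_day, stop_day,
                                       config.refill_interval_days, config.refill_cv), ins_code)

        if disc_day is None and stop_day < cov_end_day:
            disc_day = stop_day  # lost to observation (attrition)
        truth_rows.append(
            {
                "person_id": pid,
                "sex": sexes[i],
                "birth_year": int(birth_years[i]),
                "true_onset_date": epoch + pd.Timedelta(days=round(onset_day)),
                "true_modality": modality,
                "true_discontinuation_date": (
                    epoch + pd.Timedelta(days=round(disc_day)) if disc_day is not None else pd.NaT
                ),
            }
        )

    if config.pcos_rate > 0:
        for i in np.nonzero(pcos_has)[0]:
            k = pcos_first[i]
            r = pcos_rate_mat[i, k]
            tau = -np.log(1.0 - pcos_frac[i] * (1.0 - np.exp(-r))) / r
            start = year_start_day[k] + tau * year_len_day[k]
            stop = min(cov_end_day, start + pcos_dur_e[i] * config.pcos_duration_years * 365.25)
            _emit(persons["person_id"].iloc[i],
                  _fill_times(rng, start, stop, config.refill_interval_days, config.refill_cv),
                  METFORMIN)

    attrs = persons.set_index("person_id")
    records = pd.DataFrame(
        {
            "person_id": rec_pid,
            "dispense_date": epoch + pd.to_timedelta(np.round(rec_day).astype(int), unit="D"),
            "atc_code": rec_code,
        }
    )
    records["sex"] = records["person_id"].map(attrs["sex"]) if len(records) else pd.Series(dtype=str)
    records["birth_year"] = (
        records["person_id"].map(attrs["birth_year"]).astype(int) if len(records) else pd.Series(dtype=int)
    )
    records = records.sort_values(["person_id", "dispense_date", "atc_code"], kind="stable")
    records = records[["person_id", "dispense_date", "atc_code", "sex", "birth_year"]].reset_index(drop=True)

    truth = pd.DataFrame(
        truth_rows,
        columns=["person_id", "sex", "birth_year", "true_onset_date",
                 "true_modality", "true_discontinuation_date"],
    )
    return records, truth


def truth_summary(truth: pd.DataFrame, years) -> pd.DataFrame:
    """Gold-standard onset counts per (year, sex, age band).

    Classifier incident counts may legitimately differ through planned
    artefacts (PCOS metformin fills, re-incidence after long gaps); with
    those mechanisms disabled they match exactly on observable years.
    """
    years = list(years)
    if truth.empty:
        return pd.DataFrame(columns=["year", "sex", "age_band", "n_onsets"])
    t = truth.copy()
    t["year"] = pd.to_datetime(t["true_onset_date"]).dt.year
    t = t[t["year"].isin(years)]
    t["age_band"] = (t["year"] - t["birth_year"]).map(age_band)
    out = (
        t.groupby(["year", "sex", "age_band"]).size().reset_index(name="n_onsets")
    )
    return out.sort_values(["year", "sex", "age_band"]).reset_index(drop=True)


def write_truth(truth: pd.DataFrame, path) -> None:
    out = truth.copy()
    for c in ("true_onset_date", "true_discontinuation_date"):
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
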