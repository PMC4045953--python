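"""Calibration and recovery studies run on the synthetic registry.

National-registry microdata are not redistributable, so the statistical
machinery is validated by simulation instead: trend recovery (does the
Poisson IRR-per-year interval cover the simulated calendar trend?),
likelihood-ratio test size under a true no-interaction model, Wald
interval coverage for incidence rates, washout monotonicity of the
classifier, and recovery of a planted transient-insulin (gestational)
discontinuation fraction.  Every study takes a seed and derives one
child seed per replicate, so results are reproducible end to end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import WindowConfig, discontinuation_fraction, sensitivity_sweep
from .io import RegistryCoverage
from .rates import incidence_rate
from .simulate import SimulationConfig, simulate_dispensings, simulate_population
from .trend import ModelSpec, fit_poisson, incident_cells, irr_per_year, lr_test
from .cohort import classify_registry

_SEED_MOD = 2**31 - 1


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(1, _SEED_MOD, size=n)]


def _flat_rates(female: float, male: float | None = None) -> dict:
    male = female if male is None else male
    bands = ("0-9", "10-19", "20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+")
    return {b: {"female": female, "male": male} for b in bands}


def irr_recovery_study(
    seed: int,
    n_replicates: int = 50,
    n_persons: int = 20_000,
    true_irr: float = 0.95,
) -> dict:
    """Fraction of replicates whose 95% Wald IRR interval covers the truth.

    Each replicate simulates a registry with calendar trend *true_irr*,
    classifies incident users of any blood glucose-lowering drug, and
    fits the year + age + sex Poisson model on observable years.  The
    artefact mechanisms (PCOS metformin, transient gestational insulin,
    attrition) are switched off: they carry no calendar trend, so leaving
    them on would dilute the planted IRR toward 1 and the study would
    measure robustness to misclassification rather than trend recovery.
    """
    covered = 0
    estimates = []
    for s in _child_seeds(seed, n_replicates):
        cfg = SimulationConfig(
            seed=s, n_persons=n_persons, annual_irr=true_irr,
            pcos_rate=0.0, gestational_fraction=0.0, attrition_rate=0.0,
        )
        rec, _ = simulate_dispensings(cfg)
        pop = simulate_population(cfg)
        cov = RegistryCoverage.from_years(cfg.start_year, cfg.end_year)
        st = classify_registry(rec, cov, years=range(2006, cfg.end_year + 1))
        cells = incident_cells(st, pop, range(2006, cfg.end_year + 1), outcome="any")
        fit = fit_poisson(cells, ModelSpec())
        est = irr_per_year(fit)
        estimates.append(est.irr)
        covered += est.ci_low <= true_irr <= est.ci_high
    return {
        "coverage": covered / n_replicates,
        "n_replicates": n_replicates,
        "mean_irr": float(np.mean(estimates)),
        "true_irr": true_irr,
    }


def _null_interaction_cells() -> pd.DataFrame:
    """Deterministic no-interaction Poisson means at national-table scale."""
    rows = []
    age_effects = {"30-39": 0.0, "40-49": 0.8, "50-59": 1.6, "60-69": 2.1, "70-79": 2.2, "80+": 1.9}
    for year in range(2006, 2012):
        for sex in ("female", "male"):
            for band, eff in age_effects.items():
                py = 2e5
                log_rate = np.log(60 / 1e5) + np.log(0.97) * (year - 2008.5) + eff + (0.1 if sex == "male" else 0.0)
                rows.append({"year": year, "sex": sex, "age_band": band,
                             "person_years": py, "mu": py * np.exp(log_rate)})
    return pd.DataFrame(rows)


def lr_type1_study(seed: int, n_replicates: int = 200, alpha: float = 0.05) -> dict:
    """Type-I error of the year x age LR test under a true null.

    Counts are drawn from a no-interaction Poisson model (the null the
    test assumes); the nominal 5% level should be attained to Monte-Carlo
    accuracy.
    """
    base = _null_interaction_cells()
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        cells = base.assign(count=rng.poisson(base["mu"].to_numpy()))
        null = fit_poisson(cells, ModelSpec())
        alt = fit_poisson(cells, ModelSpec(interaction=True))
        if lr_test(null, alt).p_value < alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_replicates, "n_replicates": n_replicates}


def lr_power_study(seed: int, n_replicates: int = 50, interaction_slope: float = 0.04) -> dict:
    """Power of the LR test against a planted year x age interaction."""
    base = _null_interaction_cells()
    order = {b: i for i, b in enumerate(["30-39", "40-49", "50-59", "60-69", "70-79", "80+"])}
    tilt = np.exp(
        interaction_slope
        * (base["year"] - 2008.5)
        * base["age_band"].map(order)
    )
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        cells = base.assign(count=rng.poisson(base["mu"].to_numpy() * tilt.to_numpy()))
        null = fit_poisson(cells, ModelSpec())
        alt = fit_poisson(cells, ModelSpec(interaction=True))
        if lr_test(null, alt).p_value < 0.05:
            rejections += 1
    return {"rejection_rate": rejections / n_replicates, "n_replicates": n_replicates}


def ci_coverage_study(
    seed: int,
    n_draws: int = 500,
    true_rate: float = 300.0,
    person_years: float = 300_000.0,
) -> dict:
    """Coverage of the Wald rate interval over Poisson draws (counts >= 100)."""
    rng = np.random.default_rng(seed)
    counts = rng.poisson(true_rate / 1e5 * person_years, size=n_draws)
    covered = 0
    for c in counts:
        est = incidence_rate(int(c), person_years)
        covered += est.ci_low <= true_rate <= est.ci_high
    return {"coverage": covered / n_draws, "n_draws": n_draws}


def washout_monotonicity_study(
    seed: int,
    n_registries: int = 100,
    n_persons: int = 150,
    washouts=(24, 36, 48, 60, 72),
    year: int = 2010,
) -> dict:
    """Counts never increase when the washout is extended, registry by registry."""
    monotone = 0
    for s in _child_seeds(seed, n_registries):
        cfg = SimulationConfig(seed=s, n_persons=n_persons, pre_coverage_years=6)
        rec, _ = simulate_dispensings(cfg)
        if rec.empty:
            monotone += 1
            continue
        cov = RegistryCoverage.from_years(cfg.start_year, cfg.end_year)
        sweep = sensitivity_sweep(rec, year, [WindowConfig(w, 12) for w in washouts], cov)
        ok = True
        for col in ("prevalent_insulin_only", "incident_any", "incident_oad", "incident_insulin_only"):
            vals = sweep[col].to_numpy(dtype=float)
            ok = ok and bool((np.diff(vals) <= 0).all())
        monotone += ok
    return {"monotone_fraction": monotone / n_registries, "n_registries": n_registries}


def gestational_recovery_study(
    seed: int,
    gestational_fraction: float = 0.6,
    n_persons: int = 20_000,
) -> dict:
    """Recover a planted transient-insulin share from the classifier output.

    Onsets are confined to women under 40 with an insulins-only modality;
    a *gestational_fraction* share stop within 4-9 months.  The
    discontinuation fraction (no insulin fill in the last 12 months of a
    24-month horizon) among young female incident insulins-only users
    should equal the planted share up to binomial error.
    """
    rates = _flat_rates(0.0)
    rates["20-29"]["female"] = 700.0
    rates["30-39"]["female"] = 700.0
    cfg = SimulationConfig(
        seed=seed,
        n_persons=n_persons,
        onset_rate=rates,
        modality_mix={"oad_only": 0.0, "oad_then_insulin": 0.0, "insulin_only": 1.0},
        gestational_fraction=gestational_fraction,
        pcos_rate=0.0,
        attrition_rate=0.0,
    )
    rec, _ = simulate_dispensings(cfg)
    cov = RegistryCoverage.from_years(cfg.start_year, cfg.end_year)
    st = classify_registry(rec, cov, years=range(2006, 2010))
    frac = discontinuation_fraction(
        st, rec, cov, horizon_months=24,
        years=range(2006, 2010), sex="female",
        age_range=cfg.gestational_age_range,
    )
    n_users = int(st["incident_insulin_only"].sum())
    return {
        "discontinuation_fraction": frac,
        "planted_fraction": gestational_fraction,
        "n_incident_users": n_users,
    }
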