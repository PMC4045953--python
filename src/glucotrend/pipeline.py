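"""Pipeline orchestration: configuration, staged artifacts, manifest.

Stages write intermediate artifacts to disk (simulate -> classify ->
rates/trend -> report) so every reported number is re-derivable from the
on-disk UserStatus table, and downstream stages can be re-run or audited
independently.  All outputs are deterministic given config and seed (no
timestamps), so a rerun is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    WindowConfig,
    classify_registry,
    observable_years,
    read_statuses,
    write_statuses,
)
from .io import RegistryCoverage, read_dispensings, read_population, write_dispensings, write_population
from .rates import make_table
from .simulate import SimulationConfig, simulate_dispensings, simulate_population, write_truth
from .trend import ModelSpec, fit_poisson, incident_cells, irr_per_year, lr_test

log = logging.getLogger("glucotrend")


class PipelineError(RuntimeError):
    """Invalid configuration or missing upstream artifact."""


@dataclass
class PipelineConfig:
    outdir: Path = Path("glucotrend-out")
    coverage: RegistryCoverage = field(default_factory=lambda: RegistryCoverage.from_years(2004, 2011))
    windows: WindowConfig = field(default_factory=WindowConfig)
    alpha: float = 0.05
    seed: int = 0
    by_age: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    dispensings: Path | None = None
    population: Path | None = None

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.dispensings is None:
            self.dispensings = self.outdir / "dispensings.csv"
        if self.population is None:
            self.population = self.outdir / "population.csv"
        self.simulation.seed = self.seed
        self.simulation.start_year = self.coverage.start.year
        self.simulation.end_year = self.coverage.end.year

    # -- construction -------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cov = d.pop("coverage", None)
        if cov is not None:
            d["coverage"] = RegistryCoverage(cov["start"], cov["end"])
        win = d.pop("windows", None)
        if win is not None:
            d["windows"] = WindowConfig(**win)
        sim = d.pop("simulation", None)
        if sim is not None:
            d["simulation"] = SimulationConfig.from_dict(sim)
        for key in ("outdir", "dispensings", "population"):
            if d.get(key) is not None:
                d[key] = Path(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "dispensings": str(self.dispensings),
            "population": str(self.population),
            "coverage": {"start": str(self.coverage.start.date()), "end": str(self.coverage.end.date())},
            "windows": {
                "washout_months": self.windows.washout_months,
                "lookforward_months": self.windows.lookforward_months,
            },
            "alpha": self.alpha,
            "seed": self.seed,
            "by_age": self.by_age,
            "simulation": self.simulation.to_dict(),
        }

    def config_hash(self) -> str:
        """Hash of the analysis configuration (output locations excluded)."""
        d = self.to_dict()
        for key in ("outdir", "dispensings", "population"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    # -- artifact paths -----------------------------------------------
    @property
    def truth_path(self) -> Path:
        return self.outdir / "truth.csv"

    @property
    def statuses_path(self) -> Path:
        return self.outdir / "statuses.csv"

    @property
    def incidence_table_path(self) -> Path:
        return self.outdir / "incidence_table.csv"

    @property
    def prevalence_table_path(self) -> Path:
        return self.outdir / "prevalence_table.csv"

    @property
    def trend_summary_path(self) -> Path:
        return self.outdir / "trend_summary.csv"

    @property
    def lr_tests_path(self) -> Path:
        return self.outdir / "lr_tests.csv"

    @property
    def manifest_path(self) -> Path:
        return self.outdir / "manifest.json"


def _require(path: Path, producer: str) -> None:
    if not Path(path).exists():
        raise PipelineError(f"missing artifact {path}; run the '{producer}' stage first")


def stage_simulate(cfg: PipelineConfig) -> None:
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    records, truth = simulate_dispensings(cfg.simulation)
    pop = simulate_population(cfg.simulation)
    write_dispensings(records, cfg.dispensings)
    write_population(pop, cfg.population)
    write_truth(truth, cfg.truth_path)
    log.info(
        "simulate: %d records, %d persons with onset, %d population strata",
        len(records), len(truth), len(pop),
    )


def stage_classify(cfg: PipelineConfig) -> None:
    _require(cfg.dispensings, "simulate")
    records = read_dispensings(cfg.dispensings, cfg.coverage)
    statuses = classify_registry(records, cfg.coverage, cfg.windows)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    write_statuses(statuses, cfg.statuses_path)
    log.info("classify: %d records -> %d person-year status rows", len(records), len(statuses))
    for year, grp in statuses.groupby("year"):
        log.info(
            "classify: year %d prevalent_any=%d incident_any=%d",
            year, int(grp["prevalent_any"].sum()), int(grp["incident_any"].sum()),
        )


def stage_rates(cfg: PipelineConfig) -> None:
    _require(cfg.statuses_path, "classify")
    _require(cfg.population, "simulate")
    statuses = read_statuses(cfg.statuses_path)
    pop = read_population(cfg.population)
    table = make_table(statuses, pop, cfg.coverage, cfg.windows, alpha=cfg.alpha, by_age=cfg.by_age)
    inc = table[table["measure"] == "incidence"].drop(columns="measure")
    prev = table[table["measure"] == "prevalence"].drop(columns=["measure", "ci_low", "ci_high"])
    inc.to_csv(cfg.incidence_table_path, index=False)
    prev.to_csv(cfg.prevalence_table_path, index=False)
    n_unobs = int((~table["observable"]).sum())
    if n_unobs:
        log.warning("rates: %d unobservable cells marked explicitly", n_unobs)
    log.info("rates: wrote %s and %s", cfg.incidence_table_path, cfg.prevalence_table_path)


def stage_trend(cfg: PipelineConfig) -> None:
    _require(cfg.statuses_path, "classify")
    _require(cfg.population, "simulate")
    statuses = read_statuses(cfg.statuses_path)
    pop = read_population(cfg.population)
    obs = observable_years(cfg.coverage, cfg.windows)
    rows, lr_rows = [], []
    for outcome, years in (("any", obs["incidence"]), ("oad", obs["incidence"]),
                           ("insulin_only", obs["insulin_only"])):
        if len(years) < 2:
            continue
        cells = incident_cells(statuses, pop, years, outcome=outcome)
        fit = fit_poisson(cells, ModelSpec())
        irr = irr_per_year(fit, alpha=cfg.alpha)
        se = fit.se
        for term in fit.params.index:
            rows.append(
                {
                    "outcome": outcome,
                    "term": term,
                    "estimate": fit.params[term],
                    "se": se[term],
                    "irr": np.nan if term == "intercept" else float(np.exp(fit.params[term])),
                }
            )
        rows.append(
            {
                "outcome": outcome,
                "term": "irr_per_year",
                "estimate": irr.irr,
                "se": se["year"],
                "irr": irr.irr,
                "ci_low": irr.ci_low,
                "ci_high": irr.ci_high,
            }
        )
        alt = fit_poisson(cells, ModelSpec(interaction=True))
        lr = lr_test(fit, alt)
        lr_rows.append(
            {
                "outcome": outcome,
                "test": "year_x_age_interaction",
                "statistic": lr.statistic,
                "df": lr.df,
                "p_value": lr.p_value,
                "dispersion_null": fit.pearson_dispersion,
            }
        )
        log.info("trend %s: IRR/year %.4f (%.4f, %.4f), LR p=%.4f",
                 outcome, irr.irr, irr.ci_low, irr.ci_high, lr.p_value)
    pd.DataFrame(rows).to_csv(cfg.trend_summary_path, index=False, float_format="%.10g")
    pd.DataFrame(lr_rows).to_csv(cfg.lr_tests_path, index=False, float_format="%.10g")


def stage_report(cfg: PipelineConfig) -> None:
    stage_rates(cfg)
    statuses = read_statuses(cfg.statuses_path)
    records = read_dispensings(cfg.dispensings, cfg.coverage)
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_sha256": cfg.config_hash(),
        "counts": {
            "dispensing_records": int(len(records)),
            "persons_with_a10": int(statuses["person_id"].nunique()),
            "status_rows": int(len(statuses)),
        },
        "observable_years": {k: list(v) for k, v in observable_years(cfg.coverage, cfg.windows).items()},
    }
    with open(cfg.manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("report: manifest written to %s", cfg.manifest_path)


STAGES = {
    "simulate": (stage_simulate,),
    "classify": (stage_classify,),
    "rates": (stage_rates,),
    "trend": (stage_trend,),
    "report": (stage_report,),
    "all": (stage_simulate, stage_classify, stage_rates, stage_trend, stage_report),
}


def run(command: str, cfg: PipelineConfig) -> None:
    """Run a pipeline stage (or 'all'); raises PipelineError on bad input."""
    if command not in STAGES:
        raise PipelineError(f"unknown command {command!r}; choose from {sorted(STAGES)}")
    for stage in STAGES[command]:
        stage(cfg)
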