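"""Poisson log-linear trend regression on stratum-year event counts.

The model is ``count_i ~ Poisson(mu_i)`` with
``log mu_i = log(person_years_i) + x_i' beta``: a linear calendar-year
term (centred at the midpoint of the fitted years for conditioning —
the IRR per year is invariant to centring), categorical 10-year age
band (reference: youngest band present), categorical sex (reference:
female), and optionally a year x age interaction.

Fitting is iteratively reweighted least squares (IRLS) on the canonical
log link, with step halving whenever a step would decrease the
log-likelihood, so the likelihood is non-decreasing across iterations.
The covariance is the inverse observed (= expected, canonical link)
information at the MLE.  Overdispersion is not modelled; a Pearson
dispersion statistic is reported as a diagnostic only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .rates import DEFAULT_AGE_BANDS, age_band, band_bounds, person_years


@dataclass(frozen=True)
class ModelSpec:
    """Terms of the log-linear rate model."""

    year_term: bool = True
    age_term: bool = True
    sex_term: bool = True
    interaction: bool = False  # year x age
    center_year: bool = True

    def __post_init__(self) -> None:
        if self.interaction and not (self.year_term and self.age_term):
            raise ValueError("year x age interaction requires both main terms")


@dataclass
class PoissonFit:
    params: pd.Series
    cov: pd.DataFrame
    log_likelihood: float
    converged: bool
    n_iterations: int
    pearson_dispersion: float
    year_center: float = 0.0
    n_obs: int = 0

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)


@dataclass(frozen=True)
class IrrEstimate:
    """Incidence rate ratio per calendar year with Wald CI."""

    irr: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class LrTestResult:
    statistic: float
    df: int
    p_value: float


def build_design(cells: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, float]:
    """Design matrix, response and log-PY offset for a cell table.

    *cells* has columns year, sex, age_band, count, person_years.
    Returns ``(X, y, offset, year_center)``.
    """
    n = len(cells)
    if n == 0:
        raise ValueError("empty cell table")
    if (cells["person_years"] <= 0).any():
        raise ValueError("person_years must be positive in every cell")
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    center = 0.0
    if spec.year_term:
        years = cells["year"].to_numpy(dtype=float)
        if spec.center_year:
            center = (years.min() + years.max()) / 2.0
        cols["year"] = years - center
    age_dummies: list[str] = []
    if spec.age_term:
        bands = sorted(cells["age_band"].unique(), key=band_bounds)
        for b in bands[1:]:
            name = f"age[{b}]"
            cols[name] = (cells["age_band"] == b).to_numpy(dtype=float)
            age_dummies.append(name)
    if spec.sex_term:
        cols["sex[male]"] = (cells["sex"] == "male").to_numpy(dtype=float)
    if spec.interaction:
        for name in age_dummies:
            cols[f"year:{name}"] = cols["year"] * cols[name]
    X = pd.DataFrame(cols, index=cells.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify candidate collinear columns from the QR diagonal
        _, r = np.linalg.qr(X.to_numpy())
        ndiag = min(r.shape)
        suspects = [X.columns[i] for i in range(X.shape[1])
                    if i >= ndiag or abs(r[i, i]) < 1e-8] or list(X.columns)
        raise ValueError(f"rank-deficient design (rank {rank} < {X.shape[1]}); collinear columns: {suspects}")
    y = cells["count"].to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    offset = np.log(cells["person_years"].to_numpy(dtype=float))
    return X, y, offset, center


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    mu = np.exp(eta)
    return float(np.sum(y * eta - mu - gammaln(y + 1)))


def fit_poisson(
    cells: pd.DataFrame,
    spec: ModelSpec | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> PoissonFit:
    """Maximise the Poisson log-likelihood by IRLS with step halving.

    Convergence when the relative log-likelihood change or the score
    norm falls below *tol*.  Non-convergence within *max_iter* returns
    the last iterate with ``converged=False``.
    """
    spec = spec or ModelSpec()
    X, y, offset, center = build_design(cells, spec)
    Xm = X.to_numpy()
    n, p = Xm.shape
    if n < p:
        raise ValueError(f"{n} cells cannot identify {p} parameters")

    beta = np.zeros(p)
    # start from the crude overall rate on the intercept
    beta[0] = np.log((y.sum() + 0.5) / np.exp(offset).sum())
    eta = offset + Xm @ beta
    ll = _loglik(y, eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = np.exp(eta)
        score = Xm.T @ (y - mu)
        if np.linalg.norm(score) < tol:
            converged = True
            break
        W = mu  # canonical link: working weights = mu
        z = (eta - offset) + (y - mu) / np.where(mu > 0, mu, 1.0)
        XtW = Xm.T * W
        try:
            step_beta = np.linalg.solve(XtW @ Xm, XtW @ z)
        except np.linalg.LinAlgError:
            step_beta, *_ = np.linalg.lstsq(XtW @ Xm, XtW @ z, rcond=None)
        # step halving keeps the likelihood non-decreasing
        direction = step_beta - beta
        frac = 1.0
        for _ in range(30):
            cand = beta + frac * direction
            eta_cand = offset + Xm @ cand
            ll_cand = _loglik(y, eta_cand)
            if ll_cand >= ll - 1e-12:
                break
            frac /= 2.0
        beta, eta, ll_new = cand, eta_cand, ll_cand
        if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    mu = np.exp(eta)
    info = (Xm.T * mu) @ Xm
    cov = np.linalg.inv(info)
    resid = (y - mu) / np.sqrt(np.where(mu > 0, mu, 1.0))
    dof = max(n - p, 1)
    return PoissonFit(
        params=pd.Series(beta, index=X.columns),
        cov=pd.DataFrame(cov, index=X.columns, columns=X.columns),
        log_likelihood=ll,
        converged=converged,
        n_iterations=it,
        pearson_dispersion=float(np.sum(resid**2) / dof),
        year_center=center,
        n_obs=n,
    )


def irr_per_year(fit: PoissonFit, alpha: float = 0.05) -> IrrEstimate:
    """exp(year coefficient) with a Wald confidence interval."""
    if "year" not in fit.params.index:
        raise ValueError("model has no calendar-year term")
    if not fit.converged:
        raise ValueError("fit did not converge; IRR not reported")
    b = float(fit.params["year"])
    se = float(np.sqrt(fit.cov.loc["year", "year"]))
    z = stats.norm.ppf(1 - alpha / 2)
    return IrrEstimate(np.exp(b), np.exp(b - z * se), np.exp(b + z * se))


def lr_test(null_fit: PoissonFit, alt_fit: PoissonFit) -> LrTestResult:
    """Likelihood-ratio test of nested Poisson models."""
    df = len(alt_fit.params) - len(null_fit.params)
    if df < 1:
        raise ValueError("alternative model must have more parameters than the null")
    stat = 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood)
    if stat < -1e-6 * (abs(null_fit.log_likelihood) + 1.0):
        raise ValueError(
            f"alternative log-likelihood {alt_fit.log_likelihood:.6f} below null "
            f"{null_fit.log_likelihood:.6f}: models not nested or fit not converged"
        )
    stat = max(stat, 0.0)
    return LrTestResult(stat, df, float(stats.chi2.sf(stat, df)))


def incident_cells(
    statuses: pd.DataFrame,
    pop: pd.DataFrame,
    years,
    outcome: str = "any",
    sex: str | None = None,
    bands: list[str] | None = None,
    drop_empty_bands: bool = True,
) -> pd.DataFrame:
    """Aggregate incident counts into model cells with person-year offsets.

    One row per (year, sex, age band) with the incident-user count for
    *outcome* and the mean-population person-years.  Cells whose
    person-years are zero (no population in the stratum) are dropped;
    age bands with zero events in every cell are dropped by default,
    since their dummy coefficients are not identified (the MLE diverges).
    """
    flag = {"any": "incident_any", "oad": "incident_oad", "insulin_only": "incident_insulin_only"}[outcome]
    bands = bands or DEFAULT_AGE_BANDS
    years = list(years)
    st = statuses[statuses["year"].isin(years)].copy()
    if sex is not None:
        st = st[st["sex"] == sex]
    st["age_band"] = (st["year"] - st["birth_year"]).map(age_band)
    counts = (
        st[st[flag].astype(bool)]
        .groupby(["year", "sex", "age_band"])
        .size()
        .to_dict()
    )
    rows = []
    for year in years:
        for s in ([sex] if sex is not None else ["female", "male"]):
            for b in bands:
                py = person_years(pop, year, sex=s, ages=band_bounds(b))
                if py <= 0:
                    continue
                rows.append(
                    {
                        "year": year,
                        "sex": s,
                        "age_band": b,
                        "count": int(counts.get((year, s, b), 0)),
                        "person_years": py,
                    }
                )
    out = pd.DataFrame(rows)
    if drop_empty_bands and len(out):
        totals = out.groupby("age_band")["count"].sum()
        keep = totals[totals > 0].index
        if len(keep):
            out = out[out["age_band"].isin(keep)].reset_index(drop=True)
    return out
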