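"""Conventional quasi-Poisson rate regressions, imputation and pooling.

Admission counts y over person-years t are modeled on the log scale,

    log mu = log t + b0 + b1 x1 + ... + bk xk,

so exp(b) is the factor by which the yearly admission rate changes per unit
of the regressor. Because real admission counts are heavily overdispersed
(variance >> mean), standard errors use the quasi-Poisson convention: the
Poisson point estimates are kept and SEs are inflated by sqrt(phi), with
phi the Pearson dispersion X^2 / (n - p).

The module also provides a simple multivariate-normal multiple-imputation
scheme for missing covariates and Rubin's rules for pooling estimates
across completed datasets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .simulate import stream_rng

__all__ = [
    "QuasiPoissonFit",
    "QuasiPoissonGLM",
    "PooledFit",
    "fit_quasipoisson",
    "impute_missing",
    "pool_rubin",
    "rate_per_sd",
]

_Z95 = 1.959963984540054


@dataclass
class QuasiPoissonFit:
    """Coefficients of a quasi-Poisson rate regression.

    Coefficients are on the log-rate scale, per unit of each regressor;
    ``dispersion`` is the Pearson phi. ``rate_table`` exponentiates them to
    rate ratios with Wald CIs (symmetric on the log scale).
    """

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    dispersion: float
    n: int
    offset: str = "log person_years"

    def coef_for(self, term: str) -> tuple[float, float]:
        i = self.terms.index(term)
        return float(self.coef[i]), float(self.se[i])

    def rate_table(self, scales: dict[str, float] | None = None) -> pd.DataFrame:
        """Rate ratios and 95% CIs per term; ``scales`` maps a term to a
        multiplier (e.g. an exposure SD) applied on the log scale."""
        rows = []
        for i, term in enumerate(self.terms):
            if term == "const":
                continue
            s = (scales or {}).get(term, 1.0)
            b, se = self.coef[i] * s, self.se[i] * abs(s)
            rows.append(
                {
                    "term": term,
                    "scale": s,
                    "rate_ratio": math.exp(b),
                    "ci_low": math.exp(b - _Z95 * se),
                    "ci_high": math.exp(b + _Z95 * se),
                }
            )
        return pd.DataFrame(rows)


class QuasiPoissonGLM(BaseEstimator):
    """Scikit-learn style quasi-Poisson rate regression with person-time offset.

    Fits a Poisson-family log-link GLM of counts on the columns of X with a
    log(person_years) offset; point estimates are the Poisson MLEs and SEs
    carry the Pearson dispersion. Fitted attributes: ``coef_``,
    ``intercept_``, ``se_``, ``dispersion_``, ``fit_`` (a
    :class:`QuasiPoissonFit`), ``result_`` (the statsmodels results).

    Parameters
    ----------
    validate_counts : bool
        Require nonnegative integer counts (disable for pre-aggregated or
        weighted inputs).
    """

    def __init__(self, validate_counts: bool = True):
        self.validate_counts = validate_counts

    def fit(self, X, y, person_years):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        t = np.asarray(person_years, dtype=float)
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("person_years (offset) must be positive and finite")
        if self.validate_counts:
            if np.any(y < 0) or np.any(np.asarray(y, dtype=float) != np.round(y)):
                raise ValueError("counts must be nonnegative integers")
        if np.all(y == 0):
            raise ValueError("degenerate outcome: all counts are zero")
        design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
        model = sm.GLM(y, design, family=sm.families.Poisson(), offset=np.log(t))
        res = model.fit(scale="X2")
        self.result_ = res
        self.terms_ = ["const"] + [str(c) for c in X.columns]
        self.coef_ = np.asarray(res.params[1:])
        self.intercept_ = float(res.params[0])
        self.se_ = np.asarray(res.bse[1:])
        self.dispersion_ = float(res.scale)
        self.n_ = int(res.nobs)
        self.fit_ = QuasiPoissonFit(
            terms=self.terms_,
            coef=np.asarray(res.params),
            se=np.asarray(res.bse),
            dispersion=self.dispersion_,
            n=self.n_,
        )
        return self

    def predict(self, X, person_years):
        """Expected counts for new rows."""
        design = sm.add_constant(pd.DataFrame(X).to_numpy(dtype=float), has_constant="add")
        t = np.asarray(person_years, dtype=float)
        return self.result_.predict(design, offset=np.log(t))


def fit_quasipoisson(
    counts,
    regressors: pd.DataFrame,
    person_years,
    covariates: pd.DataFrame | None = None,
) -> QuasiPoissonFit:
    """Quasi-Poisson rate regression of counts on regressors (+ covariates)
    with a log person-years offset."""
    X = pd.DataFrame(regressors).copy()
    if covariates is not None:
        for c in covariates.columns:
            X[c] = covariates[c].to_numpy()
    est = QuasiPoissonGLM().fit(X, counts, person_years)
    return est.fit_


def _nearest_level(values: np.ndarray, levels: np.ndarray) -> np.ndarray:
    idx = np.abs(values[:, None] - levels[None, :]).argmin(axis=1)
    return levels[idx]


def impute_missing(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    m: int = 10,
    seed: int = 0,
    categorical: list[str] | None = None,
) -> list[pd.DataFrame]:
    """m stochastic completions of missing covariate cells.

    Working model: multivariate normal with complete-case mean/covariance
    over the numeric columns; each incomplete row's missing cells are drawn
    from the conditional normal given its observed cells (missing at
    random, given the included columns). Categorical columns are imputed on
    the underlying numeric code scale and mapped back to the nearest
    observed level. Observed cells are never altered.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    cols = columns or [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    sub = table[cols].astype(float)
    frac = sub.isna().mean()
    if (frac == 1.0).any():
        raise ValueError(f"all-missing column(s): {list(frac.index[frac == 1.0])}")
    high = list(frac.index[frac > 0.5])
    if high:
        warnings.warn(f"columns more than 50% missing: {high}", UserWarning)
    if not sub.isna().to_numpy().any():
        return [table.copy() for _ in range(m)]
    complete = sub.dropna()
    if len(complete) < len(cols) + 2:
        raise ValueError("too few complete cases to estimate the working model")
    mu = complete.mean().to_numpy()
    # small ridge keeps the conditional solve stable under near-collinearity
    cov = np.cov(complete.to_numpy(), rowvar=False)
    cov = cov + 1e-10 * np.eye(len(cols)) * max(np.trace(cov), 1.0)
    rng = stream_rng(seed, "imputation")
    levels = {
        c: np.unique(sub[c].dropna().to_numpy()) for c in (categorical or []) if c in cols
    }
    X = sub.to_numpy()
    out = []
    for _ in range(m):
        filled = X.copy()
        for i in np.flatnonzero(np.isnan(X).any(axis=1)):
            miss = np.isnan(X[i])
            obs = ~miss
            if obs.any():
                S_oo = cov[np.ix_(obs, obs)]
                S_mo = cov[np.ix_(miss, obs)]
                solve = np.linalg.solve(S_oo, X[i, obs] - mu[obs])
                cmean = mu[miss] + S_mo @ solve
                ccov = cov[np.ix_(miss, miss)] - S_mo @ np.linalg.solve(S_oo, S_mo.T)
                ccov = (ccov + ccov.T) / 2.0
            else:
                cmean = mu[miss]
                ccov = cov[np.ix_(miss, miss)]
            filled[i, miss] = rng.multivariate_normal(cmean, ccov, method="svd")
        comp = table.copy()
        for k, c in enumerate(cols):
            vals = filled[:, k]
            if c in levels:
                was_na = sub[c].isna().to_numpy()
                vals = vals.copy()
                vals[was_na] = _nearest_level(vals[was_na], levels[c])
            comp[c] = vals
        out.append(comp)
    return out


@dataclass
class PooledFit:
    """Rubin's-rules pooling of one coefficient across m imputations:
    T = W + (1 + 1/m) B with W the mean squared SE and B the
    between-imputation variance of the estimates."""

    estimate: float
    within: float
    between: float
    total: float
    m: int

    @property
    def se(self) -> float:
        return math.sqrt(self.total)


def pool_rubin(estimates, ses) -> PooledFit:
    """Pool per-imputation estimates and standard errors by Rubin's rules."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.shape != se.shape:
        raise ValueError("mismatched layouts: estimates and SEs differ in shape")
    m = est.shape[0]
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 imputations")
    W = float(np.mean(se**2))
    B = float(np.var(est, ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    return PooledFit(estimate=float(est.mean()), within=W, between=B, total=T, m=m)


def pool_rubin_fits(fits: list[QuasiPoissonFit]) -> dict[str, PooledFit]:
    """Pool every coefficient of m quasi-Poisson fits with identical layout."""
    terms = fits[0].terms
    for f in fits[1:]:
        if f.terms != terms:
            raise ValueError("mismatched layouts across imputation fits")
    out = {}
    for i, t in enumerate(terms):
        out[t] = pool_rubin([f.coef[i] for f in fits], [f.se[i] for f in fits])
    return out


def rate_per_sd(log_coef: float, se: float, sd: float):
    """Rescale a per-unit log-rate coefficient to a per-SD (or per-0.1-unit)
    rate ratio with its 95% CI. Returns (rate_ratio, ci_low, ci_high)."""
    if sd <= 0:
        raise ValueError("scaling SD must be positive")
    b, s = log_coef * sd, se * sd
    return math.exp(b), math.exp(b - _Z95 * s), math.exp(b + _Z95 * s)
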