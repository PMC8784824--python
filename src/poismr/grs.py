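"""Weighted genetic risk scores and instrument-strength diagnostics.

A genetic risk score (GRS) collapses many small per-allele effects into one
instrument: weighted dosages are summed and divided by the sum of the
weights, giving each participant an estimate of their average number of
exposure-increasing alleles (a score in [0, 2]). Weights are first oriented
so every effect allele is the exposure-increasing one.

Instrument strength is reported as the first-stage F statistic and partial
R^2; for multivariable MR the conditional Sanderson-Windmeijer F measures
the strength of the instruments for one exposure given the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "FirstStageFit",
    "orient_weights",
    "compute_grs",
    "fit_first_stage",
    "f_from_r2",
    "conditional_sw_f",
    "read_weight_table",
]


@dataclass
class FirstStageFit:
    """OLS fit of an exposure on a GRS (plus optional covariates).

    beta_exp is in exposure units per GRS unit; r_squared and f_statistic
    are partial to the GRS term when covariates are present. For a single
    unadjusted regressor, f_statistic = (n-2) r^2 / (1 - r^2) exactly.
    """

    beta_exp: float
    se_exp: float
    r_squared: float
    f_statistic: float
    n: int
    covariates: list[str]
    pvalue: float = float("nan")


def orient_weights(weights: pd.DataFrame) -> pd.DataFrame:
    """Orient a variant weight table so all weights are positive.

    Rows with negative weight have effect/other alleles swapped, the weight
    negated and (when present) eaf replaced by 1 - eaf, so the effect
    allele is always the exposure-increasing one. Idempotent. A zero weight
    is an error: it defines no exposure-increasing allele.
    """
    required = {"variant_id", "effect_allele", "other_allele", "weight"}
    missing = required - set(weights.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    if weights["variant_id"].duplicated().any():
        raise ValueError("variant ids must be unique")
    if (weights["weight"] == 0).any():
        bad = weights.loc[weights["weight"] == 0, "variant_id"].tolist()
        raise ValueError(f"zero weight defines no exposure-increasing allele: {bad}")
    out = weights.copy()
    neg = out["weight"] < 0
    ea = out.loc[neg, "effect_allele"].copy()
    out.loc[neg, "effect_allele"] = out.loc[neg, "other_allele"].to_numpy()
    out.loc[neg, "other_allele"] = ea.to_numpy()
    out.loc[neg, "weight"] = -out.loc[neg, "weight"]
    if "eaf" in out.columns:
        out.loc[neg, "eaf"] = 1.0 - out.loc[neg, "eaf"]
    return out


def compute_grs(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    dosage_alleles: pd.Series | dict | None = None,
) -> pd.Series:
    """Weighted GRS: G_i = sum_j w_j d_ij / sum_j w_j.

    ``dosages`` columns are per-variant allele counts in [0, 2].
    ``dosage_alleles`` optionally maps variant id to the allele the dosage
    column counts; where it differs from the weight table's effect allele
    the dosage is reflected (2 - d) so the score counts exposure-increasing
    alleles. Missing variants or missing dosage values are errors — no
    silent imputation.
    """
    w = weights.set_index("variant_id")["weight"]
    missing = [v for v in w.index if v not in dosages.columns]
    if missing:
        raise ValueError(f"dosage matrix missing variants: {missing}")
    d = dosages[list(w.index)].to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("missing dosage values; exclude participants instead of imputing")
    if dosage_alleles is not None:
        coded = pd.Series(dosage_alleles)
        ea = weights.set_index("variant_id")["effect_allele"]
        flip = np.array([coded[v] != ea[v] for v in w.index])
        d[:, flip] = 2.0 - d[:, flip]
    wv = w.to_numpy(dtype=float)
    return pd.Series(d @ wv / wv.sum(), index=dosages.index, name="grs")


def fit_first_stage(
    exposure,
    grs,
    covariates: pd.DataFrame | None = None,
) -> FirstStageFit:
    """OLS of the exposure on the GRS (plus covariates).

    Reports the GRS coefficient with its SE, the instrument partial R^2 and
    the instrument F (the squared t of the GRS term when adjusted; the
    classical regression F when unadjusted, where the two coincide).
    """
    y = np.asarray(exposure, dtype=float)
    g = np.asarray(grs, dtype=float)
    cols = [g]
    names = ["grs"]
    if covariates is not None and covariates.shape[1] > 0:
        c = covariates.to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), c]))
        if rank < c.shape[1] + 1:
            raise ValueError(
                f"collinear covariates: {list(covariates.columns)} "
                "(design matrix is rank deficient)"
            )
        cols.append(c)
        names += list(covariates.columns)
    x = sm.add_constant(np.column_stack(cols))
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need n > number of regressors + 1")
    res = sm.OLS(y, x).fit()
    tsq = float((res.params[1] / res.bse[1]) ** 2)
    if covariates is None or covariates.shape[1] == 0:
        r2 = float(res.rsquared)
        f = float(tsq)  # equals (n-2) r2 / (1-r2) for the single regressor
    else:
        r2 = float(tsq / (tsq + res.df_resid))  # partial R^2 of the GRS term
        f = float(tsq)
    return FirstStageFit(
        beta_exp=float(res.params[1]),
        se_exp=float(res.bse[1]),
        r_squared=r2,
        f_statistic=f,
        n=int(res.nobs),
        covariates=names[1:],
        pvalue=float(res.pvalues[1]),
    )


def f_from_r2(n: int, r_squared: float) -> float:
    """Single-instrument first-stage F from its R^2: F = (n-2) R^2/(1-R^2)."""
    if not (0.0 <= r_squared < 1.0):
        raise ValueError("r_squared must be in [0, 1)")
    return (n - 2) * r_squared / (1.0 - r_squared)


def _project_out(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residual of y after OLS on x (x includes any constant)."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def conditional_sw_f(exposures: pd.DataFrame, instruments: pd.DataFrame) -> pd.Series:
    """Conditional Sanderson-Windmeijer F statistics for multivariable MR.

    For each exposure k (of K >= 2), the other exposures are partialled out
    by 2SLS using the J instruments, and the F statistic tests the joint
    explanatory power of the instruments for the resulting residual, with
    numerator df J - (K - 1) and denominator df n - J - (K - 1) - 1. Values
    well below the unconditional F indicate that the instruments do not
    separate that exposure from the others.
    """
    X = exposures.to_numpy(dtype=float)
    Z = instruments.to_numpy(dtype=float)
    n, K = X.shape
    J = Z.shape[1]
    if K < 2:
        raise ValueError("conditional F needs at least two exposures")
    if J < K:
        raise ValueError("not identified: fewer instruments than exposures")
    ones = np.ones((n, 1))
    Z1 = np.column_stack([ones, Z])
    # first-stage fitted values for every exposure
    coef, *_ = np.linalg.lstsq(Z1, X, rcond=None)
    Xhat = Z1 @ coef
    out = {}
    df_num = J - (K - 1)
    df_den = n - J - (K - 1) - 1
    for k, name in enumerate(exposures.columns):
        xk = X[:, k]
        others = np.delete(X, k, axis=1)
        others_hat = np.delete(Xhat, k, axis=1)
        # 2SLS of exposure k on the other exposures (instrumented)
        W = np.column_stack([ones, others_hat])
        delta, *_ = np.linalg.lstsq(W, xk, rcond=None)
        resid = xk - np.column_stack([ones, others]) @ delta
        if resid.var() < 1e-12 * max(xk.var(), 1e-300):
            out[name] = 0.0  # exposure has no variation independent of the others
            continue
        e0 = resid - resid.mean()
        e1 = _project_out(resid, Z1)
        rss0 = float(e0 @ e0)
        rss1 = float(e1 @ e1)
        out[name] = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    return pd.Series(out, name="conditional_f")


def read_weight_table(path) -> pd.DataFrame:
    """Read a variant weight table from a GWAS-summary-style delimited file
    (columns variant_id, effect_allele, other_allele, beta or weight, ...)."""
    df = pd.read_csv(path, sep="\t")
    if "weight" not in df.columns and "beta" in df.columns:
        df = df.rename(columns={"beta": "weight"})
    return df


def sw_f_pvalue(f: float, j: int, k: int, n: int) -> float:
    """P-value companion for :func:`conditional_sw_f`."""
    return float(stats.f.sf(f, j - (k - 1), n - j - (k - 1) - 1))
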