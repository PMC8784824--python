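"""One-sample Mendelian randomization with a quasi-Poisson second stage.

The just-identified estimator uses a single genetic risk score G as the
instrument. The first stage is a linear regression of the exposure on G
(beta_exp); the second stage is a quasi-Poisson regression of admission
counts on G with a log person-years offset (beta_out, on the log-rate
scale). The causal rate ratio per exposure unit is

    exp(beta_out / beta_exp),

the Wald ratio exponentiated. Because the Poisson log link is collapsible,
this equals the two-stage predictor substitution (2SPS) coefficient from
regressing counts on the first-stage fitted exposure — an exact affine
reparameterization, which the tests verify to floating tolerance.

Standard errors use a first-order Taylor (delta-method) expansion of the
ratio, omitting the cross-stage covariance term; the omission is
conservative when direct instrument-outcome effects are weak, and the test
suite bounds the discrepancy against a simulation-based SE.

Multivariable one-sample MR regresses each exposure on the full SNP set,
then regresses counts on all fitted-value columns jointly; inference is by
full-sample nonparametric bootstrap of both stages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .grs import FirstStageFit, fit_first_stage
from .observational import QuasiPoissonGLM, _Z95
from .simulate import stream_rng

__all__ = [
    "SecondStageFit",
    "MREstimate",
    "fit_second_stage",
    "wald_iv",
    "residual_exposure",
    "OneSampleMR",
    "mvmr_onesample",
    "MultivariableOneSampleMR",
]


@dataclass
class SecondStageFit:
    """Quasi-Poisson fit of counts on the instrument (log-rate units per
    GRS unit), with Pearson dispersion."""

    beta_out: float
    se_out: float
    dispersion: float
    n: int
    covariates: list[str] = field(default_factory=list)


@dataclass
class MREstimate:
    """A causal MR estimate on the log-rate scale.

    ``log_rate_coef`` is per exposure unit; ``rate_ratio`` its exponent;
    the CI is on the rate scale. ``per_scale`` rescales (e.g. per SD).
    """

    log_rate_coef: float
    se: float
    rate_ratio: float
    ci_low: float
    ci_high: float
    method: str
    n: int
    exposure: str = ""
    ci_method: str = "wald"

    @classmethod
    def from_log(cls, b: float, se: float, method: str, n: int, exposure: str = "") -> "MREstimate":
        return cls(
            log_rate_coef=b,
            se=se,
            rate_ratio=math.exp(b),
            ci_low=math.exp(b - _Z95 * se),
            ci_high=math.exp(b + _Z95 * se),
            method=method,
            n=n,
            exposure=exposure,
        )

    def per_scale(self, scale: float) -> "MREstimate":
        """Rescaled estimate (e.g. per exposure SD or per 0.1 unit):
        multiply the log-rate coefficient by ``scale``."""
        out = MREstimate.from_log(
            self.log_rate_coef * scale, self.se * abs(scale), self.method, self.n, self.exposure
        )
        if self.ci_method == "percentile":
            out.ci_low = self.ci_low**scale if scale >= 0 else self.ci_high**scale
            out.ci_high = self.ci_high**scale if scale >= 0 else self.ci_low**scale
            out.ci_method = "percentile"
        return out


def fit_second_stage(
    counts,
    grs,
    person_years,
    covariates: pd.DataFrame | None = None,
) -> SecondStageFit:
    """Quasi-Poisson regression of counts on the GRS with log-t offset."""
    X = pd.DataFrame({"grs": np.asarray(grs, dtype=float)})
    names = []
    if covariates is not None:
        for c in covariates.columns:
            X[c] = covariates[c].to_numpy()
            names.append(str(c))
    est = QuasiPoissonGLM().fit(X, counts, person_years)
    b, se = est.fit_.coef_for("grs")
    return SecondStageFit(
        beta_out=b, se_out=se, dispersion=est.dispersion_, n=est.n_, covariates=names
    )


def wald_iv(
    first: FirstStageFit,
    second: SecondStageFit,
    weak_f_threshold: float = 10.0,
    exposure: str = "",
) -> MREstimate:
    """Wald-ratio IV estimate: log rate ratio per exposure unit is
    beta_out / beta_exp, with a first-order delta-method SE

        se^2 = se_out^2 / beta_exp^2 + beta_out^2 se_exp^2 / beta_exp^4

    (the two stages treated as uncorrelated)."""
    if first.beta_exp == 0:
        raise ValueError("irrelevant instrument: first-stage coefficient is zero")
    if first.f_statistic < weak_f_threshold:
        warnings.warn(
            f"weak instrument: first-stage F = {first.f_statistic:.2f} < {weak_f_threshold}",
            UserWarning,
        )
    b = second.beta_out / first.beta_exp
    var = (
        second.se_out**2 / first.beta_exp**2
        + second.beta_out**2 * first.se_exp**2 / first.beta_exp**4
    )
    return MREstimate.from_log(b, math.sqrt(var), "wald_iv", second.n, exposure)


def residual_exposure(secondary, primary) -> pd.Series:
    """Residuals of an OLS regression of one exposure on another (with
    intercept); e.g. WHR adjusted for BMI. Orthogonal to the primary."""
    y = np.asarray(secondary, dtype=float)
    x = np.asarray(primary, dtype=float)
    if x.var() == 0:
        raise ValueError("primary exposure is constant")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return pd.Series(res.resid, name="residual_exposure")


class OneSampleMR(BaseEstimator):
    """One-sample GRS Mendelian randomization for a count outcome.

    Runs the linear first stage and quasi-Poisson second stage and forms
    the Wald-ratio estimate. Fitted attributes: ``first_stage_``,
    ``second_stage_``, ``estimate_`` (an :class:`MREstimate`).

    Parameters
    ----------
    weak_f_threshold : float
        First-stage F below which a weak-instrument warning is raised.
    external_beta_exp, external_se_exp : float, optional
        Use an externally estimated gene-exposure coefficient in place of
        the in-sample first-stage slope (two-sample-style denominator).
    """

    def __init__(
        self,
        weak_f_threshold: float = 10.0,
        external_beta_exp: float | None = None,
        external_se_exp: float = 0.0,
    ):
        self.weak_f_threshold = weak_f_threshold
        self.external_beta_exp = external_beta_exp
        self.external_se_exp = external_se_exp

    def fit(self, exposure, counts, grs, person_years, covariates=None, exposure_name=""):
        self.first_stage_ = fit_first_stage(exposure, grs, covariates)
        self.second_stage_ = fit_second_stage(counts, grs, person_years, covariates)
        first = self.first_stage_
        if self.external_beta_exp is not None:
            first = FirstStageFit(
                beta_exp=self.external_beta_exp,
                se_exp=self.external_se_exp,
                r_squared=float("nan"),
                f_statistic=float("inf"),
                n=self.second_stage_.n,
                covariates=[],
            )
        self.estimate_ = wald_iv(
            first, self.second_stage_, self.weak_f_threshold, exposure=exposure_name
        )
        return self


def _two_stage_point(counts, t, X_expo, Z, cov, validate=True):
    """Stage 1: OLS of each exposure on all instruments (+covariates);
    stage 2: quasi-Poisson of counts on the fitted-value columns."""
    Z1 = np.column_stack([np.ones(Z.shape[0]), Z])
    design1 = Z1 if cov is None else np.column_stack([Z1, cov])
    coefs, *_ = np.linalg.lstsq(design1, X_expo, rcond=None)
    fitted = design1 @ coefs
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(fitted)), fitted]))
    if rank < fitted.shape[1] + 1:
        raise ValueError("exposures not separately identified: fitted values collinear")
    X2 = pd.DataFrame(fitted, columns=[f"x{k}" for k in range(fitted.shape[1])])
    if cov is not None:
        for i in range(cov.shape[1]):
            X2[f"c{i}"] = cov[:, i]
    est = QuasiPoissonGLM(validate_counts=validate).fit(X2, counts, t)
    return est.coef_[: fitted.shape[1]], est.se_[: fitted.shape[1]]


def mvmr_onesample(
    counts,
    person_years,
    exposures: pd.DataFrame,
    dosages: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict[str, MREstimate]:
    """One-sample multivariable MR with full-sample bootstrap inference.

    Each exposure is regressed on the combined SNP set; admission counts
    are then regressed on all K fitted-value columns jointly in a
    quasi-Poisson model with log person-years offset, giving direct
    (mutually adjusted) per-unit effects. SEs and percentile CIs come from
    ``n_boot`` nonparametric bootstrap replicates of both stages.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for percentile intervals")
    y = np.asarray(counts)
    t = np.asarray(person_years, dtype=float)
    X = exposures.to_numpy(dtype=float)
    Z1 = np.asarray(dosages, dtype=float)
    cov = covariates.to_numpy(dtype=float) if covariates is not None else None
    point, _ = _two_stage_point(y, t, X, Z1, cov)
    n = len(y)
    rng = stream_rng(seed, "mvmr-bootstrap")
    boots = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        cb = cov[idx] if cov is not None else None
        boots[b], _ = _two_stage_point(y[idx], t[idx], X[idx], Z1[idx], cb, validate=False)
    se = boots.std(axis=0, ddof=1)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    out = {}
    for k, name in enumerate(exposures.columns):
        est = MREstimate(
            log_rate_coef=float(point[k]),
            se=float(se[k]),
            rate_ratio=math.exp(point[k]),
            ci_low=math.exp(lo[k]),
            ci_high=math.exp(hi[k]),
            method="mvmr_onesample",
            n=n,
            exposure=str(name),
            ci_method="percentile",
        )
        out[str(name)] = est
    return out


class MultivariableOneSampleMR(BaseEstimator):
    """Estimator wrapper around :func:`mvmr_onesample`.

    Fitted attributes: ``estimates_`` (exposure name -> MREstimate),
    ``conditional_f_`` (Sanderson-Windmeijer conditional F per exposure).
    """

    def __init__(self, n_boot: int = 10_000, seed: int = 0):
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, counts, person_years, exposures, dosages, covariates=None):
        from .grs import conditional_sw_f

        self.conditional_f_ = conditional_sw_f(exposures, pd.DataFrame(dosages))
        self.estimates_ = mvmr_onesample(
            counts, person_years, exposures, dosages, covariates, self.n_boot, self.seed
        )
        return self
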