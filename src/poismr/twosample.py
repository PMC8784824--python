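"""Two-sample summary-statistics Mendelian randomization.

Inputs are harmonized per-SNP association tables: gene-exposure betas
(exposure units per effect allele, with SEs) and gene-outcome betas on the
log admission-rate scale. Each SNP j yields a Wald ratio
beta_Yj / beta_Xj; the module implements four pleiotropy-robust ways of
combining them:

* exact-weights IVW — minimizes Q(b) = sum_j (beta_Yj - b beta_Xj)^2 /
  (sigma_Yj^2 + b^2 sigma_Xj^2), where the weights depend on the causal
  parameter itself (LIML-like, robust to regression dilution); reduces to
  the classical inverse-variance weighted mean when sigma_X = 0;
* MR-Egger — weighted regression of outcome on exposure betas with a free
  intercept (the average directional pleiotropic effect), all exposure
  associations oriented positive;
* penalized weighted median — inverse-variance weighted median of the
  ratios, with heterogeneity-penalized weights; consistent when at least
  half the weight comes from valid instruments;
* weighted mode — the peak of a kernel-smoothed weighted density of the
  ratios; consistent when the largest homogeneous cluster is valid.

Heterogeneity is quantified by Cochran's Q (about the IVW slope, df J-1)
and Rucker's Q' (about the Egger fit, df J-2), with per-SNP contributions
and leave-one-out trajectories for outlier screening. Multivariable IVW
regresses outcome betas on several exposure-beta columns through the
origin. Harmonization and greedy LD pruning prepare the inputs.

Random-effects inference is multiplicative: SEs are scaled by
sqrt(max(1, Q/df)), the common convention for these estimators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .observational import _Z95
from .simulate import stream_rng

__all__ = [
    "TwoSampleResult",
    "HeterogeneityReport",
    "harmonize",
    "ld_prune",
    "wald_ratios",
    "ivw_closed_form",
    "ivw_exact",
    "mr_egger",
    "penalized_weighted_median",
    "weighted_mode",
    "cochran_q",
    "rucker_q",
    "heterogeneity_report",
    "leave_one_out",
    "mvmr_ivw_twosample",
    "IVWEstimator",
    "EggerEstimator",
    "WeightedMedianEstimator",
    "WeightedModeEstimator",
    "MultivariableIVWEstimator",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class TwoSampleResult:
    """A two-sample MR estimate: slope on the log-rate scale per exposure
    unit, with SE and Wald CI; Egger additionally reports the intercept."""

    method: str
    slope: float
    se: float
    ci_low: float
    ci_high: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None
    q_statistic: float | None = None

    def rate_view(self, scale: float = 1.0) -> dict:
        """Rate-ratio view at a given scale (1 = per unit; an SD; 0.1)."""
        b, s = self.slope * scale, self.se * abs(scale)
        return {
            "rate_ratio": math.exp(b),
            "ci_low": math.exp(b - _Z95 * s),
            "ci_high": math.exp(b + _Z95 * s),
            "scale": scale,
        }


@dataclass
class HeterogeneityReport:
    """Cochran's Q (IVW model, df J-1) and Rucker's Q' (Egger model,
    df J-2), their p-values, and per-SNP contributions (which sum to Q)."""

    q_cochran: float
    df_cochran: int
    p_cochran: float
    q_rucker: float
    df_rucker: int
    p_rucker: float
    contributions: pd.DataFrame = field(repr=False)


def _check_stats(stats_df: pd.DataFrame, min_snps: int = 2, caller: str = "") -> pd.DataFrame:
    need = {"beta_exposure", "se_exposure", "beta_outcome", "se_outcome"}
    missing = need - set(stats_df.columns)
    if missing:
        raise ValueError(f"summary table missing columns: {sorted(missing)}")
    if (stats_df["se_outcome"] <= 0).any() or (stats_df["se_exposure"] < 0).any():
        raise ValueError("standard errors must be positive")
    if len(stats_df) < min_snps:
        raise ValueError(f"{caller or 'estimator'} needs at least {min_snps} SNPs")
    return stats_df


def harmonize(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58),
):
    """Align exposure and outcome summary statistics to one effect-allele
    convention.

    Inner-joins on variant id. Outcome rows coded on the exposure's other
    allele have their beta sign and eaf flipped; rows that only match after
    strand complementing are complemented first. Strand-ambiguous (A/T,
    C/G) variants are dropped when their eaf lies within the ambiguity
    window, and aligned by allele frequency otherwise. Returns
    (harmonized stats, audit table of flipped/dropped variants).
    """
    lo, hi = palindromic_eaf_window
    exp = exposure_stats.set_index("variant_id")
    out = outcome_stats.set_index("variant_id")
    shared = exp.index.intersection(out.index)
    rows, audit = [], []
    for vid in shared:
        e, o = exp.loc[vid], out.loc[vid]
        ea, oa = str(e["effect_allele"]), str(e["other_allele"])
        b_y, se_y = float(o["beta"]), float(o["se"])
        eaf_o = float(o.get("eaf", np.nan))
        o_ea, o_oa = str(o["effect_allele"]), str(o["other_allele"])
        palindromic = oa == _COMPLEMENT.get(ea)
        action = "ok"
        if palindromic:
            eaf_e = float(e.get("eaf", np.nan))
            if np.isnan(eaf_e) or lo <= eaf_e <= hi:
                audit.append({"variant_id": vid, "action": "dropped", "reason": "palindromic"})
                continue
            # align by frequency: a mismatch in which allele is minor means flipped coding
            same_coding = (o_ea == ea) == ((eaf_e < 0.5) == (eaf_o < 0.5)) if not np.isnan(
                eaf_o
            ) else (o_ea == ea)
            if not same_coding:
                b_y, eaf_o, action = -b_y, 1.0 - eaf_o, "flipped"
        else:
            if (o_ea, o_oa) == (ea, oa):
                pass
            elif (o_ea, o_oa) == (oa, ea):
                b_y, eaf_o, action = -b_y, 1.0 - eaf_o, "flipped"
            else:
                c_ea = _COMPLEMENT.get(o_ea, "?")
                c_oa = _COMPLEMENT.get(o_oa, "?")
                if (c_ea, c_oa) == (ea, oa):
                    action = "strand_flipped"
                elif (c_ea, c_oa) == (oa, ea):
                    b_y, eaf_o, action = -b_y, 1.0 - eaf_o, "strand_and_allele_flipped"
                else:
                    audit.append(
                        {"variant_id": vid, "action": "dropped", "reason": "incompatible alleles"}
                    )
                    continue
        if action != "ok":
            audit.append({"variant_id": vid, "action": action, "reason": ""})
        rows.append(
            {
                "variant_id": vid,
                "effect_allele": ea,
                "other_allele": oa,
                "beta_exposure": float(e["beta"]),
                "se_exposure": float(e["se"]),
                "pval_exposure": float(e.get("pval", np.nan)),
                "eaf": float(e.get("eaf", np.nan)),
                "beta_outcome": b_y,
                "se_outcome": se_y,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(audit, columns=["variant_id", "action", "reason"])


def ld_prune(
    snps: pd.DataFrame,
    r2: pd.DataFrame | np.ndarray,
    r2_threshold: float = 0.001,
    pval_column: str = "pval_exposure",
) -> list[str]:
    """Greedy LD pruning: visit SNPs by ascending exposure p-value and keep
    each one iff its r^2 with every already-kept SNP is below the
    threshold. Returns the retained variant ids."""
    ids = list(snps["variant_id"])
    r2 = pd.DataFrame(np.asarray(r2), index=ids, columns=ids) if not isinstance(
        r2, pd.DataFrame
    ) else r2
    missing = [v for v in ids if v not in r2.index or v not in r2.columns]
    if missing:
        raise ValueError(f"missing r^2 entries for: {missing}")
    if r2[ids].loc[ids].isna().to_numpy().any():
        raise ValueError("missing r^2 entries in the matrix")
    order = snps.sort_values(pval_column, kind="mergesort")["variant_id"]
    kept: list[str] = []
    for vid in order:
        if all(float(r2.loc[vid, k]) < r2_threshold for k in kept):
            kept.append(vid)
    return kept


def dosage_r2(dosages: pd.DataFrame) -> pd.DataFrame:
    """Pairwise squared Pearson correlation of dosage columns."""
    c = np.corrcoef(dosages.to_numpy(dtype=float), rowvar=False)
    return pd.DataFrame(c**2, index=dosages.columns, columns=dosages.columns)


def wald_ratios(stats_df: pd.DataFrame, second_order: bool = False) -> pd.DataFrame:
    """Per-SNP Wald ratios beta_Yj / beta_Xj with first-order SEs
    sigma_Yj / |beta_Xj| (optionally adding the second-order term
    beta_Yj^2 sigma_Xj^2 / beta_Xj^4). SNPs with beta_Xj = 0 are excluded
    with a warning."""
    s = _check_stats(stats_df, 1, "wald_ratios").copy()
    zero = s["beta_exposure"] == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} SNP(s) with zero exposure beta", UserWarning
        )
        s = s.loc[~zero]
    bx = s["beta_exposure"].to_numpy(dtype=float)
    by = s["beta_outcome"].to_numpy(dtype=float)
    sy = s["se_outcome"].to_numpy(dtype=float)
    ratio = by / bx
    var = sy**2 / bx**2
    if second_order:
        sx = s["se_exposure"].to_numpy(dtype=float)
        var = var + by**2 * sx**2 / bx**4
    out = s.copy()
    out["ratio"] = ratio
    out["ratio_se"] = np.sqrt(var)
    out["weight"] = 1.0 / var
    return out


def ivw_closed_form(stats_df: pd.DataFrame) -> float:
    """Classical IVW slope: the sigma_Y^-2-weighted regression of outcome
    betas on exposure betas through the origin (equivalently the
    beta_X^2 sigma_Y^-2-weighted mean of the Wald ratios)."""
    s = _check_stats(stats_df, 2, "ivw")
    bx = s["beta_exposure"].to_numpy(dtype=float)
    by = s["beta_outcome"].to_numpy(dtype=float)
    w = 1.0 / s["se_outcome"].to_numpy(dtype=float) ** 2
    return float(np.sum(w * bx * by) / np.sum(w * bx**2))


def _q_exact(b, bx, by, sy2, sx2):
    return float(np.sum((by - b * bx) ** 2 / (sy2 + b**2 * sx2)))


def ivw_exact(stats_df: pd.DataFrame, effects_model: str = "random") -> TwoSampleResult:
    """Exact-weights IVW: the slope minimizing
    Q(b) = sum_j (beta_Yj - b beta_Xj)^2 / (sigma_Yj^2 + b^2 sigma_Xj^2),
    found by bracketed 1-D minimization seeded at the closed-form IVW
    value. With sigma_X = 0 this is the closed form exactly. Fixed-effects
    SE from the curvature at the optimum; random-effects SE additionally
    scaled by sqrt(max(1, Q/(J-1)))."""
    if effects_model not in ("fixed", "random"):
        raise ValueError("effects_model must be 'fixed' or 'random'")
    s = _check_stats(stats_df, 2, "ivw_exact")
    bx = s["beta_exposure"].to_numpy(dtype=float)
    by = s["beta_outcome"].to_numpy(dtype=float)
    sy2 = s["se_outcome"].to_numpy(dtype=float) ** 2
    sx2 = s["se_exposure"].to_numpy(dtype=float) ** 2
    j = len(bx)
    b0 = ivw_closed_form(s)
    if np.all(sx2 == 0):
        bhat = b0
    else:
        span = max(1.0, abs(b0)) * 4.0
        res = optimize.minimize_scalar(
            _q_exact,
            bounds=(b0 - span, b0 + span),
            args=(bx, by, sy2, sx2),
            method="bounded",
            options={"xatol": 1e-12},
        )
        if not res.success:  # pragma: no cover
            raise RuntimeError(f"exact-weights IVW failed to converge: {res.message}")
        bhat = float(res.x)
    # curvature-based (observed-information) fixed-effects variance
    h = max(1e-6, 1e-6 * abs(bhat))
    d2 = (
        _q_exact(bhat + h, bx, by, sy2, sx2)
        - 2 * _q_exact(bhat, bx, by, sy2, sx2)
        + _q_exact(bhat - h, bx, by, sy2, sx2)
    ) / h**2
    if d2 <= 0:
        d2 = 2.0 * np.sum(bx**2 / (sy2 + bhat**2 * sx2))
    se = math.sqrt(2.0 / d2)
    q = _q_exact(bhat, bx, by, sy2, sx2)
    if effects_model == "random":
        se *= math.sqrt(max(1.0, q / (j - 1)))
    return TwoSampleResult(
        method="ivw_exact",
        slope=bhat,
        se=se,
        ci_low=bhat - _Z95 * se,
        ci_high=bhat + _Z95 * se,
        n_snps=j,
        q_statistic=q,
    )


def _oriented(s: pd.DataFrame):
    sign = np.sign(s["beta_exposure"].to_numpy(dtype=float))
    bx = s["beta_exposure"].to_numpy(dtype=float) * sign
    by = s["beta_outcome"].to_numpy(dtype=float) * sign
    return bx, by


def mr_egger(stats_df: pd.DataFrame, effects_model: str = "random") -> TwoSampleResult:
    """MR-Egger: sigma_Y^-2-weighted regression of outcome betas on
    exposure betas with a free intercept, all exposure associations
    oriented positive. The intercept estimates the average directional
    pleiotropic effect; its test is reported. Random-effects SEs scale by
    sqrt(max(1, Q_R/(J-2)))."""
    s = _check_stats(stats_df, 3, "mr_egger")
    bx, by = _oriented(s)
    if np.allclose(bx, bx[0]):
        raise ValueError("slope/intercept not separable: no variation in exposure betas")
    w = 1.0 / s["se_outcome"].to_numpy(dtype=float) ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    qr = float(np.sum(w * resid**2))
    j = len(bx)
    cov = np.linalg.inv(xtwx)
    scale = max(1.0, qr / (j - 2)) if effects_model == "random" else 1.0
    se = np.sqrt(np.diag(cov) * scale)
    intercept, slope = float(coef[0]), float(coef[1])
    zint = intercept / se[0] if se[0] > 0 else np.inf
    return TwoSampleResult(
        method="egger",
        slope=slope,
        se=float(se[1]),
        ci_low=slope - _Z95 * se[1],
        ci_high=slope + _Z95 * se[1],
        n_snps=j,
        intercept=intercept,
        intercept_se=float(se[0]),
        intercept_pvalue=float(2 * stats.norm.sf(abs(zint))),
        q_statistic=qr,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation at cumulative weight 0.5;
    ties in the values are broken by input order (stable sort)."""
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cum, v))


def penalized_weighted_median(
    stats_df: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    penalty: float = 20.0,
) -> TwoSampleResult:
    """Penalized weighted median of the Wald ratios.

    Inverse-variance weights; each weight is then multiplied by
    min(1, penalty * p_j), where p_j is the one-sided chi^2_1 p-value of
    SNP j's heterogeneity contribution at the unpenalized weighted-median
    estimate, down-weighting outlying variants. SE by parametric bootstrap
    of the summary statistics."""
    s = _check_stats(stats_df, 3, "penalized_weighted_median")
    wr = wald_ratios(s)
    est = _pwm_point(wr, penalty)
    rng = stream_rng(seed, "median-bootstrap")
    boots = _parametric_boot(s, rng, n_boot, lambda d: _pwm_point(wald_ratios(d), penalty))
    se = float(np.std(boots, ddof=1))
    return TwoSampleResult(
        method="penalized_weighted_median",
        slope=est,
        se=se,
        ci_low=est - _Z95 * se,
        ci_high=est + _Z95 * se,
        n_snps=len(wr),
    )


def _pwm_point(wr: pd.DataFrame, penalty: float) -> float:
    ratios = wr["ratio"].to_numpy(dtype=float)
    w = wr["weight"].to_numpy(dtype=float)
    b0 = _weighted_median(ratios, w)
    q_j = w * (ratios - b0) ** 2
    p_j = stats.chi2.sf(q_j, df=1)
    w_pen = w * np.minimum(1.0, penalty * p_j)
    if w_pen.sum() == 0:
        raise ValueError("all weight removed by penalization")
    return _weighted_median(ratios, w_pen)


def _silverman_bandwidth(x: np.ndarray, factor: float) -> float:
    n = len(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(np.std(x, ddof=1), iqr / 1.349) if iqr > 0 else np.std(x, ddof=1)
    return factor * 0.9 * spread * n ** (-0.2)


def weighted_mode(
    stats_df: pd.DataFrame,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> TwoSampleResult:
    """Weighted mode of the Wald ratios: the argmax of a normal-kernel
    weighted density with a modified-Silverman bandwidth. SE by parametric
    bootstrap."""
    s = _check_stats(stats_df, 3, "weighted_mode")
    wr = wald_ratios(s)
    est = _mode_point(wr, bandwidth_factor)
    rng = stream_rng(seed, "mode-bootstrap")
    boots = _parametric_boot(
        s, rng, n_boot, lambda d: _mode_point(wald_ratios(d), bandwidth_factor)
    )
    se = float(np.std(boots, ddof=1))
    return TwoSampleResult(
        method="weighted_mode",
        slope=est,
        se=se,
        ci_low=est - _Z95 * se,
        ci_high=est + _Z95 * se,
        n_snps=len(wr),
    )


def _mode_point(wr: pd.DataFrame, bandwidth_factor: float) -> float:
    ratios = wr["ratio"].to_numpy(dtype=float)
    w = wr["weight"].to_numpy(dtype=float)
    if np.allclose(ratios, ratios[0]):
        return float(ratios[0])
    h = _silverman_bandwidth(ratios, bandwidth_factor)
    if h <= 0:
        raise ValueError("zero kernel bandwidth")
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 2048)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
    g0 = grid[int(np.argmax(dens))]
    span = grid[1] - grid[0]
    res = optimize.minimize_scalar(
        lambda b: -(w * np.exp(-0.5 * ((b - ratios) / h) ** 2)).sum(),
        bounds=(g0 - 2 * span, g0 + 2 * span),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def _parametric_boot(s: pd.DataFrame, rng, n_boot: int, point_fn) -> np.ndarray:
    bx = s["beta_exposure"].to_numpy(dtype=float)
    by = s["beta_outcome"].to_numpy(dtype=float)
    sx = s["se_exposure"].to_numpy(dtype=float)
    sy = s["se_outcome"].to_numpy(dtype=float)
    out = np.empty(n_boot)
    d = s.copy()
    for b in range(n_boot):
        d = d.assign(
            beta_exposure=rng.normal(bx, sx),
            beta_outcome=rng.normal(by, sy),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            out[b] = point_fn(d)
    return out


def cochran_q(wr: pd.DataFrame, beta_ref: float):
    """Cochran's Q about a reference slope, with per-SNP contributions
    q_j = beta_Xj^2 sigma_Yj^-2 (ratio_j - beta_ref)^2. Returns
    (Q, contributions Series); p-value against chi^2(J-1)."""
    if len(wr) < 2:
        raise ValueError("Cochran's Q needs at least 2 SNPs")
    bx = wr["beta_exposure"].to_numpy(dtype=float)
    sy2 = wr["se_outcome"].to_numpy(dtype=float) ** 2
    ratios = wr["beta_outcome"].to_numpy(dtype=float) / bx
    contrib = bx**2 / sy2 * (ratios - beta_ref) ** 2
    q = float(contrib.sum())
    return q, pd.Series(contrib, index=wr["variant_id"].to_numpy(), name="q_contribution")


def rucker_q(stats_df: pd.DataFrame, egger: TwoSampleResult):
    """Rucker's Q': weighted residual sum of squares about the Egger fit,
    sum_j sigma_Yj^-2 (beta_Yj - b0 - b1 beta_Xj)^2 on the positively
    oriented betas; compared with chi^2(J-2). Always <= Cochran's Q."""
    s = _check_stats(stats_df, 3, "rucker_q")
    bx, by = _oriented(s)
    sy2 = s["se_outcome"].to_numpy(dtype=float) ** 2
    resid = by - egger.intercept - egger.slope * bx
    contrib = resid**2 / sy2
    return float(contrib.sum()), pd.Series(
        contrib, index=s["variant_id"].to_numpy(), name="q_rucker_contribution"
    )


def heterogeneity_report(stats_df: pd.DataFrame) -> HeterogeneityReport:
    """Q (at the closed-form IVW slope) and Q' (at the Egger fit) with
    per-SNP contributions."""
    s = _check_stats(stats_df, 3, "heterogeneity_report")
    j = len(s)
    b_ivw = ivw_closed_form(s)
    qc, contrib_c = cochran_q(s, b_ivw)
    egger = mr_egger(s)
    qr, contrib_r = rucker_q(s, egger)
    contrib = pd.DataFrame(
        {"q_contribution": contrib_c, "q_rucker_contribution": contrib_r}
    ).reset_index(names="variant_id")
    return HeterogeneityReport(
        q_cochran=qc,
        df_cochran=j - 1,
        p_cochran=float(stats.chi2.sf(qc, j - 1)),
        q_rucker=qr,
        df_rucker=j - 2,
        p_rucker=float(stats.chi2.sf(qr, j - 2)),
        contributions=contrib,
    )


def leave_one_out(
    stats_df: pd.DataFrame,
    flag_alpha: float = 0.05,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Leave-one-out sensitivity table for outlier screening.

    For each SNP: the closed-form IVW estimate, Cochran's Q and Rucker's
    Q' recomputed without it, its own Q contribution, and a Bonferroni
    outlier flag (contribution chi^2_1 p < flag_alpha / J, or membership in
    the top_k contributions when given) — a reproducible stand-in for
    visual inspection of leave-one-out heterogeneity plots."""
    s = _check_stats(stats_df, 3, "leave_one_out")
    j = len(s)
    full = heterogeneity_report(s)
    b_full = ivw_closed_form(s)
    rows = []
    for i in range(j):
        rest = s.drop(s.index[i])
        vid = s.iloc[i]["variant_id"]
        b = ivw_closed_form(rest)
        qc, _ = cochran_q(rest, b)
        qr = (
            rucker_q(rest, mr_egger(rest))[0] if len(rest) >= 3 else float("nan")
        )
        contrib = float(
            full.contributions.set_index("variant_id").loc[vid, "q_contribution"]
        )
        rows.append(
            {
                "variant_id": vid,
                "estimate_without": b,
                "delta_estimate": b - b_full,
                "q_cochran_without": qc,
                "delta_q_cochran": qc - full.q_cochran,
                "q_rucker_without": qr,
                "q_contribution": contrib,
                "contribution_pvalue": float(stats.chi2.sf(contrib, 1)),
            }
        )
    out = pd.DataFrame(rows)
    if top_k is not None:
        thresh = out["q_contribution"].nlargest(top_k).min()
        out["flagged"] = out["q_contribution"] >= thresh
    else:
        out["flagged"] = out["contribution_pvalue"] < flag_alpha / j
    return out.sort_values("q_contribution", ascending=False).reset_index(drop=True)


def mvmr_ivw_twosample(
    stats_df: pd.DataFrame,
    exposure_columns: list[str],
    effects_model: str = "random",
) -> dict[str, TwoSampleResult]:
    """Multivariable two-sample IVW: sigma_Y^-2-weighted regression of the
    outcome betas on K exposure-beta columns through the origin. Reduces to
    the closed-form IVW when K = 1. Random-effects SEs scale by
    sqrt(max(1, Q/(J-K)))."""
    K = len(exposure_columns)
    X = stats_df[exposure_columns].to_numpy(dtype=float)
    y = stats_df["beta_outcome"].to_numpy(dtype=float)
    sy2 = stats_df["se_outcome"].to_numpy(dtype=float) ** 2
    j = len(y)
    if j <= K:
        raise ValueError("need more SNPs than exposures")
    if np.linalg.matrix_rank(X) < K:
        raise ValueError("collinear exposure beta columns")
    w = 1.0 / sy2
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coef
    q = float(np.sum(w * resid**2))
    scale = max(1.0, q / (j - K)) if effects_model == "random" else 1.0
    cov = np.linalg.inv(xtwx) * scale
    out = {}
    for k, name in enumerate(exposure_columns):
        se = math.sqrt(cov[k, k])
        out[name] = TwoSampleResult(
            method="mvmr_ivw",
            slope=float(coef[k]),
            se=se,
            ci_low=float(coef[k]) - _Z95 * se,
            ci_high=float(coef[k]) + _Z95 * se,
            n_snps=j,
            q_statistic=q,
        )
    return out


class _SummaryMREstimator(BaseEstimator):
    """Base for two-sample estimators fit on per-SNP summary arrays.

    ``fit(beta_exposure, beta_outcome, se_outcome, se_exposure=None)``
    treats SNPs as samples; fitted attributes: ``slope_``, ``se_``,
    ``result_`` (a :class:`TwoSampleResult`)."""

    def _frame(self, bx, by, sy, sx):
        bx = np.asarray(bx, dtype=float).reshape(len(by), -1)
        if bx.shape[1] != 1:
            raise ValueError("this estimator takes a single exposure-beta column")
        return pd.DataFrame(
            {
                "variant_id": [f"snp{i}" for i in range(len(by))],
                "beta_exposure": bx[:, 0],
                "se_exposure": np.zeros(len(by)) if sx is None else np.asarray(sx, dtype=float),
                "beta_outcome": np.asarray(by, dtype=float),
                "se_outcome": np.asarray(sy, dtype=float),
            }
        )

    def fit(self, beta_exposure, beta_outcome, se_outcome, se_exposure=None):
        frame = self._frame(beta_exposure, beta_outcome, se_outcome, se_exposure)
        self.result_ = self._point(frame)
        self.slope_ = self.result_.slope
        self.se_ = self.result_.se
        return self

    def predict(self, beta_exposure):
        """Predicted outcome betas under the fitted causal slope."""
        b = np.asarray(beta_exposure, dtype=float).reshape(-1)
        base = 0.0 if self.result_.intercept is None else self.result_.intercept
        return base + self.slope_ * b


class IVWEstimator(_SummaryMREstimator):
    """Exact-weights inverse-variance weighted estimator."""

    def __init__(self, effects_model: str = "random"):
        self.effects_model = effects_model

    def _point(self, frame):
        return ivw_exact(frame, self.effects_model)


class EggerEstimator(_SummaryMREstimator):
    """MR-Egger regression with pleiotropy intercept."""

    def __init__(self, effects_model: str = "random"):
        self.effects_model = effects_model

    def _point(self, frame):
        return mr_egger(frame, self.effects_model)


class WeightedMedianEstimator(_SummaryMREstimator):
    """Penalized weighted median estimator."""

    def __init__(self, n_boot: int = 1000, seed: int = 0, penalty: float = 20.0):
        self.n_boot = n_boot
        self.seed = seed
        self.penalty = penalty

    def _point(self, frame):
        return penalized_weighted_median(frame, self.n_boot, self.seed, self.penalty)


class WeightedModeEstimator(_SummaryMREstimator):
    """Weighted mode estimator."""

    def __init__(self, bandwidth_factor: float = 1.0, n_boot: int = 1000, seed: int = 0):
        self.bandwidth_factor = bandwidth_factor
        self.n_boot = n_boot
        self.seed = seed

    def _point(self, frame):
        return weighted_mode(frame, self.bandwidth_factor, self.n_boot, self.seed)


class MultivariableIVWEstimator(BaseEstimator):
    """Multivariable two-sample IVW on a (J x K) exposure-beta matrix.

    ``fit(beta_exposures, beta_outcome, se_outcome)``; fitted attributes:
    ``slopes_`` (array, one per exposure), ``results_`` (dict of
    :class:`TwoSampleResult`)."""

    def __init__(self, effects_model: str = "random"):
        self.effects_model = effects_model

    def fit(self, beta_exposures, beta_outcome, se_outcome):
        X = pd.DataFrame(beta_exposures)
        names = [str(c) for c in X.columns]
        frame = X.copy()
        frame.columns = names
        frame["beta_outcome"] = np.asarray(beta_outcome, dtype=float)
        frame["se_outcome"] = np.asarray(se_outcome, dtype=float)
        self.results_ = mvmr_ivw_twosample(frame, names, self.effects_model)
        self.slopes_ = np.array([self.results_[n].slope for n in names])
        return self


def plot_scatter(stats_df: pd.DataFrame, path, results: list | None = None) -> None:
    """Scatter of outcome vs exposure betas with fitted estimator lines
    (IVW through the origin; Egger with intercept), written to an image
    file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = _check_stats(stats_df, 2, "plot_scatter")
    bx, by = _oriented(s)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        bx, by, yerr=s["se_outcome"], xerr=s["se_exposure"],
        fmt="o", ms=3, lw=0.8, alpha=0.7, color="0.3",
    )
    xs = np.linspace(0, bx.max() * 1.05, 50)
    for res in results or []:
        intercept = res.intercept or 0.0
        ax.plot(xs, intercept + res.slope * xs, label=res.method)
    ax.set_xlabel("per-allele effect on exposure")
    ax.set_ylabel("per-allele effect on log admission rate")
    if results:
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_leave_one_out(loo: pd.DataFrame, path) -> None:
    """Bar plot of per-SNP heterogeneity contributions from a
    leave-one-out table, flagged outliers highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    colors = ["firebrick" if f else "0.5" for f in loo["flagged"]]
    ax.bar(range(len(loo)), loo["q_contribution"], color=colors)
    ax.set_xticks(range(len(loo)))
    ax.set_xticklabels(loo["variant_id"], rotation=90, fontsize=6)
    ax.set_ylabel("Q contribution")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
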