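"""Repeated-simulation validation experiments.

These functions run the package's estimators over many simulated cohorts
or summary-statistic sets and report calibration quantities: parameter
recovery and CI coverage for the one-sample Wald estimator, delta-method
vs simulation standard errors, heterogeneity-statistic null calibration,
and the behavior of the two-sample estimators under injected pleiotropy.
They back both the test suite and the reproduction script, with problem
sizes passed in by the caller.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .grs import compute_grs, fit_first_stage, orient_weights
from .observational import fit_quasipoisson
from .onesample import fit_second_stage, wald_iv
from .simulate import SimConfig, simulate_cohort, stream_rng
from .twosample import _pwm_point, ivw_closed_form, ivw_exact, mr_egger, wald_ratios

__all__ = [
    "true_weight_table",
    "onesample_estimate",
    "wald_2sps_difference",
    "onesample_recovery",
    "se_validity",
    "q_null_calibration",
    "pleiotropy_behavior",
    "generator_moments",
]


def true_weight_table(cohort):
    name = cohort.exposure_names[0]
    tbl = cohort.alleles[["variant_id", "effect_allele", "other_allele", "maf"]].copy()
    tbl["weight"] = cohort.true_weights[name].reindex(tbl["variant_id"]).to_numpy()
    tbl = tbl.rename(columns={"maf": "eaf"})
    return tbl[tbl["weight"] != 0.0].reset_index(drop=True)


def onesample_estimate(cohort, weak_f_threshold: float = 10.0):
    """GRS, first stage, second stage and Wald estimate for a simulated
    cohort using the ground-truth (oriented) instrument weights."""
    wt = orient_weights(true_weight_table(cohort))
    coded = cohort.alleles.set_index("variant_id")["effect_allele"]
    g = compute_grs(cohort.dosages, wt, dosage_alleles=coded)
    name = cohort.exposure_names[0]
    first = fit_first_stage(cohort.data[name], g)
    second = fit_second_stage(cohort.data["admissions"], g, cohort.data["person_years"])
    est = wald_iv(first, second, weak_f_threshold, exposure=name)
    return g, first, second, est


def wald_2sps_difference(n: int = 20_000, n_snps: int = 15, seed: int = 0) -> float:
    """|Wald ratio - 2SPS coefficient| on one simulated cohort.

    The 2SPS route regresses counts on the first-stage fitted exposure in
    a quasi-Poisson model; with a single GRS instrument the log-link makes
    the two routes an exact reparameterization.
    """
    cfg = SimConfig(n_participants=n, n_snps=n_snps, seed=seed)
    cohort = simulate_cohort(cfg)
    g, first, second, est = onesample_estimate(cohort)
    import statsmodels.api as sm

    fitted = sm.OLS(
        cohort.data[cohort.exposure_names[0]], sm.add_constant(np.asarray(g, dtype=float))
    ).fit().fittedvalues
    fit2 = fit_quasipoisson(
        cohort.data["admissions"], pd.DataFrame({"fitted": fitted}), cohort.data["person_years"]
    )
    b_2sps, _ = fit2.coef_for("fitted")
    return abs(est.log_rate_coef - b_2sps)


def onesample_recovery(
    n_reps: int = 200,
    n: int = 50_000,
    n_snps: int = 15,
    seed: int = 0,
) -> dict:
    """Parameter recovery of the one-sample Wald estimator.

    Simulates ``n_reps`` cohorts with confounding on and no pleiotropy,
    estimates the causal log-rate coefficient per exposure unit, and
    reports relative bias, 95% CI coverage, and the companion
    observational (confounded) estimate for contrast.
    """
    cfg0 = SimConfig(n_participants=n, n_snps=n_snps)
    truth = cfg0.true_log_rate_per_exposure_unit
    root = stream_rng(seed, "recovery-seeds")
    ests, ses, covered, obs = [], [], [], []
    for r in range(n_reps):
        rep_seed = int(root.integers(0, 2**31 - 1))
        cohort = simulate_cohort(replace(cfg0, seed=rep_seed))
        _, first, second, est = onesample_estimate(cohort)
        ests.append(est.log_rate_coef)
        ses.append(est.se)
        lo = est.log_rate_coef - 1.959963984540054 * est.se
        hi = est.log_rate_coef + 1.959963984540054 * est.se
        covered.append(lo <= truth <= hi)
        name = cohort.exposure_names[0]
        fit = fit_quasipoisson(
            cohort.data["admissions"], cohort.data[[name]], cohort.data["person_years"]
        )
        obs.append(fit.coef_for(name)[0])
    ests = np.asarray(ests)
    obs = np.asarray(obs)
    return {
        "truth": truth,
        "mean_estimate": float(ests.mean()),
        "relative_bias": float(ests.mean() / truth - 1.0),
        "coverage": float(np.mean(covered)),
        "mc_se": float(ests.std(ddof=1) / math.sqrt(n_reps)),
        "mean_delta_se": float(np.mean(ses)),
        "mean_observational": float(obs.mean()),
        "observational_mc_se": float(obs.std(ddof=1) / math.sqrt(n_reps)),
        "estimates": ests,
    }


def se_validity(
    n_reps: int = 500,
    n: int = 20_000,
    n_snps: int = 15,
    seed: int = 0,
) -> dict:
    """Delta-method SE against a parametric-simulation SE.

    Replicates the full data-generating process ``n_reps`` times at fixed
    parameters; the SD of the estimates across replicates is the reference
    SE, compared with the average delta-method SE.
    """
    cfg0 = SimConfig(n_participants=n, n_snps=n_snps)
    root = stream_rng(seed, "se-validity-seeds")
    ests, ses = [], []
    for r in range(n_reps):
        rep_seed = int(root.integers(0, 2**31 - 1))
        cohort = simulate_cohort(replace(cfg0, seed=rep_seed))
        _, _, _, est = onesample_estimate(cohort)
        ests.append(est.log_rate_coef)
        ses.append(est.se)
    boot_se = float(np.std(ests, ddof=1))
    delta_se = float(np.mean(ses))
    return {"delta_se": delta_se, "bootstrap_se": boot_se, "ratio": delta_se / boot_se}


def q_null_calibration(
    n_reps: int = 2000,
    n_snps: int = 30,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of Cochran's Q at the chi^2(J-1) critical value under
    a valid-instrument null (all heterogeneity from outcome sampling
    error)."""
    from scipy import stats as sps

    rng = stream_rng(seed, "q-null")
    crit = sps.chi2.ppf(1 - alpha, n_snps - 1)
    b = 0.1
    rejections = 0
    for _ in range(n_reps):
        bx = rng.uniform(0.03, 0.12, n_snps)
        sy = rng.uniform(0.005, 0.02, n_snps)
        by = rng.normal(b * bx, sy)
        frame = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(n_snps)],
                "beta_exposure": bx,
                "se_exposure": np.zeros(n_snps),
                "beta_outcome": by,
                "se_outcome": sy,
            }
        )
        bhat = ivw_closed_form(frame)
        wr = wald_ratios(frame)
        q = float((wr["weight"] * (wr["ratio"] - bhat) ** 2).sum())
        rejections += q > crit
    return rejections / n_reps


def _summary_replicate(rng, n_snps, b, invalid_frac, mode, m):
    bx = rng.uniform(0.05, 0.15, n_snps)
    sx = np.full(n_snps, 0.002)
    sy = np.full(n_snps, 0.002)
    alpha = np.zeros(n_snps)
    n_invalid = int(round(invalid_frac * n_snps))
    if n_invalid and mode != "none":
        idx = rng.choice(n_snps, n_invalid, replace=False)
        if mode == "directional":
            alpha[idx] = m
        else:  # balanced
            alpha[idx] = rng.normal(0.0, m, n_invalid)
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(n_snps)],
            "beta_exposure": rng.normal(bx, sx),
            "se_exposure": sx,
            "beta_outcome": rng.normal(b * bx + alpha, sy),
            "se_outcome": sy,
        }
    ), alpha


def pleiotropy_behavior(
    n_reps: int = 200,
    n_snps: int = 40,
    seed: int = 0,
    mode: str = "directional",
    invalid_frac: float = 0.3,
    direct_effect: float = 0.015,
    true_slope: float = 0.12,
) -> dict:
    """Behavior of IVW, Egger and the penalized weighted median under
    injected pleiotropy.

    Directional mode gives a fraction of SNPs a common positive direct
    effect (mean direct effect over all SNPs = invalid_frac *
    direct_effect); balanced mode draws mean-zero direct effects. Reports
    the mean point estimates with Monte Carlo SEs.
    """
    rng = stream_rng(seed, f"pleiotropy-{mode}")
    ivw_est, egger_slope, egger_int, pwm_est, mean_alpha = [], [], [], [], []
    for _ in range(n_reps):
        frame, alpha = _summary_replicate(rng, n_snps, true_slope, invalid_frac, mode, direct_effect)
        mean_alpha.append(alpha.mean())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            ivw_est.append(ivw_exact(frame).slope)
            e = mr_egger(frame)
            egger_slope.append(e.slope)
            egger_int.append(e.intercept)
            pwm_est.append(_pwm_point(wald_ratios(frame), penalty=20.0))
    def _m(x):
        x = np.asarray(x)
        return float(x.mean()), float(x.std(ddof=1) / math.sqrt(len(x)))

    out = {"true_slope": true_slope, "injected_mean_direct_effect": float(np.mean(mean_alpha))}
    for name, vals in (
        ("ivw", ivw_est),
        ("egger_slope", egger_slope),
        ("egger_intercept", egger_int),
        ("weighted_median", pwm_est),
    ):
        mean, mc = _m(vals)
        out[name] = mean
        out[f"{name}_mc_se"] = mc
    return out


def generator_moments(n: int = 300_000, seed: int = 0) -> dict:
    """Marginal moments of a default-configuration synthetic cohort."""
    cohort = simulate_cohort(SimConfig(n_participants=n, seed=seed))
    d = cohort.data
    return {
        "count_mean": float(d["admissions"].mean()),
        "count_variance": float(d["admissions"].var(ddof=1)),
        "followup_mean": float(d["person_years"].mean()),
        "followup_sd": float(d["person_years"].std(ddof=1)),
        "death_fraction": float(d["died"].mean()),
        "exposure_mean": float(d[cohort.exposure_names[0]].mean()),
        "exposure_sd": float(d[cohort.exposure_names[0]].std(ddof=1)),
    }
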