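"""Synthetic cohort generation for count-outcome Mendelian randomization.

This module simulates individual-level biobank-style cohorts with the
statistical structure the downstream estimators assume: independent SNP
dosages, an exposure built from many small genetic effects plus a latent
confounder, staggered-entry follow-up with administrative censoring and a
small death hazard, and overdispersed admission counts generated as a
gamma-frailty (negative-binomial marginal) Poisson process on person-time.

Default parameters target the moments of a large UK cohort: exposure mean
27.4 (SD 4.74) for a BMI-like trait, follow-up mean 6.05 y (SD 0.91) with
~2% deaths, admission counts with mean ~1.89 and variance ~55, and a
genetic risk score explaining ~1.7% of exposure variance.

All randomness flows from a single root seed through named sub-streams, so
identical configurations produce byte-identical cohorts.
"""

from __future__ import annotations

import json
import math
import warnings
import zlib
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SimConfig",
    "Cohort",
    "stream_rng",
    "generate_genotypes",
    "generate_exposures",
    "generate_followup",
    "inject_pleiotropy",
    "generate_admissions",
    "simulate_cohort",
    "simulate_two_exposure_cohort",
    "split_two_sample",
    "generate_summary_stats",
    "with_duplicated_snp",
]

_BASES = np.array(list("ACGT"))


def stream_rng(seed: int, label: str) -> np.random.Generator:
    """Named random sub-stream derived from a root seed.

    Uses a CRC32 hash of the label as a SeedSequence spawn key, so streams
    for different pipeline stages are independent and reproducible.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class SimConfig:
    """Configuration of one synthetic single-exposure cohort.

    Parameters
    ----------
    n_participants, n_snps
        Cohort size and number of independent instrument SNPs.
    maf_range
        Minor-allele-frequency range; per-SNP MAF drawn uniformly in it.
    exposure_mean, exposure_sd
        Marginal moments of the exposure (BMI-like defaults 27.4 / 4.74).
    true_log_rate_per_exposure_unit
        Causal log rate ratio per exposure unit. The default corresponds to
        a rate ratio of 1.13 per exposure SD.
    grs_r2_target
        Fraction of exposure variance explained by the instrument set.
    confounder_effect_exposure
        Effect of the standard-normal latent confounder on the exposure, in
        exposure SDs per confounder SD.
    confounder_log_rate
        Effect of the confounder on the log admission rate.
    frailty_variance
        Variance of the mean-one gamma frailty multiplying the rate; 0 gives
        an equidispersed Poisson outcome. The default 13.6 is the
        closed-form moment-matching value reproducing count variance ~55.3
        at count mean 1.89 under the other defaults.
    mean_count_target
        Marginal admission-count mean used to calibrate the baseline rate.
    pleiotropy, pleiotropy_mean, pleiotropy_sd
        Direct SNP->log-rate effects: "none", "balanced" (mean zero) or
        "directional" (nonzero mean).
    recruit_window_years, max_followup_years, death_hazard
        Staggered uniform entry, administrative censoring horizon (from the
        start of the recruitment window) and exponential death hazard; the
        defaults give follow-up mean ~6.05 y, SD ~0.91, ~2% deaths.
    seed
        Root seed for all sub-streams.
    """

    n_participants: int = 310_000
    n_snps: int = 76
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_name: str = "bmi"
    exposure_mean: float = 27.4
    exposure_sd: float = 4.74
    true_log_rate_per_exposure_unit: float = math.log(1.13) / 4.74
    grs_r2_target: float = 0.017
    confounder_effect_exposure: float = 0.21
    confounder_log_rate: float = 0.2
    frailty_variance: float = 13.6
    mean_count_target: float = 1.89
    pleiotropy: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    recruit_window_years: float = 2.63
    max_followup_years: float = 7.43
    death_hazard: float = 0.0033
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must be ordered and within (0, 1)")
        if not (0.0 <= self.grs_r2_target < 1.0):
            raise ValueError("grs_r2_target must be in [0, 1)")
        if self.frailty_variance < 0:
            raise ValueError("frailty_variance must be nonnegative")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode: {self.pleiotropy!r}")
        if self.death_hazard < 0:
            raise ValueError("death_hazard must be nonnegative")

    @classmethod
    def bmi(cls, **overrides) -> "SimConfig":
        """BMI-like exposure preset (the module defaults)."""
        return cls(**overrides)

    @classmethod
    def whr(cls, **overrides) -> "SimConfig":
        """Waist-hip-ratio-like exposure preset: mean 0.872, SD 0.09,
        instruments explaining ~0.4% of variance, rate ratio 1.26 per SD."""
        defaults = dict(
            exposure_name="whr",
            exposure_mean=0.872,
            exposure_sd=0.09,
            grs_r2_target=0.004,
            n_snps=39,
            true_log_rate_per_exposure_unit=math.log(1.26) / 0.09,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(d["maf_range"])
        return d


@dataclass
class Cohort:
    """A simulated cohort plus the ground truth used to generate it.

    ``data`` holds one row per participant: dosage columns named by variant
    id, the exposure column(s), covariates (age, sex, confounder),
    person_years, admissions and died.
    """

    data: pd.DataFrame
    snp_ids: list[str]
    alleles: pd.DataFrame  # variant_id, effect_allele, other_allele (coded dosage allele)
    true_weights: dict[str, pd.Series]  # exposure name -> per-SNP weights
    direct_effects: pd.Series  # per-SNP direct log-rate effects
    config: SimConfig
    baseline_log_rate: float = float("nan")
    exposure_names: list[str] = field(default_factory=list)

    @property
    def dosages(self) -> pd.DataFrame:
        return self.data[self.snp_ids]

    def write(self, path, meta_path=None) -> None:
        """Write the cohort as tab-delimited text with a JSON sidecar."""
        self.data.to_csv(path, sep="\t", index=False)
        if meta_path is not None:
            meta = {
                "config": self.config.to_dict(),
                "snp_ids": self.snp_ids,
                "alleles": self.alleles.to_dict(orient="list"),
                "true_weights": {k: v.to_dict() for k, v in self.true_weights.items()},
                "direct_effects": self.direct_effects.to_dict(),
                "baseline_log_rate": self.baseline_log_rate,
                "exposure_names": self.exposure_names,
            }
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=1)

    @classmethod
    def read(cls, path, meta_path) -> "Cohort":
        """Read a cohort written by :meth:`write` (TSV + JSON sidecar)."""
        data = pd.read_csv(path, sep="\t")
        with open(meta_path) as fh:
            meta = json.load(fh)
        cfg = dict(meta["config"])
        cfg["maf_range"] = tuple(cfg["maf_range"])
        return cls(
            data=data,
            snp_ids=meta["snp_ids"],
            alleles=pd.DataFrame(meta["alleles"]),
            true_weights={k: pd.Series(v) for k, v in meta["true_weights"].items()},
            direct_effects=pd.Series(meta["direct_effects"]),
            config=SimConfig(**cfg),
            baseline_log_rate=meta["baseline_log_rate"],
            exposure_names=meta["exposure_names"],
        )


def generate_genotypes(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw an n x J dosage matrix of independent binomial(2, maf) SNPs.

    Returns (dosages, alleles): a DataFrame with one column per variant id,
    and an allele table recording which allele the dosage counts.
    """
    if config.n_snps == 0:
        raise ValueError("no instruments: n_snps must be >= 1")
    rng = rng if rng is not None else stream_rng(config.seed, "genotypes")
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=config.n_snps)
    ids = [f"rs{j + 1:05d}" for j in range(config.n_snps)]
    dose = rng.binomial(2, mafs, size=(config.n_participants, config.n_snps))
    allele_idx = np.array([rng.choice(4, size=2, replace=False) for _ in ids])
    alleles = pd.DataFrame(
        {
            "variant_id": ids,
            "effect_allele": _BASES[allele_idx[:, 0]],
            "other_allele": _BASES[allele_idx[:, 1]],
            "maf": mafs,
        }
    )
    return pd.DataFrame(dose, columns=ids), alleles


def with_duplicated_snp(dosages: pd.DataFrame, variant_id: str, new_id: str) -> pd.DataFrame:
    """Append a perfect-LD (r^2 = 1) copy of an existing dosage column."""
    out = dosages.copy()
    out[new_id] = out[variant_id]
    return out


def generate_exposures(
    dosages: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    confounder: np.ndarray | None = None,
):
    """Build the exposure from SNP dosages, a latent confounder and noise.

    exposure = mean + sum_j w_j * dosage_j + gamma * confounder + noise,
    with the weights jointly rescaled so the realized genetic component
    explains ``grs_r2_target`` of the configured exposure variance, and the
    noise variance chosen so the marginal SD matches ``exposure_sd``.

    Returns (exposure, confounder, weights); the weights are the ground
    truth per-allele effects on the dosage coding of ``dosages``.
    """
    rng = rng if rng is not None else stream_rng(config.seed, "exposure")
    n, j = dosages.shape
    if confounder is None:
        confounder = stream_rng(config.seed, "confounder").standard_normal(n)
    r2 = config.grs_r2_target
    gamma = config.confounder_effect_exposure * config.exposure_sd
    resid_var = config.exposure_sd**2 * (1.0 - r2 - config.confounder_effect_exposure**2)
    if resid_var <= 0:
        raise ValueError(
            "grs_r2_target and confounder_effect_exposure leave no residual variance"
        )
    d = dosages.to_numpy(dtype=float)
    if r2 == 0.0:
        weights = np.zeros(j)
        genetic = np.zeros(n)
    else:
        raw = rng.standard_normal(j)
        g = d @ raw
        gvar = g.var()
        if gvar == 0:
            raise ValueError("dosage matrix has no variation")
        scale = math.sqrt(r2 * config.exposure_sd**2 / gvar)
        weights = raw * scale
        genetic = g * scale
    noise = rng.normal(0.0, math.sqrt(resid_var), size=n)
    exposure = config.exposure_mean + (genetic - genetic.mean()) + gamma * confounder + noise
    return (
        pd.Series(exposure, name=config.exposure_name),
        pd.Series(confounder, name="confounder"),
        pd.Series(weights, index=dosages.columns, name="weight"),
    )


def generate_followup(config: SimConfig, n: int | None = None, rng=None):
    """Staggered entry, administrative censoring and exponential death.

    Entry is uniform over the recruitment window; follow-up runs to the
    administrative horizon or an independent exponential death time,
    whichever is first. Returns (person_years, died).
    """
    if config.max_followup_years <= config.recruit_window_years:
        raise ValueError("censoring horizon must exceed the recruitment window")
    n = n if n is not None else config.n_participants
    rng = rng if rng is not None else stream_rng(config.seed, "followup")
    entry = rng.uniform(0.0, config.recruit_window_years, size=n)
    admin = config.max_followup_years - entry
    if config.death_hazard > 0:
        death_time = rng.exponential(1.0 / config.death_hazard, size=n)
        died = (death_time < admin).astype(int)
        t = np.minimum(admin, death_time)
    else:
        died = np.zeros(n, dtype=int)
        t = admin
    return pd.Series(t, name="person_years"), pd.Series(died, name="died")


def inject_pleiotropy(config: SimConfig, n_snps: int | None = None, rng=None) -> pd.Series:
    """Per-SNP direct effects on the log admission rate (the ground truth
    exclusion-restriction violation). Mode "none" gives an exact zero
    vector; "balanced" draws i.i.d. mean-zero effects; "directional" draws
    i.i.d. effects around a nonzero configured mean."""
    n_snps = n_snps if n_snps is not None else config.n_snps
    rng = rng if rng is not None else stream_rng(config.seed, "pleiotropy")
    ids = [f"rs{j + 1:05d}" for j in range(n_snps)]
    if config.pleiotropy == "none":
        vals = np.zeros(n_snps)
    elif config.pleiotropy == "balanced":
        vals = rng.normal(0.0, config.pleiotropy_sd, size=n_snps)
    elif config.pleiotropy == "directional":
        vals = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=n_snps)
    else:  # pragma: no cover - guarded in SimConfig
        raise ValueError(f"unknown pleiotropy mode: {config.pleiotropy!r}")
    return pd.Series(vals, index=ids, name="direct_effect")


def generate_admissions(
    person_years,
    exposure,
    confounder,
    config: SimConfig,
    rng=None,
    extra_log_rate=None,
):
    """Draw overdispersed admission counts on person-time.

    y ~ Poisson(t * nu * exp(b0 + beta*exposure + beta_c*confounder + extra)),
    with nu a mean-one gamma frailty of variance ``frailty_variance``. The
    baseline b0 is calibrated so the expected marginal count mean equals
    ``mean_count_target``. Returns (counts, baseline_log_rate).
    """
    if config.frailty_variance < 0:
        raise ValueError("frailty_variance must be nonnegative")
    rng = rng if rng is not None else stream_rng(config.seed, "admissions")
    t = np.asarray(person_years, dtype=float)
    if np.any(t <= 0):
        raise ValueError("person_years must be positive")
    eta = config.true_log_rate_per_exposure_unit * np.asarray(exposure, dtype=float)
    eta = eta + config.confounder_log_rate * np.asarray(confounder, dtype=float)
    if extra_log_rate is not None:
        eta = eta + np.asarray(extra_log_rate, dtype=float)
    b0 = math.log(config.mean_count_target) - math.log(np.mean(t * np.exp(eta)))
    if config.frailty_variance > 0:
        shape = 1.0 / config.frailty_variance
        nu = rng.gamma(shape, config.frailty_variance, size=t.shape[0])
    else:
        nu = np.ones_like(t)
    counts = rng.poisson(t * nu * np.exp(b0 + eta))
    return pd.Series(counts, name="admissions"), b0


def _covariates(config: SimConfig, n: int) -> pd.DataFrame:
    rng = stream_rng(config.seed, "covariates")
    age = rng.normal(57.4, 7.99, size=n)
    sex = rng.binomial(1, 0.537, size=n)  # 1 = female
    return pd.DataFrame({"age": age, "sex": sex})


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a complete single-exposure cohort under ``config``."""
    dosages, alleles = generate_genotypes(config)
    exposure, confounder, weights = generate_exposures(dosages, config)
    t, died = generate_followup(config)
    direct = inject_pleiotropy(config)
    extra = dosages.to_numpy(dtype=float) @ direct.to_numpy() if direct.abs().sum() else None
    counts, b0 = generate_admissions(t, exposure, confounder, config, extra_log_rate=extra)
    cov = _covariates(config, config.n_participants)
    data = pd.concat(
        [
            pd.Series(np.arange(config.n_participants), name="pid"),
            dosages,
            exposure,
            confounder,
            cov,
            t,
            counts,
            died,
        ],
        axis=1,
    )
    return Cohort(
        data=data,
        snp_ids=list(dosages.columns),
        alleles=alleles,
        true_weights={config.exposure_name: weights},
        direct_effects=direct,
        config=config,
        baseline_log_rate=b0,
        exposure_names=[config.exposure_name],
    )


def simulate_two_exposure_cohort(
    config_a: SimConfig, config_b: SimConfig, seed: int | None = None
) -> Cohort:
    """Generate a cohort with two exposures driven by disjoint SNP sets.

    The combined dosage matrix holds config_a.n_snps + config_b.n_snps SNPs;
    each exposure loads only on its own block, both share the latent
    confounder, and the admission rate combines both causal effects. Used
    for multivariable MR scenarios. Cohort size and follow-up come from
    ``config_a``; ``seed`` overrides config_a.seed when given.
    """
    seed = config_a.seed if seed is None else seed
    n = config_a.n_participants
    total = config_a.n_snps + config_b.n_snps
    joint = replace(config_a, seed=seed, n_snps=total)
    dosages, alleles = generate_genotypes(joint)
    ids = list(dosages.columns)
    block_a, block_b = ids[: config_a.n_snps], ids[config_a.n_snps :]
    confounder = stream_rng(seed, "confounder").standard_normal(n)
    expo_a, _, w_a = generate_exposures(
        dosages[block_a], replace(config_a, seed=seed), stream_rng(seed, "exposure-a"), confounder
    )
    expo_b, _, w_b = generate_exposures(
        dosages[block_b],
        replace(config_b, n_participants=n, seed=seed),
        stream_rng(seed, "exposure-b"),
        confounder,
    )
    t, died = generate_followup(joint)
    direct = inject_pleiotropy(joint)
    extra = config_b.true_log_rate_per_exposure_unit * expo_b.to_numpy()
    if direct.abs().sum():
        extra = extra + dosages.to_numpy(dtype=float) @ direct.to_numpy()
    counts, b0 = generate_admissions(
        t, expo_a, confounder, replace(config_a, seed=seed), extra_log_rate=extra
    )
    weights_a = pd.Series(0.0, index=ids, name="weight")
    weights_a[block_a] = w_a.to_numpy()
    weights_b = pd.Series(0.0, index=ids, name="weight")
    weights_b[block_b] = w_b.to_numpy()
    data = pd.concat(
        [
            pd.Series(np.arange(n), name="pid"),
            dosages,
            expo_a,
            expo_b,
            pd.Series(confounder, name="confounder"),
            _covariates(joint, n),
            t,
            counts,
            died,
        ],
        axis=1,
    )
    return Cohort(
        data=data,
        snp_ids=ids,
        alleles=alleles,
        true_weights={config_a.exposure_name: weights_a, config_b.exposure_name: weights_b},
        direct_effects=direct,
        config=joint,
        baseline_log_rate=b0,
        exposure_names=[config_a.exposure_name, config_b.exposure_name],
    )


def split_two_sample(data: pd.DataFrame, seed: int, fraction: float = 0.5):
    """Randomly split rows into two disjoint subsamples (for building
    non-overlapping exposure and outcome summary statistics)."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    n = len(data)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = stream_rng(seed, "two-sample-split")
    perm = rng.permutation(n)
    k = int(round(fraction * n))
    k = min(max(k, 1), n - 1)
    first = data.iloc[np.sort(perm[:k])]
    second = data.iloc[np.sort(perm[k:])]
    return first, second


def _marginal_linear(y, d, cov):
    x = sm.add_constant(np.column_stack([d] + cov))
    res = sm.OLS(y, x).fit()
    return res.params[1], res.bse[1], res.pvalues[1]


def _marginal_quasipoisson(y, d, cov, offset):
    x = sm.add_constant(np.column_stack([d] + cov))
    model = sm.GLM(y, x, family=sm.families.Poisson(), offset=offset)
    res = model.fit(scale="X2")
    return res.params[1], res.bse[1], res.pvalues[1]


def generate_summary_stats(
    cohort: Cohort,
    which: str,
    exposure: str | None = None,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP marginal association scan in GWAS-summary form.

    which="exposure" runs a linear regression of the exposure on each SNP
    dosage; which="outcome" runs a quasi-Poisson regression of admission
    counts on each SNP with a log person-years offset. Covariate columns
    may be adjusted for. Zero-variance SNPs are omitted with a warning.

    Returns columns: variant_id, effect_allele, other_allele, beta, se,
    pval, eaf, n.
    """
    if which not in ("exposure", "outcome"):
        raise ValueError("which must be 'exposure' or 'outcome'")
    df = cohort.data
    cov = [df[c].to_numpy(dtype=float) for c in (covariates or [])]
    if which == "exposure":
        name = exposure or cohort.exposure_names[0]
        y = df[name].to_numpy(dtype=float)
        offset = None
    else:
        y = df["admissions"].to_numpy()
        offset = np.log(df["person_years"].to_numpy(dtype=float))
    rows = []
    allele_map = cohort.alleles.set_index("variant_id")
    for snp in cohort.snp_ids:
        d = df[snp].to_numpy(dtype=float)
        if d.var() == 0:
            warnings.warn(f"SNP {snp} has zero dosage variance; omitted", UserWarning)
            continue
        if which == "exposure":
            beta, se, p = _marginal_linear(y, d, cov)
        else:
            beta, se, p = _marginal_quasipoisson(y, d, cov, offset)
        rows.append(
            {
                "variant_id": snp,
                "effect_allele": allele_map.loc[snp, "effect_allele"],
                "other_allele": allele_map.loc[snp, "other_allele"],
                "beta": beta,
                "se": se,
                "pval": p,
                "eaf": d.mean() / 2.0,
                "n": len(d),
            }
        )
    return pd.DataFrame(rows)
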