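"""Config-driven orchestration: simulate -> GRS -> observational ->
one-sample MR -> two-sample MR -> multivariable MR -> report.

A :class:`RunConfig` (typically loaded from YAML) declares the stages to
run, the simulation block and analysis options. Every stochastic stage
draws from a named sub-stream of the single root seed, so an identical
config yields a byte-identical results table. Results accumulate in a long
table with one row per (analysis, exposure, method, scale).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import grs as grs_mod
from . import observational as obs_mod
from . import onesample as os_mod
from . import twosample as ts_mod
from .simulate import Cohort, SimConfig, simulate_cohort, simulate_two_exposure_cohort
from .simulate import generate_summary_stats, split_two_sample

__all__ = ["RunConfig", "run_pipeline", "write_results", "read_results", "RESULT_COLUMNS"]

RESULT_COLUMNS = [
    "analysis",
    "exposure",
    "method",
    "scale",
    "estimate",
    "ci_low",
    "ci_high",
    "n",
    "f_statistic",
    "conditional_f",
    "dispersion",
    "q_cochran",
    "q_rucker",
    "j_snps",
]

_ALL_STAGES = ["simulate", "grs", "observational", "onesample", "twosample", "mvmr", "report"]


@dataclass
class RunConfig:
    """Declarative pipeline configuration.

    ``sim`` and ``sim_b`` are keyword blocks for :class:`SimConfig` (the
    second exposure is optional; when present the cohort is generated with
    two exposures on disjoint SNP blocks and the mvmr stage becomes
    available). ``seed`` overrides the sim blocks' seeds.
    """

    stages: list[str] = field(default_factory=lambda: _ALL_STAGES.copy())
    sim: dict = field(default_factory=dict)
    sim_b: dict | None = None
    seed: int = 0
    outdir: str | None = None
    covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    n_boot_mvmr: int = 10_000
    two_sample_fraction: float = 0.5
    r2_threshold: float = 0.001
    weak_f_threshold: float = 10.0
    verbosity: int = 1

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in _ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        names = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def demo(cls, seed: int = 0, **overrides) -> "RunConfig":
        """Desk-scale demo: n=20,000 participants, 60 SNPs across two
        exposures, 200 bootstrap replicates."""
        cfg = dict(
            stages=_ALL_STAGES.copy(),
            sim=dict(n_participants=20_000, n_snps=40, grs_r2_target=0.04),
            sim_b=dict(
                exposure_name="whr",
                exposure_mean=0.872,
                exposure_sd=0.09,
                grs_r2_target=0.02,
                n_snps=20,
                true_log_rate_per_exposure_unit=math.log(1.26) / 0.09,
            ),
            seed=seed,
            n_boot_mvmr=200,
        )
        cfg.update(overrides)
        return cls(**cfg)

    def build_sim_configs(self) -> tuple[SimConfig, SimConfig | None]:
        a = SimConfig(**{**self.sim, "seed": self.seed})
        b = None
        if self.sim_b is not None:
            merged = {**self.sim_b, "seed": self.seed}
            merged.setdefault("n_participants", a.n_participants)
            b = SimConfig(**merged)
        return a, b


def _fmt6(x) -> str:
    if isinstance(x, float):
        if math.isnan(x):
            return "NA"
        return f"{x:.6g}"
    return str(x)


def write_results(table: pd.DataFrame, path) -> None:
    """Write the results table as tab-delimited text, fixed column order,
    6 significant digits. An empty table is an error and creates no file."""
    if table is None or len(table) == 0:
        raise ValueError("results table is empty")
    out = table.reindex(columns=RESULT_COLUMNS)
    buf = io.StringIO()
    buf.write("\t".join(RESULT_COLUMNS) + "\n")
    for _, row in out.iterrows():
        buf.write("\t".join(_fmt6(v) for v in row.to_list()) + "\n")
    Path(path).write_text(buf.getvalue())


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def _row(analysis, exposure, method, scale, estimate, ci_low, ci_high, n, **diag):
    base = {
        "analysis": analysis,
        "exposure": exposure,
        "method": method,
        "scale": scale,
        "estimate": estimate,
        "ci_low": ci_low,
        "ci_high": ci_high,
        "n": n,
        "f_statistic": float("nan"),
        "conditional_f": float("nan"),
        "dispersion": float("nan"),
        "q_cochran": float("nan"),
        "q_rucker": float("nan"),
        "j_snps": float("nan"),
    }
    base.update(diag)
    return base


def _weight_table(cohort: Cohort, exposure: str) -> pd.DataFrame:
    w = cohort.true_weights[exposure]
    tbl = cohort.alleles[["variant_id", "effect_allele", "other_allele", "maf"]].copy()
    tbl["weight"] = w.reindex(tbl["variant_id"]).to_numpy()
    tbl["eaf"] = tbl.pop("maf")
    return tbl[tbl["weight"] != 0.0].reset_index(drop=True)


def run_pipeline(config: RunConfig):
    """Execute the declared stages in dependency order.

    Returns (results table, run log lines). When ``config.outdir`` is set,
    the cohort, summary statistics, results table and run log are written
    there as delimited text.
    """
    log: list[str] = []
    rows: list[dict] = []
    cfg_a, cfg_b = config.build_sim_configs()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    log.append(f"root seed: {config.seed}")
    stages = [s for s in _ALL_STAGES if s in config.stages]

    if "simulate" not in stages and any(
        s in stages for s in ("grs", "observational", "onesample", "twosample", "mvmr")
    ):
        raise ValueError("stage dependency unmet: analysis stages need 'simulate'")

    cohort = None
    if "simulate" in stages:
        cohort = (
            simulate_two_exposure_cohort(cfg_a, cfg_b, seed=config.seed)
            if cfg_b is not None
            else simulate_cohort(cfg_a)
        )
        log.append(
            f"simulate: n={len(cohort.data)}, snps={len(cohort.snp_ids)}, "
            f"exposures={cohort.exposure_names}, mean count="
            f"{cohort.data['admissions'].mean():.4f}"
        )
        if outdir:
            cohort.write(outdir / "cohort.tsv", outdir / "cohort_meta.json")

    sds = {name: float(cohort.data[name].std(ddof=1)) for name in cohort.exposure_names} if cohort else {}
    cov_df = cohort.data[config.covariates] if cohort is not None and config.covariates else None

    grs_fits: dict[str, tuple[pd.Series, grs_mod.FirstStageFit]] = {}
    if "grs" in stages:
        for name in cohort.exposure_names:
            wt = grs_mod.orient_weights(_weight_table(cohort, name))
            coded = cohort.alleles.set_index("variant_id")["effect_allele"]
            g = grs_mod.compute_grs(cohort.dosages, wt, dosage_alleles=coded)
            fs = grs_mod.fit_first_stage(cohort.data[name], g, cov_df)
            grs_fits[name] = (g, fs)
            log.append(
                f"grs[{name}]: J={len(wt)}, beta_exp={fs.beta_exp:.4f}, "
                f"R2={fs.r_squared:.5f}, F={fs.f_statistic:.1f}"
            )

    if "observational" in stages:
        for name in cohort.exposure_names:
            fit = obs_mod.fit_quasipoisson(
                cohort.data["admissions"],
                cohort.data[[name]],
                cohort.data["person_years"],
                cov_df,
            )
            b, se = fit.coef_for(name)
            for scale_name, s in (("per-unit", 1.0), ("per-SD", sds[name])):
                rr, lo, hi = obs_mod.rate_per_sd(b, se, s)
                rows.append(
                    _row(
                        "observational",
                        name,
                        "quasipoisson",
                        scale_name,
                        rr,
                        lo,
                        hi,
                        fit.n,
                        dispersion=fit.dispersion,
                    )
                )
            log.append(f"observational[{name}]: phi={fit.dispersion:.2f}")

    if "onesample" in stages:
        if "grs" not in stages:
            raise ValueError("stage dependency unmet: 'onesample' needs 'grs'")
        for name in cohort.exposure_names:
            g, fs = grs_fits[name]
            est = os_mod.OneSampleMR(weak_f_threshold=config.weak_f_threshold).fit(
                cohort.data[name],
                cohort.data["admissions"],
                g,
                cohort.data["person_years"],
                cov_df,
                exposure_name=name,
            )
            for scale_name, s in (("per-unit", 1.0), ("per-SD", sds[name])):
                e = est.estimate_.per_scale(s)
                rows.append(
                    _row(
                        "onesample_mr",
                        name,
                        "wald_iv",
                        scale_name,
                        e.rate_ratio,
                        e.ci_low,
                        e.ci_high,
                        e.n,
                        f_statistic=fs.f_statistic,
                        dispersion=est.second_stage_.dispersion,
                    )
                )
            log.append(f"onesample[{name}]: RR/SD={est.estimate_.per_scale(sds[name]).rate_ratio:.3f}")

    summary: dict[str, pd.DataFrame] = {}
    if "twosample" in stages or "mvmr" in stages:
        half_a, half_b = split_two_sample(cohort.data, config.seed, config.two_sample_fraction)
        coh_a = Cohort(
            half_a.reset_index(drop=True),
            cohort.snp_ids,
            cohort.alleles,
            cohort.true_weights,
            cohort.direct_effects,
            cohort.config,
            cohort.baseline_log_rate,
            cohort.exposure_names,
        )
        coh_b = Cohort(
            half_b.reset_index(drop=True),
            cohort.snp_ids,
            cohort.alleles,
            cohort.true_weights,
            cohort.direct_effects,
            cohort.config,
            cohort.baseline_log_rate,
            cohort.exposure_names,
        )
        out_stats = generate_summary_stats(coh_b, "outcome", covariates=config.covariates)
        r2 = ts_mod.dosage_r2(coh_a.dosages)
        for name in cohort.exposure_names:
            exp_stats = generate_summary_stats(
                coh_a, "exposure", exposure=name, covariates=config.covariates
            )
            instruments = set(
                cohort.true_weights[name].index[cohort.true_weights[name] != 0.0]
            )
            exp_stats = exp_stats[exp_stats["variant_id"].isin(instruments)]
            harm, audit = ts_mod.harmonize(exp_stats, out_stats)
            kept = ts_mod.ld_prune(harm, r2.loc[harm["variant_id"], harm["variant_id"]],
                                   config.r2_threshold)
            harm = harm[harm["variant_id"].isin(kept)].reset_index(drop=True)
            summary[name] = harm
            log.append(
                f"twosample[{name}]: {len(harm)} SNPs retained "
                f"({len(audit)} harmonization actions)"
            )
            if outdir:
                harm.to_csv(outdir / f"summary_{name}.tsv", sep="\t", index=False)

    if "twosample" in stages:
        for name in cohort.exposure_names:
            harm = summary[name]
            het = ts_mod.heterogeneity_report(harm)
            results = {
                "ivw_exact": ts_mod.ivw_exact(harm),
                "egger": ts_mod.mr_egger(harm),
                "penalized_weighted_median": ts_mod.penalized_weighted_median(
                    harm, seed=config.seed
                ),
                "weighted_mode": ts_mod.weighted_mode(harm, seed=config.seed),
            }
            for method, res in results.items():
                for scale_name, s in (("per-unit", 1.0), ("per-SD", sds[name])):
                    view = res.rate_view(s)
                    rows.append(
                        _row(
                            "twosample_mr",
                            name,
                            method,
                            scale_name,
                            view["rate_ratio"],
                            view["ci_low"],
                            view["ci_high"],
                            len(coh_b.data),
                            q_cochran=het.q_cochran,
                            q_rucker=het.q_rucker,
                            j_snps=res.n_snps,
                        )
                    )
            log.append(
                f"twosample[{name}]: Qc={het.q_cochran:.2f} (df {het.df_cochran}), "
                f"Qr={het.q_rucker:.2f} (df {het.df_rucker})"
            )
            if outdir:
                loo = ts_mod.leave_one_out(harm)
                loo.to_csv(outdir / f"leave_one_out_{name}.tsv", sep="\t", index=False)

    if "mvmr" in stages:
        if len(cohort.exposure_names) < 2:
            raise ValueError("stage dependency unmet: 'mvmr' needs two exposures")
        names = cohort.exposure_names
        mv = os_mod.MultivariableOneSampleMR(n_boot=config.n_boot_mvmr, seed=config.seed).fit(
            cohort.data["admissions"],
            cohort.data["person_years"],
            cohort.data[names],
            cohort.dosages,
            cov_df,
        )
        for name in names:
            est = mv.estimates_[name]
            for scale_name, s in (("per-unit", 1.0), ("per-SD", sds[name])):
                e = est.per_scale(s)
                rows.append(
                    _row(
                        "mvmr_onesample",
                        name,
                        "mvmr_bootstrap",
                        scale_name,
                        e.rate_ratio,
                        e.ci_low,
                        e.ci_high,
                        e.n,
                        conditional_f=float(mv.conditional_f_[name]),
                        j_snps=len(cohort.snp_ids),
                    )
                )
        # two-sample multivariable IVW on the joint summary statistics
        joint = None
        for name in names:
            part = summary[name][["variant_id", "beta_exposure", "se_exposure"]].rename(
                columns={"beta_exposure": f"beta_{name}", "se_exposure": f"se_{name}"}
            )
            joint = part if joint is None else joint.merge(part, on="variant_id", how="outer")
        any_name = names[0]
        outc = pd.concat([summary[n][["variant_id", "beta_outcome", "se_outcome"]] for n in names])
        outc = outc.drop_duplicates("variant_id")
        joint = joint.merge(outc, on="variant_id").fillna(0.0)
        mv2 = ts_mod.mvmr_ivw_twosample(joint, [f"beta_{n}" for n in names])
        for name in names:
            res = mv2[f"beta_{name}"]
            for scale_name, s in (("per-unit", 1.0), ("per-SD", sds[name])):
                view = res.rate_view(s)
                rows.append(
                    _row(
                        "mvmr_twosample",
                        name,
                        "mvmr_ivw",
                        scale_name,
                        view["rate_ratio"],
                        view["ci_low"],
                        view["ci_high"],
                        len(coh_b.data),
                        q_cochran=res.q_statistic,
                        j_snps=res.n_snps,
                    )
                )
        log.append(f"mvmr: conditional F = {mv.conditional_f_.round(2).to_dict()}")

    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if "report" in stages and outdir:
        if len(table):
            write_results(table, outdir / "results.tsv")
        (outdir / "run.log").write_text("\n".join(log) + "\n")
        (outdir / "run_config.json").write_text(
            json.dumps({**config.__dict__}, default=str, indent=1)
        )
    return table, log
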