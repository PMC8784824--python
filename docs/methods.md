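# Methods

## Model

Hospital admissions are modeled as counts `y_i` accrued over observed
person-years `t_i` under a log-linear rate model,

    log E[y_i] = log t_i + β₀ + βᵀx_i ,

so `exp(β_k)` is the factor by which the *yearly* admission rate changes
per unit of regressor `x_k`, and per-SD or per-0.1-unit rate ratios are
`exp(β_k·s)`. Real admission counts are strongly overdispersed, so all
inference is quasi-likelihood (quasi-Poisson): point estimates are the
Poisson MLEs; standard errors are inflated by √φ with φ the Pearson
dispersion X²/(n−p). Confidence intervals are Wald intervals on the log
scale, exponentiated — hence symmetric on the log scale, and the rate
ratio always equals the exponentiated coefficient exactly.

### One-sample instrumental-variable estimator

The instrument is a weighted genetic risk score
G_i = Σ_j w_j d_ij / Σ_j w_j, the estimated average number of
exposure-increasing alleles. Weights are first oriented so every effect
allele increases the exposure (negative weights flip alleles, weight sign
and allele frequency); a zero weight is rejected since it defines no
exposure-increasing allele. Missing dosages are an error, not imputed —
participants with inadequate genetic data should be excluded upstream.

The Wald ratio β_out/β_exp (linear first stage, quasi-Poisson second
stage) estimates the causal log-rate coefficient per exposure unit.
Because the log link is collapsible under linear substitution, this
equals the 2SPS coefficient from regressing counts on the first-stage
fitted exposure — exactly, as an affine reparameterization; the test
suite verifies agreement to ≤1e−10.

The delta-method variance is

    se² = se_out²/β_exp² + β_out²·se_exp²/β_exp⁴ ,

the first-order Taylor expansion treating the two stages as uncorrelated.
In a one-sample design the stages share individuals, so a cross-covariance
term is omitted; with small direct gene–outcome effects the omission is
mild, and the validation battery bounds it empirically: over 500 fully
replicated simulations at n = 20,000 the mean delta SE sits within ~5% of
the SD of the replicate estimates (the acceptance check allows 15%). A
first-stage F below 10 (configurable) triggers a weak-instrument warning.
The gene–exposure denominator defaults to the in-sample GRS slope; an
externally estimated coefficient can be substituted
(`OneSampleMR(external_beta_exp=...)`) for a hybrid design in which
exposure weights come from an external consortium.

WHR adjusted for BMI is operationalized as the residual of an OLS
regression of WHR on BMI (`residual_exposure`), used as the exposure with
its own instrument set.

### Multivariable one-sample MR

Each of K exposures is regressed on the full combined SNP set (plus
covariates); counts are then regressed on the K fitted-value columns
jointly in a quasi-Poisson model with offset, giving mutually adjusted
(direct) effects. Standard errors and percentile CIs come from a
full-sample nonparametric bootstrap of both stages (default 10,000
replicates; tests and the demo pipeline use a few hundred). Instrument
strength per exposure is the conditional Sanderson–Windmeijer F: exposure
k is regressed on the other exposures by 2SLS (instrumented by all J
SNPs), and the F statistic tests the instruments' joint explanatory power
for the 2SLS residual, with numerator df J−(K−1) and denominator df
n−J−(K−1)−1. When one exposure is an exact linear function of the others
the residual is numerically zero; a variance guard returns F = 0 rather
than a 0/0 ratio.

### Two-sample summary-statistics estimators

Given harmonized per-SNP exposure betas (β_Xj, σ_Xj) and outcome betas on
the log-rate scale (β_Yj, σ_Yj):

- **Exact-weights IVW.** The slope minimizes
  Q(b) = Σ (β_Yj − b β_Xj)²/(σ_Yj² + b²σ_Xj²). A bounded Brent search
  (xatol 1e−12) is seeded at the closed-form inverse-variance-weighted
  slope and bracketed within ±4·max(1,|b₀|); when all σ_Xj = 0 the
  objective is exactly quadratic and the closed form is returned
  directly. The fixed-effects SE comes from the curvature of Q at the
  optimum (central second difference, step 1e−6·max(1,|b̂|)); the
  random-effects SE multiplies it by √max(1, Q/(J−1)).
- **MR-Egger.** Rows are oriented so every β_Xj > 0 (negating β_Yj in
  tandem — the fit is invariant to each row's sign convention); a
  σ_Yj⁻²-weighted regression with intercept follows. The intercept
  estimates the average directional pleiotropic effect under InSIDE; its
  Wald p-value is reported. Random-effects scaling uses
  √max(1, Q′/(J−2)).
- **Penalized weighted median.** Wald ratios are weighted by
  β_Xj²/σ_Yj² (the first-order inverse ratio variance); the weighted
  median interpolates linearly at cumulative weight 0.5, with ties broken
  by input order via a stable sort. Each weight is then multiplied by
  min(1, 20·p_j), where p_j is the upper-tail χ²₁ p-value of the SNP's Q
  contribution at the unpenalized estimate; the penalty constant 20 is
  configurable. SEs are parametric-bootstrap (default 1,000 draws of the
  summary statistics from their sampling distributions).
- **Weighted mode.** The argmax of a normal-kernel weighted density of
  the ratios, bandwidth = factor × 0.9·min(sd, IQR/1.349)·J^(−1/5)
  (modified Silverman; factor default 1), located on a 2048-point grid
  and polished by bounded minimization. Parametric-bootstrap SEs.

Random-effects inference is multiplicative throughout (SE inflation
floored at 1) rather than an additive τ² — the convention of the
estimators' own literature; fixed-effects variants are available via
`effects_model="fixed"`.

**Heterogeneity.** Cochran's Q = Σ β_Xj²σ_Yj⁻²(β̂_j − β_IVW)² is referred
to χ²(J−1) (exact under the valid-instrument null when exposure betas
carry no error; the suite verifies a 5% ± 1.5-point rejection rate over
2,000 null replicates). Rücker's Q′ uses the Egger residuals with
χ²(J−2); because the Egger fit nests the origin-constrained IVW fit,
Q′ ≤ Q always. Leave-one-out tables report the estimate and both Q
statistics without each SNP plus its own Q contribution; outliers are
flagged by a Bonferroni-adjusted contribution p-value (< 0.05/J) with a
top-k override — a deterministic, reproducible replacement for visual
inspection of leave-one-out plots, not a reconstruction of any particular
published SNP exclusion.

**Harmonization.** Exposure and outcome tables are inner-joined on
variant id; outcome rows coded on the opposite allele are sign- and
frequency-flipped, strand flips are resolved by base complementing, and
strand-ambiguous (A/T, C/G) variants are dropped when the effect-allele
frequency lies in a configurable ambiguity window (default 0.42–0.58),
otherwise aligned by frequency. An audit table records every action.
**LD pruning** is greedy: SNPs are visited in order of ascending exposure
p-value and kept iff r² with every kept SNP is below the threshold
(default 0.001), guaranteeing no retained pair violates it.

**Multivariable two-sample IVW** regresses β_Yj on the K exposure-beta
columns through the origin with σ_Yj⁻² weights, random-effects scaling
√max(1, Q/(J−K)); with K = 1 it reproduces the closed-form IVW exactly.

### Observational benchmarks, imputation, pooling

The observational column is the same quasi-Poisson regression run
directly on the exposures and covariates. Missing covariates are handled
by m-fold multiple imputation (default m = 10) under a multivariate-normal
working model: complete-case mean/covariance (with a 1e−10 trace-scaled
ridge for stability), conditional-normal draws per incomplete row,
categorical columns imputed on their code scale and mapped to the nearest
observed level. This is a deliberately simple predictive-draw engine —
the load-bearing step is Rubin's pooling, which is exact:
T = W + (1 + 1/m)B with W the mean squared SE and B the between-imputation
variance of the estimates. The scheme assumes missingness at random given
the included columns, and the nearest-level treatment of categoricals is
approximate.

## The synthetic cohort generator

The generator emulates the data structure of a large prospective cohort
with linked admissions: per-participant SNP dosages, an anthropometric
exposure, a latent confounder, staggered recruitment, administrative
censoring with a small death hazard, and overdispersed admission counts.
Defaults (the BMI-like preset; a WHR-like preset is provided):

| parameter | default | meaning |
|---|---|---|
| n_participants | 310,000 | cohort size |
| n_snps | 76 | independent instruments, MAF ~ U(0.05, 0.5) |
| exposure mean / SD | 27.4 / 4.74 kg/m² | marginal exposure moments |
| grs_r2_target | 0.017 | exposure variance explained by instruments |
| true_log_rate_per_exposure_unit | ln(1.13)/4.74 | causal rate ratio 1.13/SD |
| confounder_effect_exposure | 0.21 | exposure SDs per confounder SD |
| confounder_log_rate | 0.2 | confounder effect on log rate |
| frailty_variance | 13.6 | gamma frailty variance (overdispersion) |
| mean_count_target | 1.89 | marginal admission-count mean |
| recruit_window / horizon | 2.63 / 7.43 y | uniform entry, admin. censoring |
| death_hazard | 0.0033 /y | exponential, independent of exposure |

SNP effects on the exposure are drawn i.i.d. normal and rescaled jointly
so the realized genetic component explains exactly the target variance
share — the "many small effects" regime; the residual variance is then
set so the marginal SD hits its target. Counts are drawn as
y ~ Poisson(t·ν·exp(β₀ + β x + β_c u)) with ν a mean-one gamma frailty,
giving a negative-binomial-type marginal that preserves the log-linear
rate model the estimators assume. The baseline β₀ is calibrated
empirically each draw so the expected count mean equals its target.

The frailty variance and follow-up window were fixed once by closed-form
moment matching: with v the variance of the linear predictor,
Var(y) = m + E[t²](1+φ)r²e^v − m² at rate r = m/E[t] gives φ ≈ 13.6 for
variance 55.3 at mean 1.89; the death tail contributes ≈ h·E[t³]/3 ≈ 0.25
y² of follow-up variance, so the entry window solves W²/12 = 0.91² − 0.25
and the horizon adds the ≈ 0.06 y expected loss to death. At n = 300,000
the defaults reproduce count mean ≈ 1.9, variance ≈ 55–57, follow-up
6.05 ± 0.90 y and 2.0% deaths.

All randomness flows from one root seed through named CRC32-keyed
SeedSequence sub-streams (genotypes, exposure, confounder, follow-up,
pleiotropy, admissions, covariates, splits, bootstraps), so identical
configurations are byte-identical end to end.

What the generator does **not** emulate: linkage disequilibrium (SNPs are
independent; perfect-LD duplicates can be injected explicitly), realistic
haplotype or ancestry structure, the episode-level construction of
admission counts, informative censoring (death is independent of exposure
by default, switchable), assortative mating, dynastic effects, or the
specific sociodemographic covariates of any real cohort (age and sex are
carried as columns with zero default rate effects; a single
standard-normal latent carries all confounding). Passing tests therefore
demonstrate internal statistical validity of the estimators under a
correctly specified log-linear frailty world — not robustness to the
structural violations real biobank data can harbor.

## Validation battery and problem sizes

The reproduction script and acceptance tests run, per seed: the
published-figure arithmetic (analysis n; first-stage F from R² via
F = (n−2)R²/(1−R²)); Wald ≡ 2SPS at n = 20,000; the IVW/WLS oracle
equivalence on 1,000 random summary sets; Q null calibration over 2,000
replicates at J = 30; parameter recovery and coverage over 200 cohorts of
n = 50,000 (instrument share and overdispersion at the generator
defaults); delta-vs-simulation SE over 500 replicates at n = 20,000;
directional (30% invalid SNPs) and balanced pleiotropy over 200 summary
replicates at J = 40; generator moments at n = 300,000; and the exact
invariants. These sizes keep a full run in the low minutes on one CPU
while leaving Monte Carlo error well inside the asserted bands — except
for the 200-replicate mean-bias band, whose own MC noise is of the same
order as the band; that is a property of the prescribed design, and the
recovery check should be read jointly with its coverage companion.

## Known limitations

- The delta-method SE omits the one-sample cross-stage covariance
  (slightly anti-conservative here: ratio ≈ 0.95 in the SE validity
  check).
- The weighted-mode bandwidth, the median penalty constant, and the
  palindromic ambiguity window are literature-conventional defaults, not
  estimated quantities.
- The imputation engine is a working-model MVN sampler, not a full
  EM/bootstrap multiple-imputation implementation.
- Bootstrap CIs for the multivariable one-sample estimator are
  percentile-based and inherit bootstrap noise at small replicate counts.
- The conditional F uses the homoskedastic Sanderson–Windmeijer
  construction; a heteroskedasticity-robust variant is not implemented.
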