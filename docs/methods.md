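# Methods

This note documents the statistical models implemented in `vitdmr`, the
synthetic-data conditions they are exercised under, the numerical choices,
and what the package's tests do and do not establish.

## Study design being modelled

The analysis contrasts two routes from serum 25-hydroxyvitamin D (25(OH)D,
nmol/L) to childhood dental outcomes:

1. an **observational** route — regression of outcomes on measured 25(OH)D
   with progressively richer confounder adjustment; and
2. a **Mendelian randomization (MR)** route — the same contrast driven by a
   weighted three-SNP allele score (*CYP2R1* rs10741657, *DHCR7* rs7944926,
   *GC* rs2282679), whose random allocation at conception makes it immune to
   the lifestyle confounding that contaminates route 1, provided the score
   affects outcomes only through 25(OH)D and is independent of confounders.

Outcomes: questionnaire caries experience (binary), dental general
anaesthetic (GA, binary), early caries onset (lower tertile of onset age
among cases), clinically examined caries (binary, subsample), and dmft
severity (zero-inflated count, subsample).

## Synthetic cohort generator

Real cohorts of this kind are access-controlled, so the generator is the
package's test bed.  It emulates the documented statistical structure; its
defaults are the study conditions and are not tuned per test.

**Genotypes.** Independent Binomial(2, p) allele counts per SNP
(Hardy-Weinberg), p = 0.40/0.23/0.29.  Imputed-dosage noise is available but
off by default: imputation quality for these variants is high (r² > 0.98),
so integer simulation is faithful.  The three SNPs reside in different genes
and are simulated without linkage disequilibrium.

**Exposure.**

```
vitd = mean + Σ βᵢ·dosageᵢ + A·sin(2πt/365.25 + φ) + Σ γⱼ·confounderⱼ* + ε
```

with β = (3.56, 2.15, 6.13) nmol/L, annual sinusoid of amplitude A = 12
nmol/L (a typical northern-latitude seasonal swing in children), standardized
confounder contributions, and a shifted log-normal residual ε (log-scale σ =
0.45, mean zero) giving the right skew that 25(OH)D shows empirically.  The
residual SD is solved so the **total** SD equals 19.9 nmol/L — the
near-normal reading IQR/1.349 of the target IQR width 26.9 nmol/L (48.2–75.1)
— and the intercept is placed so the overall median lands near 60.9 nmol/L.
The total-SD calibration treats the spread as approximately normal; the
reported dispersion is an IQR, so the implied SD is a modelling choice, not a
measured quantity.  Values are truncated at 0.

Measured confounders (sex, age at measurement, BMI, lag time, maternal
education, social class) are generated independently of genotype but
correlated with exposure and outcome — so exposure-quintile balance tables
flag them while score-quintile tables do not, reproducing the identifying
assumption.  A latent standard-normal confounder `u` can be given exposure
and outcome effects to create *unmeasured* confounding, the scenario MR is
for.

**Outcomes.** Caries is Bernoulli with a logistic linear predictor
`ψ·vitd + confounder terms`; the intercept is solved by bisection so the
marginal prevalence hits its target (default 27.3%; GA 10.2% with a +2
log-odds bump for caries cases, clustering GA in diseased children).  dmft is
zero-inflated Poisson (structural-zero probability 0.6, base rate 1.8,
log-rate slope log(0.95)/10 per nmol/L) in a 10% clinical subsample, capped
at 20 (deciduous dentition).  Onset age is uniform over 38–91 months among
cases.  Clinical caries status flips the questionnaire flag with
false-positive probability 5/78 and false-negative probability 72/546, the
validation-sample rates.  Genotypes are masked missing-completely-at-random
as a block for 959/6259 of participants by default, mirroring the study
flow; no informative missingness is modelled.

## Instrument and strength

Weights default to the per-allele effects (the discovery-study weights are
not reproducible here; proportionality to effect size preserves the
"weighted by strength" construction and the package accepts overrides).
Mean-1 normalization (`w̃ᵢ = m·wᵢ/Σw`) is the unique normalization putting a
three-SNP score on the documented 0–6 range.  Any participant missing a
dosage gets a missing score — complete-case, no imputation.

Strength is the OLS of 25(OH)D on the score: slope ≈ Σw̃ᵢβᵢ2pᵢqᵢ / Σw̃ᵢ²2pᵢqᵢ
≈ 3.95 nmol/L per weighted allele, and R² ≈ Σ2pᵢqᵢβᵢ²/Var(vitd) ≈ 5.8–5.9%
under the calibrated conditions; both closed forms are used as independent
oracles in tests and in the acceptance script.

## Seasonal adjustment

One annual harmonic (sin + cos, period 365.25 days) fitted by least squares;
harmonic count configurable.  One harmonic is the minimal reading of
"sine-cosine regression"; no latitude or trend terms.  Adjusted values are
`vitd − (seasonal component − its fitting-sample mean)`: subtracting the
fitting-sample mean of the seasonal component (rather than assuming it is
zero) keeps the sample mean conserved even when sampling does not tile the
year evenly, and keeps values on the nmol/L scale required by the
per-10-nmol/L effect convention.

## Observational ladder

Six logistic model specifications: unadjusted; season-adjusted exposure;
+lag; +age and sex; +maternal education; +BMI.  The documented ladder is
ambiguous about whether lag time stays in model 3; both variants are
implemented (`ladder("body")` default, `ladder("footnote")`) and neither is
asserted as canonical.  Exposure is modelled in nmol/L and reported as
OR per 10 nmol/L = exp(10β̂), so the per-10 convention is exact by
construction.  Fits are statsmodels `Logit` MLE on the complete cases of each
model; separation, non-convergence and single-class outcomes raise, naming
the model.

Categories use half-open intervals [0, 30), [30, 50), [50, ∞) nmol/L: the
conventional display ("30–49", ">50") leaves 49–50 unassigned, and the
half-open reading closes the gap while keeping 50 nmol/L "sufficient".
Boundaries are configurable.  Early onset is `age ≤ empirical 33⅓
percentile` among cases; the inclusive tie rule is deterministic and
documented because questionnaire onset ages are heavily tied (the flagged
fraction can exceed ⅓ by the tie mass).

**dmft severity** uses statsmodels `ZeroInflatedPoisson` (logit inflation,
intercept-only by default — whether the inflation part carried covariates is
not documented, so the minimal form is the default and covariates are
accepted).  Variance is the HC0 sandwich (inverse observed information
bread, outer-product-of-scores meat).  The exposure effect is
back-transformed to the count scale as exp(10β̂) with a delta-method CI.
BFGS convergence is accepted when the per-observation score is numerically
zero (< 1e-6), since the optimizer's gradient criterion is absolute and
scales with n.

## MR estimation

The causal parameter ψ (log OR per nmol/L) solves the G-estimation equation
of the double-logistic structural mean model:

1. fit the association model E[Y|X,Z] = expit(η₀ + η₁X + η₂Z);
2. form H(ψ) = expit(logit(m̂(X,Z)) − ψX), the outcome with the exposure
   effect removed;
3. find ψ with Σ(Zᵢ − Z̄)·Hᵢ(ψ) = 0 (Brent root-finding on |ψ| ≤ 1, which is
   a generous ±e¹⁰-per-10-nmol/L bracket; failure raises with a diagnostic
   grid).

CIs are percentile intervals from a nonparametric bootstrap over
participants (default 1,999 resamples), which respects the joint
genotype-exposure-outcome dependence; the p-value is normal-approximation on
the bootstrap SE.  The estimator family and CI method are
implementation-chosen: the root-form logistic SMM is the canonical variant,
and the always-computed two-stage (linear first stage, logistic second
stage) and instrument-stratified Wald-ratio estimators make the method
difference inspectable — all three agree on confounder-free data, and the
Wald ratio is the rare-disease-limit closed form.  MR models run without
covariates by default.  First-stage F < 10 attaches a weak-instrument
warning.  Bootstrap internals use a dedicated IRLS Newton solver (tested to
1e-8 against statsmodels) so resampling loops stay fast.

With strong unmeasured confounding the association model is mildly
misspecified (the true E[Y|X,Z] is a confounder-mixture, not exactly
logistic), which can shift the SMM estimate by a fraction of a bootstrap SE;
the recovery tests budget for this with a 3-SE criterion.

## Validation and balance

The 2×2 clinical-by-questionnaire table treats the clinical examination as
gold standard; false-positive and false-negative rates are defined relative
to the questionnaire classification, with per-cell exposure medians/IQRs.
The classification t-test is pooled-variance by default (Welch optional).
Quintiles use empirical 20/40/60/80% cutpoints with ties assigned to the
lower quintile — deterministic, order-independent, and the reason a discrete
score yields visibly unequal quintile sizes.  Balance tests are one-way
ANOVA F for continuous confounders (raw scale by default; Kruskal-Wallis
selectable for skewed ones) and Pearson χ² for categorical ones, with a
warning when more than 20% of expected cells fall below 1.

## Power

Analytic normal-approximation sample size for the IV Wald test with a binary
outcome: NCP = n·R²·log(OR)²·p(1−p) with OR per exposure SD, so

```
n = (z₁₋α/₂ + z_power)² / (R² · log(OR)² · p(1−p))
```

with exact minimality enforced against the two-sided power function.  At
α = 0.05, power 0.90, R² = 0.059, OR = 0.63, p = 0.273 this returns
n = 4,204.  The alternative's risk ratio is treated as an odds ratio by
default (`or_from_rr` available), because the provenance calculator's
convention is ambiguous.  The Monte-Carlo verifier simulates genotypes →
score → exposure → outcome and tests the reduced-form score-outcome
association (the IV test of no effect); logistic non-collapsibility
attenuates the reduced-form slope slightly, so empirical power runs ~3
percentage points below the analytic value — the verifier, not the formula,
is the authoritative internal check.

## Problem sizes and numerical choices

Test and acceptance runs use cohorts of 2,000–100,000: 100,000 for
instrument-strength and intercept-calibration checks, 50,000 for
causal-recovery, 2,000 × (2,000 cohorts) for test size and 2,000 × (500
cohorts, 399 bootstrap resamples) for interval coverage — sizes chosen so
Monte-Carlo error is small relative to each tolerance.  Logistic intercepts
are solved by Brent bisection to 1e-12; IRLS stops at step 1e-10 with a
1e-10 ridge; the SMM root is found to 1e-12.  All randomness flows through
seeded `numpy` generators with deterministically spawned child streams, so
cohorts, bootstraps and whole pipeline runs are bit-reproducible.

## Limitations

- The generator emulates marginal structure (prevalences, spread, skew,
  seasonality, misclassification rates), not real joint dependencies such as
  gene-environment interaction, MNAR missingness, population stratification
  or linkage disequilibrium; passing tests demonstrate correctness of the
  estimators under the stated model, not fidelity to any real cohort.
- Real-data effect estimates of the motivating design (e.g. observational
  and MR odds ratios in access-controlled cohort data) are not reproducible
  here; the package covers them by structural fidelity of the reports and by
  recovery of known simulated truths.
- The SMM variance is bootstrap-only; no analytic sandwich for ψ is
  provided.
- Single-instrument design: no pleiotropy-robust estimators (MR-Egger,
  median), which need multiple independent instruments.
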