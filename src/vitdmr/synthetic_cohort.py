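"""Seeded synthetic cohort generator.

Emulates the statistical structure of a UK birth-cohort study of circulating
25-hydroxyvitamin D (25(OH)D, nmol/L) and childhood dental caries:

* three independent vitamin-D-raising SNPs in Hardy-Weinberg equilibrium
  (CYP2R1 rs10741657, DHCR7 rs7944926, GC rs2282679) carried as imputation
  dosages in [0, 2];
* a right-skewed 25(OH)D distribution with an annual sinusoidal component,
  genetic per-allele effects, confounder contributions and a shifted
  log-normal residual, calibrated to a target total SD and median;
* binary caries experience and dental general-anaesthetic (GA) outcomes from
  logistic models whose intercepts are solved numerically to hit target
  marginal prevalences; zero-inflated Poisson dmft severity in a clinical
  examination subsample; questionnaire-vs-clinical misclassification; and
  age of caries onset among cases;
* missing-completely-at-random masking with a participant-flow summary.

The measured confounders (sex, age at measurement, BMI, maternal education,
social class, lag time) are generated independently of genotype but can be
correlated with both exposure and outcomes; an additional latent standard
normal confounder ``u`` is available to induce unmeasured exposure-outcome
confounding, which is what Mendelian randomization is meant to defeat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

DOSAGE_PREFIX = "dosage_"
DAYS_PER_YEAR = 365.25

__all__ = [
    "SnpSpec",
    "GeneratorConfig",
    "DEFAULT_SNPS",
    "default_config",
    "generate_genotypes",
    "generate_exposure",
    "generate_outcomes",
    "apply_missingness",
    "generate_cohort",
    "participant_flow",
    "dosage_columns",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpSpec:
    """One instrument variant: allele frequency, exposure effect, score weight.

    Alleles are oriented so the effect allele raises 25(OH)D, hence
    ``beta_exposure >= 0`` (nmol/L per allele).
    """

    id: str
    maf: float
    beta_exposure: float
    weight: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.maf) or not 0.0 <= self.maf <= 0.5:
            raise ValueError(
                f"SNP {self.id!r}: minor allele frequency {self.maf!r} "
                "must be finite and within [0, 0.5]"
            )
        if not np.isfinite(self.beta_exposure) or self.beta_exposure < 0:
            raise ValueError(
                f"SNP {self.id!r}: beta_exposure must be finite and >= 0 "
                "(orient alleles so the effect allele raises exposure)"
            )
        if not np.isfinite(self.weight) or self.weight < 0:
            raise ValueError(f"SNP {self.id!r}: weight must be finite and >= 0")

    @property
    def het(self) -> float:
        """2p(1-p), the dosage variance under Hardy-Weinberg equilibrium."""
        return 2.0 * self.maf * (1.0 - self.maf)


#: The three-variant instrument with its published allele frequencies and
#: per-allele 25(OH)D effects; weights default to the per-allele effects.
DEFAULT_SNPS: tuple[SnpSpec, ...] = (
    SnpSpec("rs10741657", 0.40, 3.56, 3.56),  # CYP2R1
    SnpSpec("rs7944926", 0.23, 2.15, 2.15),   # DHCR7
    SnpSpec("rs2282679", 0.29, 6.13, 6.13),   # GC
)


def _lognormal_sd(median: float, sigma: float) -> float:
    return median * math.exp(sigma**2 / 2.0) * math.sqrt(math.exp(sigma**2) - 1.0)


# Measured confounder distributions (means/SDs known analytically so that
# standardized effect sizes translate directly into variance contributions).
_EDU_LEVELS = ("CSE", "Vocational", "O level", "A level", "Degree")
_EDU_PROBS = np.array([0.202, 0.099, 0.346, 0.225, 0.129])
_EDU_PROBS = _EDU_PROBS / _EDU_PROBS.sum()
_SOC_LEVELS = ("I", "II", "III non-manual", "III manual", "IV", "V")
_SOC_PROBS = np.array([0.159, 0.448, 0.249, 0.104, 0.036, 0.005])
_SOC_PROBS = _SOC_PROBS / _SOC_PROBS.sum()

_AGE_MEAN, _AGE_SD = 117.3, 14.9          # months
_BMI_MEDIAN, _BMI_LOG_SD = 17.1, 0.153    # kg/m^2, log scale
_LAG_MEDIAN, _LAG_LOG_SD = 26.0, 0.41     # months, log scale
_FEMALE_P = 0.49

_edu_ord = np.arange(len(_EDU_LEVELS), dtype=float)
_EDU_MEAN = float(_edu_ord @ _EDU_PROBS)
_EDU_SD = float(math.sqrt(((_edu_ord - _EDU_MEAN) ** 2) @ _EDU_PROBS))

# name -> (mean, sd) used to standardize before applying effects
_CONF_STANDARDIZERS: dict[str, tuple[float, float]] = {
    "sex": (_FEMALE_P, math.sqrt(_FEMALE_P * (1 - _FEMALE_P))),
    "age_at_measure": (_AGE_MEAN, _AGE_SD),
    "bmi": (_BMI_MEDIAN * math.exp(_BMI_LOG_SD**2 / 2), _lognormal_sd(_BMI_MEDIAN, _BMI_LOG_SD)),
    "lag_months": (_LAG_MEDIAN * math.exp(_LAG_LOG_SD**2 / 2), _lognormal_sd(_LAG_MEDIAN, _LAG_LOG_SD)),
    "maternal_education": (_EDU_MEAN, _EDU_SD),
    "u": (0.0, 1.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    ``confounder_effects`` maps a confounder name to a pair
    ``(effect_on_exposure, effect_on_outcome_log_odds)`` applied to the
    *standardized* confounder, so each entry contributes
    ``effect_on_exposure**2`` to the exposure variance.  The special name
    ``"u"`` is a latent N(0,1) confounder that is generated but never exposed
    to the analysis modules (unmeasured confounding).
    """

    n: int = 6_259
    snps: tuple[SnpSpec, ...] = DEFAULT_SNPS
    exposure_mean: float = 57.1
    exposure_resid_sd: float = 16.9
    exposure_resid_log_sigma: float = 0.45  # skewness of the shifted log-normal residual
    seasonal_amplitude: float = 12.0
    seasonal_phase: float = -2.56  # radians; peak around late August
    date_window: tuple[str, str] = ("2001-01-01", "2001-12-31")
    causal_log_or_per_nmol: float = math.log(0.93) / 10.0
    causal_log_or_ga_per_nmol: float = math.log(0.96) / 10.0
    confounder_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "sex": (-1.0, 0.05),
            "age_at_measure": (-2.5, 0.0),
            "bmi": (-2.0, 0.10),
            "lag_months": (-1.5, 0.05),
            "maternal_education": (0.0, -0.15),
            "u": (0.0, 0.0),
        }
    )
    caries_base_rate: float = 0.273
    ga_base_rate: float = 0.102
    ga_caries_log_or: float = 2.0  # GA clusters in children with caries
    zip_inflation: float = 0.6
    zip_base_rate: float = 1.8  # Poisson mean of the non-structural-zero dmft part
    zip_log_rate_per_nmol: float = math.log(0.95) / 10.0
    onset_range_months: tuple[int, int] = (38, 91)
    clinical_fraction: float = 0.10  # share invited to clinical dental examination
    misclass_fp: float = 5.0 / 78.0  # P(no clinical caries | questionnaire case)
    misclass_fn: float = 72.0 / 546.0  # P(clinical caries | questionnaire control)
    dosage_noise_sd: float = 0.0  # optional fractional-imputation noise
    missing_rates: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.exposure_resid_sd <= 0:
            raise ValueError("exposure_resid_sd must be > 0")
        for name, p in {
            "caries_base_rate": self.caries_base_rate,
            "ga_base_rate": self.ga_base_rate,
            "zip_inflation": self.zip_inflation,
            "clinical_fraction": self.clinical_fraction,
            "misclass_fp": self.misclass_fp,
            "misclass_fn": self.misclass_fn,
            **{f"missing_rates[{k}]": v for k, v in self.missing_rates.items()},
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} = {p!r} is not a probability in [0, 1]")
        for name in self.confounder_effects:
            if name not in _CONF_STANDARDIZERS:
                raise ValueError(f"unknown confounder {name!r} in confounder_effects")

    # ---- analytic variance bookkeeping -----------------------------------

    @property
    def genetic_variance(self) -> float:
        """Sum of 2p(1-p) * beta^2 over SNPs (nmol/L squared)."""
        return float(sum(s.het * s.beta_exposure**2 for s in self.snps))

    @property
    def seasonal_variance(self) -> float:
        return self.seasonal_amplitude**2 / 2.0

    @property
    def confounder_variance(self) -> float:
        return float(sum(ex**2 for ex, _ in self.confounder_effects.values()))

    @property
    def total_exposure_variance(self) -> float:
        return (
            self.genetic_variance
            + self.seasonal_variance
            + self.confounder_variance
            + self.exposure_resid_sd**2
        )


def default_config(
    n: int = 6_259,
    seed: int = 0,
    *,
    total_sd: float = 19.9,
    median: float = 60.9,
    **overrides,
) -> GeneratorConfig:
    """Default cohort conditions, calibrated to a target 25(OH)D spread.

    The residual SD is solved so that the total 25(OH)D variance (genetic +
    seasonal + confounder + residual) equals ``total_sd**2``; 19.9 nmol/L is
    the near-normal reading IQR/1.349 of the target IQR width 26.9 nmol/L.
    ``exposure_mean`` is then placed so the overall median lands near
    ``median`` (the skewed residual has median below its zero mean; the
    genetic contribution has mean ``sum(2p * beta)``).
    """
    # genetic data are missing as a block for ~15% of otherwise-complete
    # participants (study-profile flow 6,259 -> 5,545)
    overrides.setdefault("missing_rates", {"genotype": 959.0 / 6259.0})
    base = GeneratorConfig(n=n, seed=seed, **overrides)
    other_var = base.genetic_variance + base.seasonal_variance + base.confounder_variance
    resid_var = total_sd**2 - other_var
    if resid_var <= 0:
        raise ValueError(
            f"target total SD {total_sd} nmol/L is below the systematic "
            f"components' SD {math.sqrt(other_var):.2f} nmol/L"
        )
    resid_sd = math.sqrt(resid_var)
    sigma = base.exposure_resid_log_sigma
    # shifted log-normal: X = exp(mu + sigma Z) - exp(mu + sigma^2/2), mean 0
    scale = resid_sd / math.sqrt(math.exp(sigma**2) * (math.exp(sigma**2) - 1.0))
    resid_median_offset = scale * (1.0 - math.exp(sigma**2 / 2.0))
    genetic_mean = sum(2.0 * s.maf * s.beta_exposure for s in base.snps)
    mean = median - genetic_mean - resid_median_offset
    return replace(base, exposure_resid_sd=resid_sd, exposure_mean=mean)


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

def dosage_columns(snps: tuple[SnpSpec, ...] | list[SnpSpec]) -> list[str]:
    return [DOSAGE_PREFIX + s.id for s in snps]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_genotypes(
    n: int,
    snps=DEFAULT_SNPS,
    seed=0,
    *,
    dosage_noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Draw independent Hardy-Weinberg genotypes as allele-count dosages.

    Each SNP is Binomial(2, maf), giving genotype probabilities
    (1-p)^2 / 2p(1-p) / p^2.  Optional Gaussian dosage noise (clipped back to
    [0, 2]) mimics fractional imputed dosages; it is off by default because
    imputation quality for these variants is high (r^2 > 0.98).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    cols = {}
    for snp in snps:
        dosage = rng.binomial(2, snp.maf, size=n).astype(float)
        if dosage_noise_sd > 0:
            dosage = np.clip(dosage + rng.normal(0.0, dosage_noise_sd, size=n), 0.0, 2.0)
        cols[DOSAGE_PREFIX + snp.id] = dosage
    return pd.DataFrame(cols)


# --------------------------------------------------------------------------
# confounders and exposure
# --------------------------------------------------------------------------

def _generate_confounders(n: int, rng: np.random.Generator) -> pd.DataFrame:
    sex = np.where(rng.random(n) < _FEMALE_P, "female", "male")
    age = np.clip(rng.normal(_AGE_MEAN, _AGE_SD, size=n), 85.0, 163.0)
    bmi = np.exp(rng.normal(math.log(_BMI_MEDIAN), _BMI_LOG_SD, size=n))
    lag = np.exp(rng.normal(math.log(_LAG_MEDIAN), _LAG_LOG_SD, size=n))
    edu = rng.choice(len(_EDU_LEVELS), size=n, p=_EDU_PROBS)
    soc = rng.choice(len(_SOC_LEVELS), size=n, p=_SOC_PROBS)
    u = rng.normal(size=n)
    return pd.DataFrame(
        {
            "sex": pd.Categorical(sex, categories=["female", "male"]),
            "age_at_measure": age,
            "bmi": bmi,
            "lag_months": lag,
            "maternal_education": pd.Categorical.from_codes(
                edu, categories=list(_EDU_LEVELS), ordered=True
            ),
            "social_class": pd.Categorical.from_codes(
                soc, categories=list(_SOC_LEVELS), ordered=True
            ),
            "u": u,
        }
    )


def _standardized_confounder(cohort: pd.DataFrame, name: str) -> np.ndarray:
    mean, sd = _CONF_STANDARDIZERS[name]
    if name == "sex":
        raw = (cohort["sex"] == "female").to_numpy(float)
    elif name == "maternal_education":
        raw = cohort["maternal_education"].cat.codes.to_numpy(float)
    else:
        raw = cohort[name].to_numpy(float)
    return (raw - mean) / sd


def _confounder_lp(cohort: pd.DataFrame, config: GeneratorConfig, which: int) -> np.ndarray:
    """Linear predictor contribution: which=0 exposure scale, 1 log-odds scale."""
    lp = np.zeros(len(cohort))
    for name, effects in config.confounder_effects.items():
        eff = effects[which]
        if eff != 0.0:
            lp += eff * _standardized_confounder(cohort, name)
    return lp


def generate_exposure(cohort: pd.DataFrame, config: GeneratorConfig, rng) -> pd.DataFrame:
    """Add ``sample_date`` and ``vitd`` columns.

    vitd = mean + sum(beta * dosage) + A * sin(2*pi*doy/365.25 + phase)
           + standardized-confounder effects + shifted log-normal residual,
    truncated at 0 nmol/L.  Sample dates are uniform over the calendar window.
    """
    if config.exposure_resid_sd <= 0:
        raise ValueError("exposure_resid_sd must be > 0")
    rng = _as_rng(rng)
    n = len(cohort)
    start = pd.Timestamp(config.date_window[0])
    end = pd.Timestamp(config.date_window[1])
    offsets = rng.integers(0, (end - start).days + 1, size=n)
    dates = start + pd.to_timedelta(offsets, unit="D")
    doy = dates.dayofyear.to_numpy(float)

    genetic = np.zeros(n)
    for snp in config.snps:
        genetic += snp.beta_exposure * cohort[DOSAGE_PREFIX + snp.id].to_numpy(float)
    seasonal = config.seasonal_amplitude * np.sin(
        2.0 * math.pi * doy / DAYS_PER_YEAR + config.seasonal_phase
    )
    sigma = config.exposure_resid_log_sigma
    if sigma > 0:
        scale = config.exposure_resid_sd / math.sqrt(
            math.exp(sigma**2) * (math.exp(sigma**2) - 1.0)
        )
        resid = scale * (np.exp(sigma * rng.normal(size=n)) - math.exp(sigma**2 / 2.0))
    else:
        resid = rng.normal(0.0, config.exposure_resid_sd, size=n)

    vitd = (
        config.exposure_mean
        + genetic
        + seasonal
        + _confounder_lp(cohort, config, 0)
        + resid
    )
    out = cohort.copy()
    out["sample_date"] = dates
    out["vitd"] = np.clip(vitd, 0.0, None)
    return out


# --------------------------------------------------------------------------
# outcomes
# --------------------------------------------------------------------------

def _solve_intercept(lp: np.ndarray, target: float, label: str) -> float:
    """Intercept alpha with mean(expit(alpha + lp)) == target, by bisection."""

    def gap(alpha: float) -> float:
        return float(np.mean(expit(alpha + lp))) - target

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            f"target prevalence {target} for {label!r} is unattainable: "
            "marginal-prevalence root not bracketed in alpha within [-30, 30]"
        )
    return brentq(gap, lo, hi, xtol=1e-12)


def generate_outcomes(cohort: pd.DataFrame, config: GeneratorConfig, rng) -> pd.DataFrame:
    """Add caries, ga, onset_age, dmft and clinical_caries columns."""
    rng = _as_rng(rng)
    n = len(cohort)
    vitd = cohort["vitd"].to_numpy(float)
    conf_y = _confounder_lp(cohort, config, 1)

    lp = config.causal_log_or_per_nmol * vitd + conf_y
    alpha = _solve_intercept(lp, config.caries_base_rate, "caries")
    caries = (rng.random(n) < expit(alpha + lp)).astype(float)

    lp_ga = (
        config.causal_log_or_ga_per_nmol * vitd
        + conf_y
        + config.ga_caries_log_or * caries
    )
    alpha_ga = _solve_intercept(lp_ga, config.ga_base_rate, "ga")
    ga = (rng.random(n) < expit(alpha_ga + lp_ga)).astype(float)

    lo, hi = config.onset_range_months
    onset = np.where(
        caries == 1, rng.integers(lo, hi + 1, size=n).astype(float), np.nan
    )

    clinical = rng.random(n) < config.clinical_fraction
    lam = config.zip_base_rate * np.exp(
        config.zip_log_rate_per_nmol * (vitd - float(np.mean(vitd)))
    )
    counts = rng.poisson(lam)
    structural_zero = rng.random(n) < config.zip_inflation
    dmft = np.where(structural_zero, 0, counts).astype(float)
    dmft = np.minimum(dmft, 20.0)  # deciduous dentition bound
    dmft[~clinical] = np.nan

    flip_case = rng.random(n) < config.misclass_fp
    flip_ctrl = rng.random(n) < config.misclass_fn
    clin_caries = np.where(caries == 1, 1.0 - flip_case, flip_ctrl * 1.0)
    clin_caries[~clinical] = np.nan

    out = cohort.copy()
    out["caries"] = caries
    out["ga"] = ga
    out["onset_age"] = onset
    out["dmft"] = dmft
    out["clinical_caries"] = clin_caries
    return out


# --------------------------------------------------------------------------
# missingness and flow
# --------------------------------------------------------------------------

def apply_missingness(cohort: pd.DataFrame, missing_rates: dict, seed=0) -> pd.DataFrame:
    """Mask fields missing-completely-at-random at the given per-field rates.

    The special key ``"genotype"`` masks all dosage columns jointly (genetic
    data tend to be missing as a block).
    """
    rng = _as_rng(seed)
    out = cohort.copy()
    for name, rate in missing_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missing rate for {name!r} is {rate!r}, not in [0, 1]")
        if rate == 0.0:
            continue
        mask = rng.random(len(out)) < rate
        if name == "genotype":
            targets = [c for c in out.columns if c.startswith(DOSAGE_PREFIX)]
        else:
            targets = [name]
        for col in targets:
            if col not in out.columns:
                raise KeyError(f"missing_rates names unknown column {col!r}")
            if isinstance(out[col].dtype, pd.CategoricalDtype):
                out.loc[mask, col] = np.nan
            else:
                vals = out[col].astype(float).to_numpy(copy=True)
                vals[mask] = np.nan
                out[col] = vals
    return out


_MULTIVARIABLE_FIELDS = [
    "vitd", "sample_date", "caries", "sex", "age_at_measure", "bmi",
    "lag_months", "maternal_education",
]


def participant_flow(cohort: pd.DataFrame) -> dict[str, int]:
    """Study-profile counts: eligible -> multivariable-complete -> MR-complete."""
    eligible = len(cohort)
    fields = [f for f in _MULTIVARIABLE_FIELDS if f in cohort.columns]
    multivariable = int(cohort[fields].notna().all(axis=1).sum())
    dosage_cols = [c for c in cohort.columns if c.startswith(DOSAGE_PREFIX)]
    mr = int(cohort[fields + dosage_cols].notna().all(axis=1).sum())
    return {
        "eligible": eligible,
        "multivariable_complete": multivariable,
        "mr_complete": mr,
        "excluded_multivariable": eligible - multivariable,
        "excluded_mr": multivariable - mr,
    }


# --------------------------------------------------------------------------
# end to end
# --------------------------------------------------------------------------

def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Full cohort: genotypes, confounders, exposure, outcomes, missingness.

    Bit-reproducible for a given (config, seed): all randomness flows through
    one seeded generator with deterministically spawned child streams.
    """
    seq = np.random.SeedSequence(config.seed)
    rng_geno, rng_conf, rng_expo, rng_out, rng_miss = (
        np.random.default_rng(s) for s in seq.spawn(5)
    )
    cohort = generate_genotypes(
        config.n, config.snps, rng_geno, dosage_noise_sd=config.dosage_noise_sd
    )
    cohort = pd.concat([cohort, _generate_confounders(config.n, rng_conf)], axis=1)
    cohort = generate_exposure(cohort, config, rng_expo)
    cohort = generate_outcomes(cohort, config, rng_out)
    if config.missing_rates:
        cohort = apply_missingness(cohort, config.missing_rates, rng_miss)
    cohort.insert(0, "id", np.arange(1, config.n + 1))
    return cohort
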