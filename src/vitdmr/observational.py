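"""Observational multivariable analyses of 25(OH)D and dental outcomes.

Implements the confounder-adjustment ladder of logistic regressions for the
binary outcomes (caries experience, dental GA, early caries onset, clinically
recorded caries), zero-inflated Poisson (ZIP) regression with sandwich
variance for dmft severity, the clinical 25(OH)D categorization
(deficient < 30, insufficient 30-49, sufficient >= 50 nmol/L), and the
lower-tertile early-onset dichotomization.

All effect estimates are reported per 10 nmol/L of 25(OH)D: the exposure is
modelled in nmol/L and the coefficient rescaled, so OR per 10 nmol/L equals
(OR per 1 nmol/L)**10 exactly.  Every fit is complete-case on the variables
of its own model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .season import SeasonalFit, deseasonalize, fit_seasonal

__all__ = [
    "ModelSpec",
    "EffectEstimate",
    "ZipFit",
    "CategoryTable",
    "ladder",
    "fit_logistic_ladder",
    "categorize_vitd",
    "early_onset_flag",
    "fit_zip_severity",
    "category_table",
    "VITD_CATEGORIES",
]

VITD_CATEGORIES = ("deficient", "insufficient", "sufficient")

#: covariates a ladder model may adjust for (beyond the seasonal adjustment)
_KNOWN_COVARIATES = ("lag_months", "sex", "age_at_measure", "maternal_education", "bmi")


@dataclass(frozen=True)
class ModelSpec:
    """One rung of the adjustment ladder."""

    tag: str
    season: bool = False
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.covariates) - set(_KNOWN_COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates {sorted(unknown)!r}")


def ladder(variant: str = "body") -> list[ModelSpec]:
    """The six-model adjustment ladder.

    ``variant="body"``: model 3 = season + age + sex (and models 4/5 build on
    it).  ``variant="footnote"``: model 3 additionally keeps lag time.  Both
    orderings circulate for this design; the body-text reading is the default.
    """
    lag3 = ("lag_months",) if variant == "footnote" else ()
    if variant not in ("body", "footnote"):
        raise ValueError("variant must be 'body' or 'footnote'")
    m3 = lag3 + ("sex", "age_at_measure")
    return [
        ModelSpec("unadjusted"),
        ModelSpec("m1", season=True),
        ModelSpec("m2", season=True, covariates=("lag_months",)),
        ModelSpec("m3", season=True, covariates=m3),
        ModelSpec("m4", season=True, covariates=m3 + ("maternal_education",)),
        ModelSpec("m5", season=True, covariates=m3 + ("bmi",)),
    ]


@dataclass(frozen=True)
class EffectEstimate:
    or_per_10: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    model: str
    outcome: str

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "model": self.model,
            "or_per_10": self.or_per_10,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n": self.n_used,
        }


def _design(cohort: pd.DataFrame, exposure: pd.Series, covariates) -> pd.DataFrame:
    """Exposure + dummy-coded covariate design frame (no intercept column)."""
    parts = {"vitd": exposure}
    for cov in covariates:
        col = cohort[cov]
        if cov == "sex":
            parts["female"] = (col == "female").astype(float)
        elif isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            # keep all-missing rows missing rather than all-zero
            dummies[col.isna()] = np.nan
            parts.update({c: dummies[c] for c in dummies.columns})
        else:
            parts[cov] = col.astype(float)
    return pd.DataFrame(parts, index=cohort.index)


def fit_logistic_ladder(
    cohort: pd.DataFrame,
    outcome: str,
    specs: list[ModelSpec] | None = None,
    *,
    season_fit: SeasonalFit | None = None,
) -> list[EffectEstimate]:
    """Maximum-likelihood logistic fits of one binary outcome along the ladder.

    Season-adjusted rungs use the deseasonalized exposure (sine-cosine fit on
    all complete exposure/date pairs unless a prefitted ``season_fit`` is
    given).  Raises on non-convergence, separation, or a single-class outcome,
    naming the model tag.
    """
    specs = ladder() if specs is None else specs
    if any(s.season for s in specs) and season_fit is None:
        season_fit = fit_seasonal(cohort["vitd"], cohort["sample_date"])
    adjusted = (
        deseasonalize(cohort["vitd"], cohort["sample_date"], season_fit)
        if season_fit is not None
        else None
    )
    y_all = cohort[outcome]
    estimates = []
    for spec in specs:
        exposure = adjusted if spec.season else cohort["vitd"]
        X = _design(cohort, exposure, spec.covariates)
        frame = pd.concat([y_all.rename("_y"), X], axis=1).dropna()
        y = frame.pop("_y").astype(float)
        if y.nunique() < 2:
            raise ValueError(
                f"model {spec.tag!r} for outcome {outcome!r}: "
                "outcome has a single class among complete cases"
            )
        design = sm.add_constant(frame.astype(float))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises on perfect separation
            raise ValueError(
                f"model {spec.tag!r} for outcome {outcome!r} failed: {exc}"
            ) from exc
        if not res.mle_retvals.get("converged", True):
            raise ValueError(f"model {spec.tag!r} for outcome {outcome!r} did not converge")
        beta = float(res.params["vitd"])
        se = float(res.bse["vitd"])
        z = stats.norm.ppf(0.975)
        estimates.append(
            EffectEstimate(
                or_per_10=float(np.exp(10.0 * beta)),
                ci_low=float(np.exp(10.0 * (beta - z * se))),
                ci_high=float(np.exp(10.0 * (beta + z * se))),
                p_value=float(res.pvalues["vitd"]),
                n_used=int(len(y)),
                model=spec.tag,
                outcome=outcome,
            )
        )
    return estimates


# --------------------------------------------------------------------------
# exposure categorization and onset dichotomization
# --------------------------------------------------------------------------

def categorize_vitd(vitd, *, boundaries: tuple[float, float] = (30.0, 50.0)) -> pd.Series:
    """Clinical 25(OH)D categories on half-open intervals.

    deficient: [0, 30); insufficient: [30, 50); sufficient: [50, inf).
    The upper edge of each interval is configurable; missing propagates and
    negative concentrations are rejected.
    """
    values = pd.Series(vitd, dtype=float)
    arr = values.to_numpy()
    if np.nanmin(arr, initial=np.inf) < 0:
        raise ValueError("negative 25(OH)D concentration")
    lo, hi = boundaries
    labels = np.select(
        [arr < lo, arr < hi, arr >= hi],
        VITD_CATEGORIES,
        default=None,
    )
    labels[~np.isfinite(arr)] = None
    return pd.Series(
        pd.Categorical(labels, categories=list(VITD_CATEGORIES), ordered=True),
        index=values.index,
        name="vitd_category",
    )


def early_onset_flag(onset_ages) -> pd.Series:
    """Lower-tertile early-onset indicator among caries cases.

    The cut is the empirical 33 1/3 percentile of non-missing onset ages;
    ages <= cut (ties included) are flagged early.  With heavily tied
    questionnaire ages the flagged fraction can exceed one third by the tie
    mass; the rule is deterministic.
    """
    ages = pd.Series(onset_ages, dtype=float)
    nonmiss = ages.dropna()
    if len(nonmiss) < 3:
        raise ValueError("need at least 3 non-missing onset ages")
    if nonmiss.nunique() == 1:
        raise ValueError("tertile undefined: all onset ages identical")
    cut = float(np.quantile(nonmiss, 1.0 / 3.0))
    flags = (ages <= cut).astype(float)
    flags[ages.isna()] = np.nan
    return flags.rename("early_onset")


# --------------------------------------------------------------------------
# zero-inflated Poisson severity model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ZipFit:
    count_params: pd.Series       # log scale
    inflation_params: pd.Series   # logit scale
    cov_robust: pd.DataFrame      # sandwich covariance, full parameter vector
    count_ratio_per_10: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    converged: bool
    zero_fraction_observed: float
    zero_fraction_poisson: float  # expected under the fitted plain-Poisson rates


def fit_zip_severity(
    dmft,
    vitd,
    covariates: pd.DataFrame | None = None,
    *,
    inflation_covariates: pd.DataFrame | None = None,
) -> ZipFit:
    """Zero-inflated Poisson fit of dmft on 25(OH)D with sandwich variance.

    The count part is log-linear in vitd (nmol/L) plus optional covariates;
    the inflation part is intercept-only by default (a logit model for the
    structural-zero probability).  The exposure effect is back-transformed to
    the count scale as exp(10 * coefficient) = multiplicative change in
    expected dmft per 10 nmol/L, with a delta-method (Wald) 95% CI from the
    robust covariance.
    """
    y = pd.Series(dmft, dtype=float).rename("dmft")
    x = pd.Series(np.asarray(vitd, dtype=float), index=y.index, name="vitd")
    frame = pd.concat([y, x], axis=1)
    if covariates is not None:
        frame = pd.concat([frame, covariates], axis=1)
    if inflation_covariates is not None:
        infl_cols = list(inflation_covariates.columns)
        frame = pd.concat([frame, inflation_covariates], axis=1)
    else:
        infl_cols = []
    frame = frame.dropna()
    yv = frame["dmft"]
    if np.any(yv < 0) or np.any(yv != np.round(yv)):
        raise ValueError("dmft must be non-negative integers")
    exog = sm.add_constant(frame.drop(columns=["dmft"] + infl_cols).astype(float))
    exog_infl = (
        sm.add_constant(frame[infl_cols].astype(float))
        if infl_cols
        else pd.DataFrame({"const": np.ones(len(frame))}, index=frame.index)
    )
    model = sm.ZeroInflatedPoisson(yv, exog, exog_infl=exog_infl, inflation="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=2000, disp=0, cov_type="HC0", gtol=1e-9)
    converged = bool(res.mle_retvals.get("converged", True))
    grad = np.asarray(model.score(np.asarray(res.params)))
    if not converged:
        # optimizer tolerance is on the absolute gradient; accept when the
        # per-observation score is numerically zero
        if np.max(np.abs(grad)) / len(yv) < 1e-6:
            converged = True
        else:
            raise ValueError(
                "zero-inflated Poisson fit did not converge; "
                f"gradient at the last iterate: {np.array2string(grad, precision=4)}"
            )
    params = res.params if isinstance(res.params, pd.Series) else pd.Series(
        res.params, index=res.model.exog_names
    )
    cov = pd.DataFrame(
        np.asarray(res.cov_params()), index=params.index, columns=params.index
    )
    infl_mask = params.index.str.startswith("inflate_")
    beta = float(params["vitd"])
    se = float(np.sqrt(cov.loc["vitd", "vitd"]))
    z = stats.norm.ppf(0.975)
    lam = np.exp(exog.to_numpy() @ params[~infl_mask].to_numpy())
    return ZipFit(
        count_params=params[~infl_mask],
        inflation_params=params[infl_mask],
        cov_robust=cov,
        count_ratio_per_10=float(np.exp(10.0 * beta)),
        ci_low=float(np.exp(10.0 * (beta - z * se))),
        ci_high=float(np.exp(10.0 * (beta + z * se))),
        p_value=float(2.0 * stats.norm.sf(abs(beta / se))),
        n_used=int(len(yv)),
        converged=converged,
        zero_fraction_observed=float(np.mean(yv == 0)),
        zero_fraction_poisson=float(np.mean(np.exp(-lam))),
    )


# --------------------------------------------------------------------------
# category table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryTable:
    table: pd.DataFrame  # per category: n, caries_n, caries_pct
    chi2: float
    p_value: float
    df: int


def category_table(cohort: pd.DataFrame) -> CategoryTable:
    """Caries proportion by 25(OH)D category with a chi-square test.

    Empty categories are reported with n = 0 and excluded from the test; if
    fewer than two non-empty categories remain the test is undefined (NaN).
    """
    cats = categorize_vitd(cohort["vitd"])
    frame = pd.DataFrame({"category": cats, "caries": cohort["caries"]}).dropna()
    rows = []
    for cat in VITD_CATEGORIES:
        sub = frame[frame["category"] == cat]
        n = len(sub)
        caries_n = int(sub["caries"].sum())
        rows.append(
            {
                "category": cat,
                "n": n,
                "caries_n": caries_n,
                "caries_pct": 100.0 * caries_n / n if n else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    counts = table[table["n"] > 0]
    if len(counts) < 2:
        return CategoryTable(table=table, chi2=np.nan, p_value=np.nan, df=0)
    contingency = np.column_stack(
        [counts["caries_n"], counts["n"] - counts["caries_n"]]
    )
    chi2, p, df, _ = stats.chi2_contingency(contingency, correction=False)
    return CategoryTable(table=table, chi2=float(chi2), p_value=float(p), df=int(df))
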