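"""End-to-end orchestration: cohort -> score -> season -> models -> reports.

A run is driven by a :class:`RunConfig` holding either a generator
configuration (synthetic run) or a path to a cohort CSV, plus the analysis
settings (score weights, ladder variant, bootstrap replicates, seed).  All
stage outputs are written as delimited text under the output directory, a
YAML manifest records the configuration echo and the participant-flow
counts, and re-running with an identical config and seed reproduces
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import mr as _mr
from . import observational as _obs
from . import scores as _scores
from . import season as _season
from . import validation as _val
from . import power as _power
from .synthetic_cohort import (
    DOSAGE_PREFIX,
    GeneratorConfig,
    default_config,
    generate_cohort,
    participant_flow,
)

__all__ = [
    "RunConfig",
    "RunManifest",
    "run_pipeline",
    "read_cohort",
    "write_cohort",
    "COHORT_SCHEMA",
]

logger = logging.getLogger("vitdmr")

#: column -> (kind, unit, note); the machine-readable file adds ranges
COHORT_SCHEMA: dict[str, tuple[str, str, str]] = {
    "id": ("int", "", "participant identifier"),
    "sex": ("category:female|male", "", "sex recorded at birth"),
    "age_at_measure": ("float", "months", "age at 25(OH)D measurement, >= 0"),
    "bmi": ("float", "kg/m^2", "body mass index, > 0"),
    "lag_months": ("float", "months", "lag between last caries measure and 25(OH)D, >= 0"),
    "maternal_education": (
        "category:CSE|Vocational|O level|A level|Degree", "", "ordered, lowest first"
    ),
    "social_class": (
        "category:I|II|III non-manual|III manual|IV|V", "", "household occupational class"
    ),
    "sample_date": ("date", "ISO-8601", "blood sample date"),
    "vitd": ("float", "nmol/L", "serum 25(OH)D, >= 0"),
    "caries": ("binary", "", "questionnaire caries experience"),
    "ga": ("binary", "", "dental general anaesthetic by 91 months"),
    "onset_age": ("float", "months", "age at first caries report; caries cases only"),
    "dmft": ("int", "count", "decayed/missing/filled deciduous teeth, 0-20"),
    "clinical_caries": ("binary", "", "caries at clinical examination"),
}


@dataclass(frozen=True)
class RunConfig:
    out_dir: str | Path = "vitdmr_run"
    cohort_path: str | Path | None = None
    generator: GeneratorConfig | None = None
    weights: tuple[float, ...] | None = None  # default: generator SNP weights
    ladder_variant: str = "body"
    category_boundaries: tuple[float, float] = (30.0, 50.0)
    bootstrap_reps: int = 1_999
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort_path is None) == (self.generator is None):
            raise ValueError(
                "exactly one of cohort_path or generator must be set per run"
            )


@dataclass
class RunManifest:
    config_echo: dict
    version: str
    flow: dict[str, int]
    stages: list[dict] = field(default_factory=list)
    analysis_n: dict[str, int] = field(default_factory=dict)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


# --------------------------------------------------------------------------
# cohort I/O
# --------------------------------------------------------------------------

def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write the cohort as CSV (header row, ISO dates, empty cell = missing)."""
    out = cohort.copy()
    if "sample_date" in out:
        out["sample_date"] = pd.to_datetime(out["sample_date"]).dt.strftime("%Y-%m-%d")
    out.drop(columns=[c for c in ("u",) if c in out], inplace=True)
    out.to_csv(path, index=False)


def write_schema(path: str | Path) -> None:
    schema = {
        col: {"kind": kind, "unit": unit, "note": note}
        for col, (kind, unit, note) in COHORT_SCHEMA.items()
    }
    schema["__dosage_columns__"] = {
        "kind": "float",
        "unit": "alleles",
        "note": f"columns named {DOSAGE_PREFIX}<rsid>: imputed dosage in [0, 2]",
    }
    Path(path).write_text(json.dumps(schema, indent=2) + "\n")


def read_cohort(path: str | Path, *, drop_invalid: bool = False) -> pd.DataFrame:
    """Read and validate a cohort CSV against the published schema.

    Unknown columns get a warning; missing mandatory columns raise.  Rows with
    out-of-range values (negative ages or lags, dosages outside [0, 2], dmft
    outside [0, 20] or non-integer, invalid calendar dates, onset ages without
    caries) are collected into a validation report and the run refuses unless
    ``drop_invalid`` is set, in which case they are dropped.
    """
    df = pd.read_csv(path)
    mandatory = ["id", "vitd", "sample_date", "caries"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    known = set(COHORT_SCHEMA)
    unknown = [
        c for c in df.columns if c not in known and not c.startswith(DOSAGE_PREFIX)
    ]
    if unknown:
        logger.warning("ignoring unknown columns: %s", unknown)

    problems: list[tuple[int, str]] = []
    dates = pd.to_datetime(df["sample_date"], format="%Y-%m-%d", errors="coerce")
    for row in df.index[dates.isna() & df["sample_date"].notna()]:
        problems.append((row, f"invalid calendar date {df.at[row, 'sample_date']!r}"))
    df["sample_date"] = dates

    def check(col: str, bad: pd.Series, what: str) -> None:
        for row in df.index[bad.fillna(False)]:
            problems.append((row, f"{col}: {what} ({df.at[row, col]!r})"))

    for col in df.columns:
        if col.startswith(DOSAGE_PREFIX):
            check(col, (df[col] < 0) | (df[col] > 2), "dosage outside [0, 2]")
    if "vitd" in df:
        check("vitd", df["vitd"] < 0, "negative concentration")
    for col in ("age_at_measure", "lag_months", "onset_age"):
        if col in df:
            check(col, df[col] < 0, "negative value")
    if "dmft" in df:
        present = df["dmft"].notna()
        bad = present & (
            (df["dmft"] < 0) | (df["dmft"] > 20) | (df["dmft"] != df["dmft"].round())
        )
        check("dmft", bad, "outside [0, 20] or non-integer")
    if "onset_age" in df and "caries" in df:
        check("onset_age", df["onset_age"].notna() & (df["caries"] != 1),
              "onset age present without caries")

    if problems:
        report = "; ".join(f"row {r}: {msg}" for r, msg in problems[:20])
        if not drop_invalid:
            raise ValueError(
                f"{len(problems)} invalid values (pass drop_invalid=True to drop "
                f"the offending rows): {report}"
            )
        bad_rows = sorted({r for r, _ in problems})
        logger.warning("dropping %d invalid rows", len(bad_rows))
        df = df.drop(index=bad_rows).reset_index(drop=True)

    for col in ("sex", "maternal_education", "social_class"):
        if col in df:
            cats = COHORT_SCHEMA[col][0].split(":", 1)[1].split("|")
            df[col] = pd.Categorical(df[col], categories=cats, ordered=col != "sex")
    return df


# --------------------------------------------------------------------------
# the run
# --------------------------------------------------------------------------

_BINARY_OUTCOMES = ("caries", "ga", "clinical_caries")
_MR_OUTCOMES = ("caries", "ga", "early_onset")

_BALANCE_CONFOUNDERS = {
    "sex": "categorical",
    "maternal_education": "categorical",
    "social_class": "categorical",
    "age_at_measure": "continuous",
    "bmi": "continuous",
    "lag_months": "continuous",
}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages, writing one delimited report per stage.

    On a stage failure the manifest marks the stage failed and later stages
    are skipped; earlier outputs remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    echo = {
        "seed": config.seed,
        "ladder_variant": config.ladder_variant,
        "category_boundaries": list(config.category_boundaries),
        "bootstrap_reps": config.bootstrap_reps,
        "cohort_path": str(config.cohort_path) if config.cohort_path else None,
        "generator": _generator_echo(config.generator),
    }
    logger.info("run config: %s", echo)

    if config.generator is not None:
        cohort = generate_cohort(config.generator)
        snps = config.generator.snps
    else:
        cohort = read_cohort(config.cohort_path)
        snps = default_config().snps
    flow = participant_flow(cohort)
    manifest = RunManifest(config_echo=echo, version=__version__, flow=flow)

    stages = [
        ("cohort", _stage_cohort),
        ("score", _stage_score),
        ("season", _stage_season),
        ("observational", _stage_observational),
        ("mr", _stage_mr),
        ("validation", _stage_validation),
        ("power", _stage_power),
    ]
    ctx: dict = {"cohort": cohort, "snps": snps, "config": config, "out": out}
    failed = False
    for name, fn in stages:
        if failed:
            manifest.stages.append({"stage": name, "status": "skipped"})
            continue
        try:
            fn(ctx, manifest)
            manifest.stages.append({"stage": name, "status": "ok"})
            logger.info("stage %s: ok", name)
        except Exception as exc:
            manifest.stages.append({"stage": name, "status": f"failed: {exc}"})
            logger.error("stage %s failed: %s", name, exc)
            failed = True
    (out / "manifest.yaml").write_text(manifest.to_yaml())
    return manifest


def _generator_echo(gen: GeneratorConfig | None) -> dict | None:
    if gen is None:
        return None
    echo = dataclasses.asdict(gen)
    echo["snps"] = [dataclasses.asdict(s) for s in gen.snps]
    return json.loads(json.dumps(echo))  # plain-text-serializable types only


def _stage_cohort(ctx, manifest) -> None:
    write_cohort(ctx["cohort"], ctx["out"] / "cohort.csv")
    write_schema(ctx["out"] / "cohort.schema.json")


def _stage_score(ctx, manifest) -> None:
    cohort, snps = ctx["cohort"], ctx["snps"]
    weights = ctx["config"].weights or tuple(s.weight for s in snps)
    dosage_cols = [DOSAGE_PREFIX + s.id for s in snps]
    score = _scores.weighted_risk_score(cohort[dosage_cols], weights)
    cohort["risk_score"] = score.values
    strength = _scores.per_allele_association(score, cohort["vitd"])
    per_snp = _scores.per_snp_effects(cohort[dosage_cols], cohort["vitd"])
    pd.DataFrame(
        [{
            "r_squared": strength.r_squared,
            "f_statistic": strength.f_statistic,
            "slope_nmol_per_allele": strength.per_allele_effect,
            "n": strength.n,
        }]
    ).to_csv(ctx["out"] / "instrument_strength.csv", index=False)
    per_snp.to_csv(ctx["out"] / "per_snp_effects.csv", index=False)
    manifest.analysis_n["instrument"] = strength.n
    ctx["strength"] = strength


def _stage_season(ctx, manifest) -> None:
    cohort = ctx["cohort"]
    fit = _season.fit_seasonal(cohort["vitd"], cohort["sample_date"])
    cohort["vitd_adjusted"] = _season.deseasonalize(
        cohort["vitd"], cohort["sample_date"], fit
    )
    logger.info(
        "seasonal fit: intercept %.2f, amplitude %.2f nmol/L, phase %.3f rad",
        fit.intercept, fit.amplitude, fit.phase,
    )
    pd.DataFrame(
        [{
            "intercept": fit.intercept, "sin_coef": fit.sin_coef,
            "cos_coef": fit.cos_coef, "amplitude": fit.amplitude,
            "phase": fit.phase, "period_days": fit.period,
        }]
    ).to_csv(ctx["out"] / "seasonal_fit.csv", index=False)
    ctx["season_fit"] = fit


def _stage_observational(ctx, manifest) -> None:
    cohort, config = ctx["cohort"], ctx["config"]
    specs = _obs.ladder(config.ladder_variant)
    cases = cohort["caries"] == 1
    cohort["early_onset"] = np.nan
    if cases.sum() >= 3 and cohort.loc[cases, "onset_age"].notna().sum() >= 3:
        cohort.loc[cases, "early_onset"] = _obs.early_onset_flag(
            cohort.loc[cases, "onset_age"]
        )
    estimates = []
    for outcome in _BINARY_OUTCOMES + ("early_onset",):
        if outcome not in cohort or cohort[outcome].dropna().nunique() < 2:
            logger.warning("skipping outcome %r (absent or single-class)", outcome)
            continue
        ests = _obs.fit_logistic_ladder(
            cohort, outcome, specs, season_fit=ctx.get("season_fit")
        )
        estimates.extend(ests)
        manifest.analysis_n[f"observational_{outcome}"] = ests[0].n_used
    ctx["observational"] = estimates
    pd.DataFrame([e.as_dict() for e in estimates]).to_csv(
        ctx["out"] / "observational_ladder.csv", index=False
    )
    if "dmft" in cohort and cohort["dmft"].notna().sum() >= 50:
        zip_fit = _obs.fit_zip_severity(cohort["dmft"], cohort["vitd"])
        pd.DataFrame(
            [{
                "count_ratio_per_10": zip_fit.count_ratio_per_10,
                "ci_low": zip_fit.ci_low, "ci_high": zip_fit.ci_high,
                "p_value": zip_fit.p_value, "n": zip_fit.n_used,
                "zero_fraction_observed": zip_fit.zero_fraction_observed,
                "zero_fraction_poisson": zip_fit.zero_fraction_poisson,
            }]
        ).to_csv(ctx["out"] / "zip_severity.csv", index=False)
        manifest.analysis_n["zip_dmft"] = zip_fit.n_used
    cat = _obs.category_table(cohort)
    cat.table.assign(chi2=cat.chi2, p_value=cat.p_value).to_csv(
        ctx["out"] / "category_table.csv", index=False
    )


def _stage_mr(ctx, manifest) -> None:
    cohort, config = ctx["cohort"], ctx["config"]
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    iv_estimates = []
    for outcome in _MR_OUTCOMES:
        if outcome not in cohort or cohort[outcome].dropna().nunique() < 2:
            continue
        est = _mr.iv_logistic_smm(
            cohort[outcome], cohort["vitd"], cohort["risk_score"],
            n_boot=config.bootstrap_reps, seed=rng, outcome_tag=outcome,
        )
        iv_estimates.append(est)
        manifest.analysis_n[f"mr_{outcome}"] = est.n
    ctx["mr"] = iv_estimates
    report = _mr.mr_report(iv_estimates, ctx.get("observational", []))
    report.to_csv(ctx["out"] / "mr_report.csv", index=False)


def _stage_validation(ctx, manifest) -> None:
    cohort = ctx["cohort"]
    if {"clinical_caries", "caries"} <= set(cohort.columns):
        paired = cohort.dropna(subset=["clinical_caries", "caries"])
        if len(paired):
            tab = _val.cross_tabulate(
                paired["clinical_caries"], paired["caries"], paired["vitd"]
            )
            tab.counts.to_csv(ctx["out"] / "crosstab_counts.csv")
            if tab.vitd_summary is not None:
                tab.vitd_summary.to_csv(ctx["out"] / "crosstab_vitd.csv", index=False)
            correct = (paired["clinical_caries"] == paired["caries"]).astype(float)
            t, p = _val.misclassification_ttest(paired["vitd"], correct)
            pd.DataFrame(
                [{"fp_rate": tab.fp_rate, "fn_rate": tab.fn_rate,
                  "t_statistic": t, "p_value": p, "n": tab.total}]
            ).to_csv(ctx["out"] / "misclassification.csv", index=False)
            manifest.analysis_n["validation"] = tab.total
    for label, column in (("vitd", "vitd"), ("score", "risk_score")):
        values = cohort[column]
        if values.notna().sum() < 5:
            continue
        quintiles = _val.quintile_assign(values)
        balance = _val.balance_tests(cohort, quintiles, _BALANCE_CONFOUNDERS)
        balance.tests.to_csv(ctx["out"] / f"balance_{label}_tests.csv", index=False)
        balance.summaries.to_csv(ctx["out"] / f"balance_{label}_summary.csv", index=False)


def _stage_power(ctx, manifest) -> None:
    strength = ctx.get("strength")
    r2 = strength.r_squared if strength else 0.059
    spec = _power.PowerSpec(instrument_r2=r2)
    result = _power.mr_required_n(spec)
    pd.DataFrame(
        [{
            "required_n": result.required_n,
            "achieved_power": result.achieved_power,
            "alpha": spec.alpha, "target_power": spec.target_power,
            "instrument_r2": spec.instrument_r2, "causal_or": spec.causal_or,
            "outcome_prevalence": spec.outcome_prevalence,
        }]
    ).to_csv(ctx["out"] / "power.csv", index=False)
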