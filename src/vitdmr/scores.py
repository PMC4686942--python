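"""Weighted genetic risk score instrument and its strength diagnostics.

The instrument is a weighted sum of exposure-raising allele dosages.  Weights
are normalized to mean 1 (``w_i -> m * w_i / sum(w)`` for m SNPs) so the score
of m SNPs spans [0, 2m] — "between 0 and 6" for the three-variant score — and
is invariant under rescaling all weights by a common positive factor.

Strength is summarized by the ordinary-least-squares fit of 25(OH)D on the
score: per-weighted-allele slope (nmol/L), variance explained R^2, and the
single-regressor F statistic, which satisfies F = R^2 (n-2) / (1 - R^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_cohort import DOSAGE_PREFIX, SnpSpec

__all__ = [
    "RiskScore",
    "InstrumentStrength",
    "weighted_risk_score",
    "per_allele_association",
    "per_snp_effects",
    "expected_slope",
    "expected_r_squared",
]


@dataclass(frozen=True)
class RiskScore:
    """Per-participant weighted allele score plus the weights that built it."""

    values: pd.Series
    weights_raw: tuple[float, ...]
    weights_normalized: tuple[float, ...]

    @property
    def n_snps(self) -> int:
        return len(self.weights_raw)

    @property
    def max_score(self) -> float:
        return 2.0 * self.n_snps


@dataclass(frozen=True)
class InstrumentStrength:
    r_squared: float
    f_statistic: float
    per_allele_effect: float  # nmol/L per unit of score
    intercept: float
    slope_se: float
    n: int


def weighted_risk_score(dosages: pd.DataFrame, weights) -> RiskScore:
    """Combine SNP dosages into a mean-1-weight-normalized risk score.

    Participants missing any dosage get a missing score (no imputation,
    matching a complete-case analysis flow).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 1 or len(weights) != dosages.shape[1]:
        raise ValueError(
            f"need one weight per SNP column: got {len(weights)} weights "
            f"for {dosages.shape[1]} columns"
        )
    if np.any(weights < 0) or not np.all(np.isfinite(weights)):
        raise ValueError("weights must be finite and >= 0")
    total = weights.sum()
    if total == 0:
        raise ValueError("all-zero weights: score undefined")
    arr = dosages.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(arr) < 0 or np.nanmax(arr) > 2:
            raise ValueError("dosages must lie within [0, 2]")
    norm = len(weights) * weights / total
    values = pd.Series(arr @ norm, index=dosages.index, name="risk_score")
    values[np.isnan(arr).any(axis=1)] = np.nan
    return RiskScore(values=values, weights_raw=tuple(weights), weights_normalized=tuple(norm))


def _complete(x: pd.Series | np.ndarray, y: pd.Series | np.ndarray):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def per_allele_association(score: RiskScore | pd.Series, vitd) -> InstrumentStrength:
    """OLS of 25(OH)D on the score: slope, R^2 and single-regressor F."""
    values = score.values if isinstance(score, RiskScore) else score
    x, y = _complete(values, vitd)
    if len(x) < 3:
        raise ValueError("need at least 3 complete (score, vitd) pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate instrument: score is constant")
    fit = stats.linregress(x, y)
    r2 = fit.rvalue**2
    n = len(x)
    f = r2 * (n - 2) / (1.0 - r2) if r2 < 1.0 else np.inf
    return InstrumentStrength(
        r_squared=float(r2),
        f_statistic=float(f),
        per_allele_effect=float(fit.slope),
        intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
        n=n,
    )


def per_snp_effects(dosages: pd.DataFrame, vitd) -> pd.DataFrame:
    """Simple-regression slope of 25(OH)D on each SNP dosage separately.

    Monomorphic SNPs are flagged (``excluded=True``) with NaN estimates.
    """
    rows = []
    for col in dosages.columns:
        x, y = _complete(dosages[col], vitd)
        snp = col.removeprefix(DOSAGE_PREFIX)
        if len(x) < 3 or np.ptp(x) == 0:
            rows.append({"snp": snp, "slope": np.nan, "se": np.nan,
                         "p_value": np.nan, "n": len(x), "excluded": True})
            continue
        fit = stats.linregress(x, y)
        rows.append({"snp": snp, "slope": float(fit.slope), "se": float(fit.stderr),
                     "p_value": float(fit.pvalue), "n": len(x), "excluded": False})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# closed-form expectations (used as independent cross-checks)
# --------------------------------------------------------------------------

def expected_slope(snps) -> float:
    """Population OLS slope of exposure on the normalized score.

    With independent SNPs, cov(vitd, S) = sum(w~ beta 2pq) and
    var(S) = sum(w~^2 2pq), so the slope is their ratio.
    """
    snps = list(snps)
    total_w = sum(s.weight for s in snps)
    m = len(snps)
    num = sum((m * s.weight / total_w) * s.beta_exposure * s.het for s in snps)
    den = sum((m * s.weight / total_w) ** 2 * s.het for s in snps)
    return num / den


def expected_r_squared(snps: list[SnpSpec] | tuple[SnpSpec, ...], total_variance: float) -> float:
    """Population R^2 of exposure on the normalized score: cov^2/(varS varY)."""
    snps = list(snps)
    total_w = sum(s.weight for s in snps)
    m = len(snps)
    cov = sum((m * s.weight / total_w) * s.beta_exposure * s.het for s in snps)
    var_s = sum((m * s.weight / total_w) ** 2 * s.het for s in snps)
    return cov**2 / (var_s * total_variance)
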