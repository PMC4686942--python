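"""Sine-cosine seasonal adjustment of serum 25(OH)D.

A least-squares fit of vitd on sin(2*pi*t/period) and cos(2*pi*t/period)
(t = day of year, period 365.25 days by default; extra harmonics optional).
Deseasonalized values are residual + intercept, keeping the series on the
nmol/L scale and conserving the sample mean on the fitting data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_cohort import DAYS_PER_YEAR

__all__ = ["SeasonalFit", "fit_seasonal", "deseasonalize"]


@dataclass(frozen=True)
class SeasonalFit:
    intercept: float
    sin_coef: float
    cos_coef: float
    period: float = DAYS_PER_YEAR
    harmonics: tuple[tuple[float, float], ...] = ()  # (sin, cos) for harmonics >= 2
    #: sample mean of the seasonal component on the fitting data; subtracting
    #: it keeps deseasonalization mean-conserving even when the sampling
    #: window does not cover the year evenly
    seasonal_mean: float = 0.0

    @property
    def amplitude(self) -> float:
        return math.hypot(self.sin_coef, self.cos_coef)

    @property
    def phase(self) -> float:
        """Phase in (-pi, pi] such that the annual term is A*sin(wt + phase)."""
        if self.amplitude == 0:
            return 0.0
        phi = math.atan2(self.cos_coef, self.sin_coef)
        return phi if phi != -math.pi else math.pi

    def predict(self, day_of_year: np.ndarray) -> np.ndarray:
        t = np.asarray(day_of_year, dtype=float)
        w = 2.0 * math.pi / self.period
        pred = self.intercept + self.sin_coef * np.sin(w * t) + self.cos_coef * np.cos(w * t)
        for k, (s, c) in enumerate(self.harmonics, start=2):
            pred += s * np.sin(k * w * t) + c * np.cos(k * w * t)
        return pred


def _day_of_year(sample_dates) -> np.ndarray:
    dates = pd.to_datetime(pd.Series(sample_dates))
    return dates.dt.dayofyear.to_numpy(dtype=float)


def fit_seasonal(vitd, sample_dates, *, period: float = DAYS_PER_YEAR,
                 n_harmonics: int = 1) -> SeasonalFit:
    """Least-squares seasonal fit on complete (vitd, date) pairs."""
    y = np.asarray(vitd, dtype=float)
    t = _day_of_year(sample_dates)
    keep = np.isfinite(y) & np.isfinite(t)
    y, t = y[keep], t[keep]
    if len(y) < 1 + 2 * n_harmonics:
        raise ValueError("too few complete (vitd, date) pairs for a seasonal fit")
    if np.unique(t).size < 2:
        raise ValueError("season unidentifiable: all sample dates share one day-of-year")
    w = 2.0 * math.pi / period
    cols = [np.ones_like(t)]
    for k in range(1, n_harmonics + 1):
        cols += [np.sin(k * w * t), np.cos(k * w * t)]
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    harmonics = tuple(
        (float(beta[1 + 2 * k]), float(beta[2 + 2 * k])) for k in range(1, n_harmonics)
    )
    fit = SeasonalFit(
        intercept=float(beta[0]),
        sin_coef=float(beta[1]),
        cos_coef=float(beta[2]),
        period=period,
        harmonics=harmonics,
    )
    seasonal_mean = float(np.mean(fit.predict(t) - fit.intercept))
    return SeasonalFit(
        intercept=fit.intercept,
        sin_coef=fit.sin_coef,
        cos_coef=fit.cos_coef,
        period=period,
        harmonics=harmonics,
        seasonal_mean=seasonal_mean,
    )


def deseasonalize(vitd, sample_dates, fit: SeasonalFit) -> pd.Series:
    """Remove the fitted seasonal component, keeping the nmol/L location.

    adjusted = vitd - (seasonal component - its fitting-sample mean), so the
    sample mean is conserved on the fitting data; missing values or dates
    propagate to missing adjusted values.
    """
    y = pd.Series(np.asarray(vitd, dtype=float))
    t = _day_of_year(sample_dates)
    adjusted = y.to_numpy() - (fit.predict(t) - fit.intercept) + fit.seasonal_mean
    adjusted[~(np.isfinite(y.to_numpy()) & np.isfinite(t))] = np.nan
    index = vitd.index if isinstance(vitd, pd.Series) else None
    return pd.Series(adjusted, index=index, name="vitd_adjusted")
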