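"""Misclassification validation and confounder-balance diagnostics.

Questionnaire-reported caries status is validated against the clinical
examination ("gold standard"): a 2x2 cross-tabulation with per-cell 25(OH)D
medians, false-positive/false-negative rates relative to the questionnaire
classification, and a t-test comparing mean 25(OH)D between correctly and
incorrectly classified participants.  Confounder balance is examined across
empirical quintiles of 25(OH)D or of the genetic score with one-way ANOVA
F-tests (continuous) and Pearson chi-square tests (categorical) — on genetic
quintiles the confounders should look balanced, which is the identifying
assumption of the MR design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CrossTab",
    "BalanceTable",
    "cross_tabulate",
    "misclassification_ttest",
    "quintile_assign",
    "balance_tests",
    "prevalence",
]


def prevalence(cases: int, total: int) -> float:
    """Prevalence in percent from case and total counts."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= cases <= total:
        raise ValueError("cases must lie in [0, total]")
    return 100.0 * cases / total


@dataclass(frozen=True)
class CrossTab:
    counts: pd.DataFrame        # 2x2 + margins; rows clinical, columns questionnaire
    fp_rate: float              # questionnaire cases without clinical caries
    fn_rate: float              # questionnaire controls with clinical caries
    vitd_summary: pd.DataFrame | None  # median (IQR) of 25(OH)D per cell

    @property
    def total(self) -> int:
        return int(self.counts.loc["total", "total"])


def _median_iqr(values: np.ndarray) -> dict:
    if len(values) == 0:
        return {"median": np.nan, "q1": np.nan, "q3": np.nan, "n": 0}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"median": med, "q1": q1, "q3": q3, "n": len(values)}


def cross_tabulate(clinical, questionnaire, vitd=None) -> CrossTab:
    """Clinical x questionnaire 2x2 agreement table with misclassification rates.

    fp_rate = P(no clinical caries | questionnaire case); fn_rate =
    P(clinical caries | questionnaire control).  With zero questionnaire cases
    (or controls) the corresponding rate is undefined and reported as NaN.
    """
    c = np.asarray(clinical, dtype=float)
    q = np.asarray(questionnaire, dtype=float)
    keep = np.isfinite(c) & np.isfinite(q)
    if vitd is not None:
        v = np.asarray(vitd, dtype=float)
    c, q = c[keep], q[keep]
    if len(c) == 0:
        raise ValueError("no paired non-missing clinical/questionnaire flags")
    cells = {
        (ci, qi): int(np.sum((c == ci) & (q == qi))) for ci in (0, 1) for qi in (0, 1)
    }
    counts = pd.DataFrame(
        {
            "no caries": [cells[(0, 0)], cells[(1, 0)]],
            "caries": [cells[(0, 1)], cells[(1, 1)]],
        },
        index=pd.Index(["no caries", "caries"], name="clinical"),
    )
    counts.columns.name = "questionnaire"
    counts["total"] = counts.sum(axis=1)
    counts.loc["total"] = counts.sum(axis=0)

    q_cases = cells[(0, 1)] + cells[(1, 1)]
    q_controls = cells[(0, 0)] + cells[(1, 0)]
    fp = cells[(0, 1)] / q_cases if q_cases else np.nan
    fn = cells[(1, 0)] / q_controls if q_controls else np.nan

    summary = None
    if vitd is not None:
        v = v[keep]
        rows = []
        for ci, clab in ((0, "no caries"), (1, "caries"), (None, "total")):
            for qi, qlab in ((0, "no caries"), (1, "caries"), (None, "total")):
                mask = np.ones(len(c), dtype=bool)
                if ci is not None:
                    mask &= c == ci
                if qi is not None:
                    mask &= q == qi
                vals = v[mask & np.isfinite(v)]
                rows.append({"clinical": clab, "questionnaire": qlab, **_median_iqr(vals)})
        summary = pd.DataFrame(rows)
    return CrossTab(counts=counts, fp_rate=fp, fn_rate=fn, vitd_summary=summary)


def misclassification_ttest(vitd, correctly_classified, *, welch: bool = False):
    """Two-sample t-test of mean 25(OH)D, correctly vs incorrectly classified.

    Pooled-variance by default; ``welch=True`` drops the equal-variance
    assumption.  Returns ``(t, p)``.
    """
    v = np.asarray(vitd, dtype=float)
    flag = np.asarray(correctly_classified, dtype=float)
    keep = np.isfinite(v) & np.isfinite(flag)
    a = v[keep & (flag == 1)]
    b = v[keep & (flag == 0)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each classification group needs n >= 2")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def quintile_assign(values) -> pd.Series:
    """Empirical quintile labels 1-5 with cutpoints at the 20/40/60/80 percentiles.

    Ties at a cutpoint go to the lower quintile, so a discrete score yields
    unequal (but deterministic, order-independent) group sizes.
    """
    v = pd.Series(values, dtype=float)
    nonmiss = v.dropna().to_numpy()
    if len(nonmiss) < 5:
        raise ValueError("need at least 5 non-missing values")
    if np.ptp(nonmiss) == 0:
        raise ValueError("constant vector: quintiles undefined")
    cuts = np.quantile(nonmiss, [0.2, 0.4, 0.6, 0.8])
    arr = v.to_numpy()
    labels = 1.0 + np.nansum([arr > c for c in cuts], axis=0)
    labels[~np.isfinite(arr)] = np.nan
    return pd.Series(labels, index=v.index, name="quintile")


@dataclass(frozen=True)
class BalanceTable:
    summaries: pd.DataFrame  # per confounder x quintile summary statistics
    tests: pd.DataFrame      # per confounder: test, statistic, p, warning
    n_per_quintile: pd.Series


def balance_tests(
    cohort: pd.DataFrame,
    quintiles: pd.Series,
    confounders: dict[str, str],
) -> BalanceTable:
    """Confounder summaries and tests across quintile strata.

    ``confounders`` maps column name to ``"continuous"`` (means/SDs, one-way
    ANOVA F) or ``"categorical"`` (percentages, Pearson chi-square).  A
    chi-square with expected counts below 1 in over 20% of cells gets a
    warning flag.  Skewed continuous confounders are tested on the raw scale
    (Kruskal-Wallis available via ``"kruskal"``).
    """
    q = pd.Series(quintiles, dtype=float)
    levels = [1, 2, 3, 4, 5]
    summaries = []
    tests = []
    for name, kind in confounders.items():
        col = cohort[name]
        keep = q.notna() & col.notna()
        groups = [col[keep & (q == lev)] for lev in levels]
        warning = ""
        if kind in ("continuous", "kruskal"):
            arrays = [g.to_numpy(float) for g in groups if len(g) > 1]
            if kind == "continuous":
                if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
                    stat, p = 0.0, 1.0
                else:
                    stat, p = stats.f_oneway(*arrays)
                test = "F"
            else:
                stat, p = stats.kruskal(*arrays)
                test = "kruskal"
            for lev, g in zip(levels, groups):
                summaries.append(
                    {"confounder": name, "quintile": lev, "level": "",
                     "mean": float(g.mean()) if len(g) else np.nan,
                     "sd": float(g.std(ddof=1)) if len(g) > 1 else np.nan,
                     "pct": np.nan, "n": len(g)}
                )
        elif kind == "categorical":
            tab = pd.crosstab(col[keep], q[keep])
            tab = tab.loc[tab.sum(axis=1) > 0, tab.sum(axis=0) > 0]
            stat, p, _, expected = stats.chi2_contingency(tab, correction=False)
            if np.mean(expected < 1) > 0.2:
                warning = "expected cell counts < 1 in > 20% of cells"
            test = "chi2"
            for lev, g in zip(levels, groups):
                vc = g.value_counts()
                for level_name, count in vc.items():
                    summaries.append(
                        {"confounder": name, "quintile": lev, "level": str(level_name),
                         "mean": np.nan, "sd": np.nan,
                         "pct": 100.0 * count / len(g) if len(g) else np.nan,
                         "n": int(count)}
                    )
        else:
            raise ValueError(f"confounder {name!r}: unknown kind {kind!r}")
        if warning:
            warnings.warn(f"{name}: {warning}", UserWarning, stacklevel=2)
        tests.append(
            {"confounder": name, "test": test, "statistic": float(stat),
             "p_value": float(p), "warning": warning}
        )
    n_per = q.dropna().astype(int).value_counts().reindex(levels, fill_value=0).sort_index()
    return BalanceTable(
        summaries=pd.DataFrame(summaries),
        tests=pd.DataFrame(tests),
        n_per_quintile=n_per.rename("n"),
    )
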