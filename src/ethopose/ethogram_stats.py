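"""Time budgets and non-parametric behavioral statistics.

A time budget is the fraction of observed time an individual allocates
to each ethogram category; seconds in which the animal was invisible
("Out of Sight"/"Out of View") carry no behavioral information and are
excluded before normalisation.  Between-period and between-individual
comparisons use the study's non-parametric toolkit:

* Mann-Whitney U on daily behavior proportions (medians/ranks),
* Pearson chi-square on second-count contingency tables (categorical
  distributions), and
* Fligner-Killeen on the dispersion of daily proportions.

Daily values (one proportion per observation day) are the sampling unit
throughout, which dampens within-day temporal autocorrelation.  The
statistics themselves are standard and are delegated to scipy; this
module fixes the study conventions (tie and continuity corrections,
contingency design, exclusion rules) behind one surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import AnnotationSeries
from .evaluation import OUT_OF_VIEW, UNSEEN_CATEGORY

#: Categories that mean "animal not observable"; excluded from budgets.
DEFAULT_EXCLUDE = frozenset({"Out of Sight", OUT_OF_VIEW, "Not Labeled", UNSEEN_CATEGORY})


class NoObservedTimeError(ValueError):
    """Every second of the series fell in an excluded category."""


@dataclass
class TimeBudget:
    individual: str
    period: str
    proportions: pd.Series  # category -> fraction of observed time
    observed_s: int

    def __post_init__(self) -> None:
        total = float(self.proportions.sum())
        if self.observed_s > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"budget proportions sum to {total}, not 1")


@dataclass
class Chi2Result:
    chi2: float
    df: int
    p: float
    expected: np.ndarray


def time_budget(
    series: AnnotationSeries,
    exclude: Iterable[str] = DEFAULT_EXCLUDE,
    period: str = "",
) -> TimeBudget:
    """Proportion of observed time per category, after exclusions.

    Raises :class:`NoObservedTimeError` when nothing remains after
    removing the excluded categories.
    """
    exclude = set(exclude)
    kept = series.labels[~series.labels.isin(exclude)]
    if len(kept) == 0:
        raise NoObservedTimeError(
            f"no observed time for {series.individual!r} after exclusions"
        )
    categories = [c for c in series.categories if c not in exclude]
    counts = kept.value_counts()
    props = pd.Series(
        [counts.get(c, 0) / len(kept) for c in categories], index=categories, dtype=float
    )
    return TimeBudget(
        individual=series.individual,
        period=period,
        proportions=props,
        observed_s=int(len(kept)),
    )


def daily_table(
    annotations: pd.DataFrame, exclude: Iterable[str] = DEFAULT_EXCLUDE
) -> pd.DataFrame:
    """Tidy per-day behavior proportions from raw per-second annotations.

    ``annotations`` has columns (individual, period, day, time_s,
    behavior); the result has one row per (individual, period, day,
    category) with the category's proportion of that day's observed
    time.  Days with no observable seconds are dropped.
    """
    exclude = set(exclude)
    kept = annotations[~annotations["behavior"].isin(exclude)]
    rows = []
    for (individual, period, day), grp in kept.groupby(
        ["individual", "period", "day"], sort=True
    ):
        total = len(grp)
        for category, n in grp["behavior"].value_counts().items():
            rows.append(
                {
                    "individual": individual,
                    "period": period,
                    "day": day,
                    "category": category,
                    "proportion": n / total,
                }
            )
    return pd.DataFrame(rows, columns=["individual", "period", "day", "category", "proportion"])


def daily_values(
    table: pd.DataFrame, individual: str, period: str, category: str
) -> np.ndarray:
    """Per-day proportions for one individual/period/category cell.

    Days in which the category was never observed contribute an
    explicit 0 so every observed day yields a value.
    """
    cell = table[(table["individual"] == individual) & (table["period"] == period)]
    if cell.empty:
        raise ValueError(f"no rows for {individual!r} in period {period!r}")
    days = sorted(cell["day"].unique())
    sub = cell[cell["category"] == category].set_index("day")["proportion"]
    return np.array([float(sub.get(d, 0.0)) for d in days])


def daily_medians(
    table: pd.DataFrame, individual: str, period: str, category: str
) -> float:
    """Median of the per-day proportions (mean of the central pair for even counts)."""
    return float(np.median(daily_values(table, individual, period, category)))


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact: bool = False,
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U for x, p-value).

    U counts pairs in which x exceeds y (ties count one half).  The
    default p-value uses the normal approximation with tie and
    continuity corrections, appropriate for small daily samples by
    software convention; set ``exact=True`` for the exact permutation
    null (only valid without ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def chi_square_counts(
    counts_a: Sequence[float], counts_b: Sequence[float]
) -> Chi2Result:
    """Pearson chi-square on the 2 x k contingency table of category counts.

    Compares the full categorical distribution of two periods (or
    individuals); df = k - 1.  Expected counts are returned so low-count
    cells can be checked.  A single shared category leaves 0 degrees of
    freedom and raises ``ValueError``.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count vectors must be 1-D and share their categories")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("both count vectors must have positive totals")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("chi-square undefined with a single category (df = 0)")
    chi2, p, df, expected = stats.chi2_contingency(np.vstack([a, b]), correction=False)
    return Chi2Result(chi2=float(chi2), df=int(df), p=float(p), expected=expected)


def chi_square_pairwise(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    categories: Sequence[str],
) -> pd.DataFrame:
    """Per-behavior 2 x 2 chi-square (category vs. all others), one row each.

    The one-vs-rest design localises which behavior drives a
    distributional difference; raw (unadjusted) p-values are reported.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    rows = []
    for i, cat in enumerate(categories):
        table = np.array(
            [[a[i], a.sum() - a[i]], [b[i], b.sum() - b[i]]], dtype=float
        )
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            rows.append({"category": cat, "chi2": np.nan, "df": 1, "p": np.nan})
            continue
        chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
        rows.append({"category": cat, "chi2": float(chi2), "df": int(df), "p": float(p)})
    return pd.DataFrame(rows)


def fligner_killeen(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Fligner-Killeen test of equal dispersion across groups.

    Rank-based and robust to non-normality: each group is centered at
    its median, pooled absolute deviations are ranked and transformed
    with normal scores, and the statistic is referred to chi-square with
    k - 1 degrees of freedom.  Returns (statistic, df, p).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs at least two values")
    stat, p = stats.fligner(*arrays)
    return float(stat), len(arrays) - 1, float(p)


def adjust_pvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; raw p is the default
    reporting convention here)."""
    return stats.false_discovery_control(np.asarray(pvalues, dtype=float), method="bh")
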