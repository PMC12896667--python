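"""Agreement between automated and manual behavior annotation.

Two complementary views are provided.  At the per-second level, a
multi-class confusion matrix (predicted rows x manual columns) and the
one-vs-rest metrics derived from it: precision, accuracy, sensitivity,
specificity and the True Skill Statistic

    TSS = sensitivity + specificity - 1,

which is 1 for a perfect classifier, 0 for a random one and negative
when predictions are worse than chance.  At the time-budget level,
Kendall's coefficient of concordance W measures how similarly two (or
more) raters rank the cumulative durations of the behavior categories,
with the large-sample chi-square approximation

    chi2 = m (n - 1) W   on  n - 1  degrees of freedom,

for m raters ranking n items.  Ties are handled with mid-ranks and the
tie-corrected denominator.

The manual category "Out of View" and the automated "Not Labeled" both
mean "no behavior could be scored for that second"; they are paired as
a single axis category when the confusion matrix is built.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import (
    AUTO_CATEGORIES,
    FORAGING,
    LOCOMOTION,
    LYING,
    NOT_LABELED,
    STANDING,
    AnnotationSeries,
)

OUT_OF_VIEW = "Out of View"

#: Joint axis category pairing manual Out of View/Out of Sight with the
#: classifier's Not Labeled.
UNSEEN_CATEGORY = "Out of View/Not Labeled"

#: Default label harmonisation applied to both axes of the confusion matrix.
DEFAULT_CATEGORY_MAP = {
    NOT_LABELED: UNSEEN_CATEGORY,
    OUT_OF_VIEW: UNSEEN_CATEGORY,
    "Out of Sight": UNSEEN_CATEGORY,
}

#: Axis order used by default for manual-vs-automated comparison.
EVAL_CATEGORIES = (STANDING, LYING, FORAGING, LOCOMOTION, UNSEEN_CATEGORY)

METRIC_NAMES = ("precision", "accuracy", "sensitivity", "specificity", "tss")


@dataclass
class ConfusionMatrix:
    """Predicted-by-manual count matrix over a shared category axis."""

    categories: tuple[str, ...]
    counts: np.ndarray  # rows = predicted, columns = manual

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.categories)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.categories), columns=list(self.categories))


@dataclass
class ConcordanceResult:
    """Kendall's W with its chi-square approximation."""

    W: float
    chi2: float
    df: int
    p: float
    m: int
    n: int


def build_confusion(
    manual: AnnotationSeries,
    predicted: AnnotationSeries,
    category_map: dict[str, str] | None = None,
    categories: tuple[str, ...] | None = None,
) -> ConfusionMatrix:
    """Count predicted-vs-manual labels over the co-observed seconds.

    ``category_map`` renames raw labels onto the shared axis before
    counting (by default it merges Out of View / Out of Sight / Not
    Labeled into one category).  Raises ``ValueError`` when the two
    series share no seconds.
    """
    if category_map is None:
        category_map = DEFAULT_CATEGORY_MAP
    common = manual.labels.index.intersection(predicted.labels.index)
    if len(common) == 0:
        raise ValueError("manual and predicted series share no seconds")
    man = manual.labels.loc[common].map(lambda c: category_map.get(c, c))
    pred = predicted.labels.loc[common].map(lambda c: category_map.get(c, c))
    if categories is None:
        mapped_default = [category_map.get(c, c) for c in AUTO_CATEGORIES]
        seen = list(dict.fromkeys(list(mapped_default) + sorted(set(man) | set(pred))))
        categories = tuple(seen)
    index = {c: i for i, c in enumerate(categories)}
    unknown = (set(man) | set(pred)) - set(categories)
    if unknown:
        raise ValueError(f"labels outside category axis: {sorted(unknown)}")
    counts = np.zeros((len(categories), len(categories)), dtype=np.int64)
    for p_lab, m_lab in zip(pred, man):
        counts[index[p_lab], index[m_lab]] += 1
    return ConfusionMatrix(categories=tuple(categories), counts=counts)


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest performance metrics per category.

    TP is the diagonal entry, FP the rest of the predicted row, FN the
    rest of the manual column, TN everything else.  Undefined ratios
    (0/0) are reported as NaN, never silently as 0.
    """
    total = cm.total
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    fp = counts.sum(axis=1) - tp
    fn = counts.sum(axis=0) - tp
    tn = total - tp - fp - fn

    def ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        return out

    precision = ratio(tp, tp + fp)
    sensitivity = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    accuracy = (tp + tn) / total
    tss = sensitivity + specificity - 1.0
    return pd.DataFrame(
        {
            "precision": precision,
            "accuracy": accuracy,
            "sensitivity": sensitivity,
            "specificity": specificity,
            "tss": tss,
        },
        index=list(cm.categories),
    )


def cumulative_budget(
    series: AnnotationSeries, categories: tuple[str, ...] | None = None
) -> pd.Series:
    """Seconds spent in each category (cumulative duration vector)."""
    categories = categories or series.categories
    counts = series.labels.value_counts()
    return pd.Series(
        [int(counts.get(c, 0)) for c in categories], index=list(categories), dtype=np.int64
    )


def _tie_correction(row_ranks: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of one rater's ranks."""
    _, tie_counts = np.unique(row_ranks, return_counts=True)
    return float(np.sum(tie_counts.astype(float) ** 3 - tie_counts))


def kendalls_w(durations: np.ndarray) -> ConcordanceResult:
    """Kendall's coefficient of concordance for an m x n rating matrix.

    Rows are raters (e.g. manual and automated scoring), columns the
    items being ranked (behavior categories by cumulative duration).
    Mid-ranks are used for ties; the tie-corrected formula is

        W = 12 S / (m^2 (n^3 - n) - m sum_j T_j)

    with S the sum of squared deviations of the item rank-sums from
    their mean and T_j = sum (t^3 - t) over tie groups of rater j.
    Significance uses chi2 = m (n-1) W on n-1 degrees of freedom.
    """
    data = np.asarray(durations, dtype=float)
    if data.ndim != 2:
        raise ValueError("durations must be a 2-D raters x items matrix")
    m, n = data.shape
    if m < 2 or n < 2:
        raise ValueError("Kendall's W needs at least 2 raters and 2 items")
    ranks = np.vstack([stats.rankdata(row) for row in data])
    rank_sums = ranks.sum(axis=0)
    s = float(np.sum((rank_sums - rank_sums.mean()) ** 2))
    ties = sum(_tie_correction(row) for row in ranks)
    denom = m * m * (n**3 - n) - m * ties
    if denom <= 0:
        raise ValueError("Kendall's W undefined: every rater ranks all items as tied")
    w = 12.0 * s / denom
    return concordance_from_w(w, m=m, n=n)


def concordance_from_w(w: float, m: int, n: int) -> ConcordanceResult:
    """Chi-square statistic and p-value for a known W with m raters, n items."""
    if not 0.0 <= w <= 1.0 + 1e-12:
        raise ValueError(f"W must lie in [0, 1], got {w}")
    chi2 = m * (n - 1) * w
    df = n - 1
    p = float(stats.chi2.sf(chi2, df))
    return ConcordanceResult(W=float(w), chi2=float(chi2), df=int(df), p=p, m=int(m), n=int(n))
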