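"""Welch unequal-variance comparisons shared by the imaging and qPCR modules.

The package reports group contrasts with Welch's t-test (the two-sample
t-test that does not pool variances, with Welch–Satterthwaite degrees of
freedom) and the usual significance-star convention: ``*`` for p < 0.05,
``**`` for p < 0.01, ``***`` for p < 0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = ["GroupComparison", "welch_compare_values", "significance_stars"]

_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float | None) -> str:
    """Map a p-value to the star annotation used in figure captions."""
    if p is None or math.isnan(p):
        return ""
    for threshold, stars in _STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group Welch comparison.

    ``p_value`` is ``None`` when either group has fewer than two
    observations; the mean difference is still reported so single-field
    contrasts are not silently dropped.
    """

    group_labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sds: tuple[float, float]
    mean_difference: float
    t_statistic: float | None
    df: float | None
    p_value: float | None
    alternative: str = "two-sided"
    stars: str = field(default="")
    computable: bool = True

    @property
    def significant(self) -> bool:
        return self.p_value is not None and self.p_value < 0.05


def welch_compare_values(
    a,
    b,
    labels: tuple[str, str] = ("A", "B"),
    alternative: str = "two-sided",
) -> GroupComparison:
    """Welch t-test of group ``a`` against group ``b``.

    ``alternative='greater'`` tests the one-sided hypothesis mean(a) >
    mean(b).  Degenerate inputs follow explicit conventions: with zero
    variance in both groups and equal means the statistic is 0 and p = 1;
    with fewer than two values on either side only the mean difference is
    reported (``computable=False``).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("groups must be 1-D value vectors")
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs at least one value")

    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a = float(a.std(ddof=1)) if a.size > 1 else float("nan")
    sd_b = float(b.std(ddof=1)) if b.size > 1 else float("nan")
    diff = mean_a - mean_b

    base = dict(
        group_labels=labels,
        n=(int(a.size), int(b.size)),
        means=(mean_a, mean_b),
        sds=(sd_a, sd_b),
        mean_difference=diff,
        alternative=alternative,
    )
    if a.size < 2 or b.size < 2:
        return GroupComparison(
            t_statistic=None, df=None, p_value=None, computable=False, **base
        )

    if sd_a == 0.0 and sd_b == 0.0:
        # Welch statistic is 0/0; identical constant groups are called null.
        if mean_a == mean_b:
            return GroupComparison(
                t_statistic=0.0, df=float(a.size + b.size - 2), p_value=1.0,
                stars=significance_stars(1.0), **base,
            )
        p = 0.0 if (alternative == "two-sided" or (alternative == "greater") == (diff > 0)) else 1.0
        return GroupComparison(
            t_statistic=math.copysign(math.inf, diff),
            df=float(a.size + b.size - 2), p_value=p,
            stars=significance_stars(p), **base,
        )

    res = _sps.ttest_ind(a, b, equal_var=False, alternative=alternative)
    p = float(res.pvalue)
    return GroupComparison(
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=p,
        stars=significance_stars(p),
        **base,
    )
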