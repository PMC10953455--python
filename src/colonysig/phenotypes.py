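"""Phenotype-level statistics for reproductive queues.

Foraging effort from census records, the arcsine-square-root transform,
the regression of transformed effort on queue rank, the paired
pre/post-manipulation Wilcoxon test, and proportional brood removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "BroodRemovalPlan",
    "arcsine_sqrt",
    "brood_removal",
    "foraging_effort",
    "promotion_change_test",
    "rank_effort_regression",
    "read_census",
]


def read_census(path) -> pd.DataFrame:
    """Census CSV: individual_id, timestamp (ISO-8601), on_nest (0/1)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if df.duplicated(["individual_id", "timestamp"]).any():
        raise ValueError("duplicate timestamps for an individual")
    df["on_nest"] = df["on_nest"].astype(bool)
    return df


def foraging_effort(records) -> float:
    """Proportion of censuses with the individual off the nest.

    ``records`` is an iterable of booleans (on_nest flags) or a
    DataFrame with an ``on_nest`` column; censuses are pooled.
    """
    if isinstance(records, pd.DataFrame):
        on_nest = records["on_nest"].to_numpy(dtype=bool)
    else:
        on_nest = np.asarray([bool(r) for r in records])
    if on_nest.size == 0:
        raise ValueError("no census records")
    return float(np.mean(~on_nest))


def arcsine_sqrt(p):
    """arcsin(sqrt(p)) variance-stabilizing transform for proportions."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


@dataclass
class RankEffortFit:
    slope: float
    slope_se: float
    p: float
    r_squared: float
    intercept: float

    def __iter__(self):  # (slope, SE, p, R2) unpacking
        return iter((self.slope, self.slope_se, self.p, self.r_squared))


def rank_effort_regression(metadata: pd.DataFrame, rank_col: str = "rank_pre",
                           effort_col: str = "effort_pre") -> RankEffortFit:
    """OLS of arcsine-sqrt-transformed foraging effort on integer rank.

    Two-sided t test on the slope.  Requires >= 3 individuals spanning
    >= 2 ranks.
    """
    df = metadata[[rank_col, effort_col]].dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 individuals")
    rank = df[rank_col].to_numpy(dtype=float)
    if np.unique(rank).size < 2:
        raise ValueError("rank is constant; slope undefined")
    y = arcsine_sqrt(df[effort_col].to_numpy(dtype=float))
    X = sm.add_constant(rank)
    fit = sm.OLS(y, X).fit()
    return RankEffortFit(
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        r_squared=float(fit.rsquared),
        intercept=float(fit.params[0]),
    )


def promotion_change_test(pre_effort, post_effort):
    """Two-sided Wilcoxon signed-rank test on per-individual change.

    Zeros are dropped (Wilcoxon convention), ties get mid-ranks; the
    exact distribution is used for n <= 25, the normal approximation
    with continuity correction above.  Returns (W, p, mean_change,
    sd_change); all-zero changes give p = 1 by convention.
    """
    pre = np.asarray(pre_effort, dtype=float)
    post = np.asarray(post_effort, dtype=float)
    if pre.shape != post.shape or pre.size == 0:
        raise ValueError("need equal-length non-empty paired vectors")
    change = post - pre
    mean_change = float(np.mean(change))
    sd_change = float(np.std(change, ddof=1)) if change.size > 1 else 0.0
    nz = change[change != 0.0]
    if nz.size == 0:
        return 0.0, 1.0, mean_change, sd_change
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(nz, zero_method="wilcox", correction=(method == "approx"),
                         alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0)), mean_change, sd_change


@dataclass
class BroodRemovalPlan:
    """Proportional brood removal after taking R of N adults: R/N of each
    feeding-dependent brood category is removed (round half to even);
    pupae, which need no feeding, are never touched."""

    R: int
    N: int
    brood_counts: dict
    removal_counts: dict

    def __post_init__(self):
        if not 0 <= self.R <= self.N or self.N < 1:
            raise ValueError("need 0 <= R <= N and N >= 1")
        for cat, removed in self.removal_counts.items():
            if removed > self.brood_counts.get(cat, 0):
                raise ValueError(f"removal exceeds count for {cat}")
        if self.removal_counts.get("pupae", 0) != 0:
            raise ValueError("pupae are never removed")


def brood_removal(R: int, N: int, brood_counts: dict) -> BroodRemovalPlan:
    """Build the removal plan: per-category removal = round-half-even
    of R/N x count, pupae exempt."""
    if N < 1 or not 0 <= R <= N:
        raise ValueError("need 0 <= R <= N and N >= 1")
    removal = {}
    for cat, count in brood_counts.items():
        if cat == "pupae":
            removal[cat] = 0
        else:
            # numpy rint rounds half to even
            removal[cat] = int(min(np.rint(R / N * count), count))
    return BroodRemovalPlan(R=R, N=N, brood_counts=dict(brood_counts), removal_counts=removal)
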