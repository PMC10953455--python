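"""Residualization decomposition for collinear rank and foraging effort.

Queue rank and foraging effort are strongly collinear, so their
"independent" expression effects are separated by fitting two additive
NB-GLMs: one with effort plus the residuals of rank regressed on effort
(the residual coefficient is the rank effect net of effort), and the
mirrored model with rank plus the residuals of effort on rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .de import DEResults, NBExpressionModel, filter_low_expression

__all__ = ["ResidualCovariate", "decomposed_de", "residualize"]


@dataclass
class ResidualCovariate:
    """OLS residuals of y on x, usable as a design covariate.

    Residuals are mean-zero and exactly uncorrelated with x (to
    numerical precision), which is what makes the decomposition an
    orthogonal split of the shared signal.
    """

    name: str
    values: np.ndarray
    regressed: str  # "y ~ x" provenance
    slope: float
    intercept: float

    def __post_init__(self):
        if abs(float(np.mean(self.values))) > 1e-8:
            raise ValueError("residuals must be centred")


def residualize(x, y, name: str = "residual") -> ResidualCovariate:
    """Residuals of ``y`` regressed on ``x`` (with intercept).

    Requires non-constant ``x`` and equal lengths >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of size >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; residualization undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return ResidualCovariate(
        name=name,
        values=np.asarray(fit.resid),
        regressed="y ~ x",
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
    )


def decomposed_de(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    theta: float = 0.0,
    rank_col: str = "rank_post",
    effort_col: str = "foraging_effort",
    exclude_reproductives: bool = True,
    grouping_col: str = "rank_pre",
    filter_low: bool = True,
    shrink_dispersion: bool = True,
) -> tuple[DEResults, DEResults]:
    """The two-arm residualization decomposition.

    Arm one fits expression ~ effort + resid(rank ~ effort) and tests
    the residual coefficient: genes significant there respond to rank
    independent of effort.  Arm two fits expression ~ rank +
    resid(effort ~ rank) and tests its residual: effort independent of
    rank.  Returns (rank_residual_results, effort_residual_results).

    By default reproductives are excluded so the decomposition acts on
    within-queue variation only.
    """
    meta = metadata.loc[list(counts.columns)].copy()
    if exclude_reproductives:
        keep = meta["role"] != "reproductive"
        meta = meta[keep]
        counts = counts[meta.index]
    rank = meta[rank_col].to_numpy(dtype=float)
    effort = meta[effort_col].to_numpy(dtype=float)
    if np.ptp(effort) == 0:
        raise ValueError("foraging effort is constant; decomposition undefined")
    if np.ptp(rank) == 0:
        raise ValueError("rank is constant; decomposition undefined")

    rank_resid = residualize(effort, rank, name="rank_resid")
    effort_resid = residualize(rank, effort, name="effort_resid")

    if filter_low:
        counts = filter_low_expression(counts, meta[grouping_col])

    design_a = pd.DataFrame(
        {"Intercept": 1.0, "effort": effort, "rank_resid": rank_resid.values},
        index=meta.index,
    )
    design_b = pd.DataFrame(
        {"Intercept": 1.0, "rank": rank, "effort_resid": effort_resid.values},
        index=meta.index,
    )
    res_rank = NBExpressionModel(counts, design_a, contrast="rank_resid").fit(
        theta=theta, shrink_dispersion=shrink_dispersion
    )
    res_effort = NBExpressionModel(counts, design_b, contrast="effort_resid").fit(
        theta=theta, shrink_dispersion=shrink_dispersion
    )
    return res_rank, res_effort
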