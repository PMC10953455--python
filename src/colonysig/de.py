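"""Negative-binomial differential expression for colony count data.

The engine mirrors the standard RNA-seq workflow: low-expression
filtering, median-of-ratios size factors, per-gene NB2 GLM fits with a
log link and size-factor offsets, Wald tests against a point null or a
composite fold-change-threshold null, and Benjamini-Hochberg correction.

Fitting is vectorized across genes: all genes share one design matrix,
so the IRLS normal equations are solved as a batch of small p x p
systems.  Dispersions are per-gene maximum (Cox-Reid adjusted profile)
likelihood estimates with a floor, optionally shrunk toward a
mean-dispersion trend.

The two model-level entry points are :class:`NBExpressionModel` (build
from a count matrix plus a design) and :func:`run_de` (the one-call
filter/normalize/fit/test pipeline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignSpec",
    "DEResults",
    "NBExpressionModel",
    "bh_adjust",
    "filter_low_expression",
    "fit_nb_glm",
    "run_de",
    "size_factors",
    "wald_test",
]

_LN2 = np.log(2.0)
_MIN_DISP = 1e-8
_MAX_DISP = 20.0


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def filter_low_expression(counts: pd.DataFrame, grouping) -> pd.DataFrame:
    """Remove genes not expressed at >= 1 count/sample in any sample group.

    Parameters
    ----------
    counts : DataFrame, genes x samples, non-negative integers.
    grouping : mapping or Series from sample id to group label (e.g.
        original rank).  A gene is retained iff its mean count within at
        least one group is >= 1; gene order is preserved.
    """
    grouping = pd.Series(grouping)
    grouping = grouping.reindex(counts.columns)
    if grouping.isna().any() or len(grouping) == 0:
        missing = list(counts.columns[grouping.isna()])
        raise ValueError(f"grouping missing for samples: {missing[:5]}")
    keep = np.zeros(counts.shape[0], dtype=bool)
    for _, cols in grouping.groupby(grouping):
        keep |= counts[cols.index].mean(axis=1).to_numpy() >= 1.0
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame | np.ndarray) -> pd.Series | np.ndarray:
    """Median-of-ratios size factors with geometric mean rescaled to 1.

    The reference profile is the per-gene geometric mean across samples,
    computed over genes with all-positive counts; if no such gene
    exists, ratios fall back to genes positive in the given sample
    (geometric means over positive entries only).
    """
    values = np.asarray(counts, dtype=float)
    if values.ndim != 2 or values.shape[1] < 1:
        raise ValueError("counts must be a genes x samples matrix")
    if not np.any(values > 0):
        raise ValueError("all-zero count matrix has no size factors")
    with np.errstate(divide="ignore"):
        logc = np.log(values)
    all_pos = np.all(values > 0, axis=1)
    n_samples = values.shape[1]
    factors = np.empty(n_samples)
    if all_pos.any():
        ref = logc[all_pos].mean(axis=1)
        for j in range(n_samples):
            factors[j] = np.exp(np.median(logc[all_pos, j] - ref))
    else:
        # poscounts-style fallback: reference over positive entries
        pos = values > 0
        with np.errstate(invalid="ignore"):
            ref = np.where(pos, logc, np.nan)
        ref = np.nanmean(ref, axis=1)
        for j in range(n_samples):
            use = pos[:, j] & np.isfinite(ref)
            if not use.any():
                raise ValueError(f"sample {j} shares no expressed gene with reference")
            factors[j] = np.exp(np.median(logc[use, j] - ref[use]))
    factors /= np.exp(np.mean(np.log(factors)))
    if isinstance(counts, pd.DataFrame):
        return pd.Series(factors, index=counts.columns, name="size_factor")
    return factors


# ---------------------------------------------------------------------------
# NB2 likelihood machinery (batched over genes)
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB2 log likelihood. y, mu: (g, n); alpha: (g, 1) or (g, n)."""
    inv = 1.0 / alpha
    ll = (
        special.gammaln(y + inv)
        - special.gammaln(inv)
        - special.gammaln(y + 1.0)
        + y * np.log(alpha * mu / (1.0 + alpha * mu))
        - inv * np.log1p(alpha * mu)
    )
    return ll.sum(axis=-1)


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    beta0: np.ndarray | None = None,
    maxiter: int = 60,
    tol: float = 1e-9,
):
    """Batched IRLS for NB2 with log link and per-sample offsets.

    y: (g, n); X: (n, p); offset: (n,) or (g, n); alpha: (g,) dispersions.
    Returns (beta (g, p), se (g, p), mu (g, n), converged (g,)).
    """
    g, n = y.shape
    p = X.shape[1]
    alpha = np.asarray(alpha, dtype=float).reshape(g, 1)
    if beta0 is None:
        # initialize from a log-linear least-squares fit
        z0 = np.log((y + 0.5)) - offset
        beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T
    else:
        beta = beta0.copy()
    converged = np.zeros(g, dtype=bool)
    ridge = 1e-10 * np.eye(p)
    for _ in range(maxiter):
        eta = np.clip(beta @ X.T + offset, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        XtWX = np.einsum("gn,ni,nj->gij", W, X, X, optimize=True)
        XtWz = np.einsum("gn,ni->gi", W * z, X, optimize=True)
        new_beta = np.linalg.solve(XtWX + ridge, XtWz[..., None])[..., 0]
        step = np.clip(new_beta - beta, -5.0, 5.0)
        beta = beta + step
        done = np.max(np.abs(step), axis=1) < tol
        converged |= done
        if done.all():
            break
    eta = np.clip(beta @ X.T + offset, -30.0, 30.0)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha * mu)
    XtWX = np.einsum("gn,ni,nj->gij", W, X, X, optimize=True)
    cov = np.linalg.inv(XtWX + ridge)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=-2, axis2=-1), 0.0))
    return beta, se, mu, converged


def _profile_dispersion(
    y: np.ndarray,
    mu: np.ndarray,
    X: np.ndarray,
    cox_reid: bool = True,
    lo: float = _MIN_DISP,
    hi: float = _MAX_DISP,
    iters: int = 60,
) -> np.ndarray:
    """Per-gene dispersion maximizing the (Cox-Reid adjusted) profile
    likelihood at fixed means, by vectorized golden-section search on
    log-alpha."""

    def objective(log_a: np.ndarray) -> np.ndarray:
        a = np.exp(log_a)[:, None]
        ll = _nb_loglik(y, mu, a)
        if cox_reid:
            W = mu / (1.0 + a * mu)
            XtWX = np.einsum("gn,ni,nj->gij", W, X, X, optimize=True)
            sign, logdet = np.linalg.slogdet(XtWX + 1e-12 * np.eye(X.shape[1]))
            ll = ll - 0.5 * logdet
        return ll

    g = y.shape[0]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a_lo = np.full(g, np.log(lo))
    a_hi = np.full(g, np.log(hi))
    x1 = a_hi - invphi * (a_hi - a_lo)
    x2 = a_lo + invphi * (a_hi - a_lo)
    f1 = objective(x1)
    f2 = objective(x2)
    for _ in range(iters):
        go_right = f1 < f2
        a_lo = np.where(go_right, x1, a_lo)
        a_hi = np.where(~go_right, x2, a_hi)
        x1 = a_hi - invphi * (a_hi - a_lo)
        x2 = a_lo + invphi * (a_hi - a_lo)
        f1 = objective(x1)
        f2 = objective(x2)
        if np.max(a_hi - a_lo) < 1e-6:
            break
    return np.exp((a_lo + a_hi) / 2.0)


def _dispersion_trend(alpha: np.ndarray, base_mean: np.ndarray) -> np.ndarray:
    """Robust asymptotic-plus-Poisson mean-dispersion trend a0 + a1/mean,
    fitted by medians."""
    mean = np.maximum(base_mean, 1e-8)
    high = mean >= np.median(mean)
    a0 = max(np.median(alpha[high]) if high.any() else np.median(alpha), _MIN_DISP)
    a1 = max(float(np.median((alpha - a0) * mean)), 0.0)
    return np.maximum(a0 + a1 / mean, _MIN_DISP)


def _moderate_dispersion(alpha: np.ndarray, base_mean: np.ndarray,
                         n_samples: int, n_coef: int,
                         min_prior_var: float = 0.0625) -> np.ndarray:
    """Empirical-Bayes moderation of gene-wise dispersions.

    Gene-wise estimates are shrunk toward the mean-dispersion trend on
    the log scale with weight sampling_var / (sampling_var + prior_var):
    the sampling variance of a log-dispersion estimate is approximated
    by trigamma((n - p) / 2) and the prior (biological) variance by the
    MAD^2 of log residuals around the trend minus that sampling term,
    floored at ``min_prior_var``.  Genes whose dispersion is well
    determined (large n) are barely shrunk; the floor keeps genuinely
    gene-specific dispersion from being flattened into the trend.
    """
    trend = _dispersion_trend(alpha, base_mean)
    log_resid = np.log(np.maximum(alpha, _MIN_DISP)) - np.log(trend)
    spread = (1.4826 * np.median(np.abs(log_resid - np.median(log_resid)))) ** 2
    sampling_var = float(special.polygamma(1, max(n_samples - n_coef, 2) / 2.0))
    prior_var = max(spread - sampling_var, min_prior_var)
    w = sampling_var / (sampling_var + prior_var)
    shrunk = np.exp((1.0 - w) * np.log(np.maximum(alpha, _MIN_DISP)) + w * np.log(trend))
    return np.clip(shrunk, _MIN_DISP, _MAX_DISP)


def fit_nb_glm(
    counts_row: np.ndarray,
    design_matrix: np.ndarray,
    size_factors: np.ndarray,
    dispersion: float | None = None,
):
    """Fit one gene's NB2 GLM; returns (coef_log2, se_log2, dispersion).

    Coefficients and standard errors are reported on the log2 scale.
    If ``dispersion`` is given it is held fixed; otherwise it is
    estimated by Cox-Reid adjusted profile maximum likelihood.
    """
    y = np.asarray(counts_row, dtype=float)[None, :]
    X = np.asarray(design_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[1]:
        raise ValueError("design matrix must be samples x coefficients")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is not full rank")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more samples than coefficients")
    offset = np.log(np.asarray(size_factors, dtype=float))
    if dispersion is None:
        alpha = np.array([0.1])
        for _ in range(3):
            beta, se, mu, _ = _irls(y, X, offset, alpha)
            alpha = _profile_dispersion(y, mu, X)
    else:
        if dispersion <= 0:
            raise ValueError("dispersion must be positive")
        alpha = np.array([dispersion])
    beta, se, mu, conv = _irls(y, X, offset, alpha)
    return beta[0] / _LN2, se[0] / _LN2, float(alpha[0])


# ---------------------------------------------------------------------------
# testing
# ---------------------------------------------------------------------------

def wald_test(log2_effect, SE, theta: float = 0.0, df: int | None = None):
    """Wald p-value against H0: effect = 0 (theta=0) or the composite
    null H0: |effect| <= theta (theta>0).

    For the composite null the statistic is max(0, |effect| - theta)/SE
    and p = 2 (1 - Phi(stat)) capped at 1; at |effect| = theta the
    statistic is 0 and p = 1.  ``df`` replaces the normal reference by
    a t distribution with that many degrees of freedom; the model-level
    fit passes the residual df so that the noise in the estimated
    dispersion (hence in SE) is reflected in the tails.
    """
    effect = np.asarray(log2_effect, dtype=float)
    se = np.asarray(SE, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    sf = stats.norm.sf if df is None else (lambda x: stats.t.sf(x, df))
    if theta == 0:
        stat = effect / se
        p = 2.0 * sf(np.abs(stat))
    else:
        stat = np.maximum(0.0, np.abs(effect) - theta) / se
        p = np.minimum(2.0 * sf(stat), 1.0)
    return np.minimum(p, 1.0)


def _wald_stat(log2_effect, SE, theta):
    effect = np.asarray(log2_effect, dtype=float)
    se = np.asarray(SE, dtype=float)
    if theta == 0:
        return effect / se
    return np.maximum(0.0, np.abs(effect) - theta) / se


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

@dataclass
class DesignSpec:
    """A model design: covariate names (columns of the metadata) and the
    coefficient of interest.

    ``covariates`` maps each name to 'categorical' or 'continuous';
    categorical covariates may carry a reference level as
    ``reference[name]``.  ``contrast`` names the covariate whose
    coefficient is tested.
    """

    covariates: dict
    contrast: str
    reference: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.contrast not in self.covariates:
            raise ValueError(f"contrast {self.contrast!r} not among covariates")

    def formula(self) -> str:
        terms = []
        for name, kind in self.covariates.items():
            if kind == "categorical":
                ref = self.reference.get(name)
                if ref is not None:
                    terms.append(f"C({name}, Treatment(reference={ref!r}))")
                else:
                    terms.append(f"C({name})")
            else:
                terms.append(name)
        return "1 + " + " + ".join(terms)


class DEResults:
    """Differential-expression results for one contrast.

    Attributes
    ----------
    table : DataFrame indexed by gene with columns base_mean,
        log2_effect, SE, wald_stat, p, p_adj, theta, converged.
    theta : the log2 threshold used in the composite null (0 for the
        point null).
    """

    def __init__(self, table: pd.DataFrame, theta: float, contrast: str, design_info=None):
        self.table = table
        self.theta = float(theta)
        self.contrast = contrast
        self.design_info = design_info

    def significant(self, alpha: float = 0.05) -> pd.Index:
        """Genes with BH-adjusted p below ``alpha`` (the study's DEG rule)."""
        t = self.table
        return t.index[(t["p_adj"] < alpha) & t["converged"]]

    @property
    def n_significant(self) -> int:
        return len(self.significant())

    def summary(self, alpha: float = 0.05) -> str:
        t = self.table
        up = int(((t["p_adj"] < alpha) & (t["log2_effect"] > 0)).sum())
        dn = int(((t["p_adj"] < alpha) & (t["log2_effect"] < 0)).sum())
        lines = [
            "Negative-binomial differential expression",
            f"  contrast:        {self.contrast}",
            f"  genes tested:    {len(t)}",
            f"  theta (log2):    {self.theta:.4g}",
            f"  DEGs (p_adj<{alpha:g}): {up + dn}  (up {up} / down {dn})",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, contrast: str = "") -> "DEResults":
        table = pd.read_csv(path, sep="\t", index_col="gene")
        theta = float(table["theta"].iloc[0]) if len(table) else 0.0
        return cls(table, theta, contrast)


class NBExpressionModel:
    """Gene-wise negative-binomial GLM over a shared sample design.

    Parameters
    ----------
    counts : DataFrame, genes x samples (non-negative integers).
    design : DataFrame (samples x coefficients, including intercept) or
        a patsy design matrix; all genes share it.
    contrast : name of the design column to test.
    sizes : optional per-sample size factors; median-of-ratios by
        default.
    """

    def __init__(self, counts: pd.DataFrame, design: pd.DataFrame, contrast: str, sizes=None):
        if (np.asarray(counts) < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.index.duplicated().any() or counts.columns.duplicated().any():
            raise ValueError("duplicate gene or sample identifiers")
        if counts.shape[0] < 1 or counts.shape[1] < 2:
            raise ValueError("need >= 1 gene and >= 2 samples")
        design = pd.DataFrame(design)
        if list(design.index) != list(counts.columns):
            design = design.reindex(counts.columns)
            if design.isna().any().any():
                raise ValueError("design does not cover all samples")
        X = design.to_numpy(dtype=float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is not full rank")
        if X.shape[0] <= X.shape[1]:
            raise ValueError("need more samples than coefficients")
        if contrast not in design.columns:
            raise ValueError(f"contrast {contrast!r} not a design column")
        self.counts = counts
        self.design = design
        self.contrast = contrast
        if sizes is None:
            sizes = size_factors(counts)
        self.sizes = np.asarray(sizes, dtype=float)
        if (self.sizes <= 0).any():
            raise ValueError("size factors must be positive")

    @classmethod
    def from_formula(
        cls,
        counts: pd.DataFrame,
        metadata: pd.DataFrame,
        formula: str,
        contrast: str,
        sizes=None,
    ) -> "NBExpressionModel":
        """Build from a patsy formula over sample metadata.

        ``contrast`` may name either a metadata column (its single
        design column is located automatically) or an explicit design
        column.
        """
        meta = metadata.loc[list(counts.columns)]
        dm = patsy.dmatrix(formula, meta, return_type="dataframe")
        if contrast not in dm.columns:
            matches = [c for c in dm.columns if contrast in c and c != "Intercept"]
            if len(matches) != 1:
                raise ValueError(
                    f"contrast {contrast!r} maps to {len(matches)} design columns: {matches}"
                )
            contrast = matches[0]
        dm.index = counts.columns
        return cls(counts, dm, contrast, sizes=sizes)

    def fit(
        self,
        theta: float = 0.0,
        shrink_dispersion: bool = True,
        dispersion: float | np.ndarray | None = None,
    ) -> DEResults:
        """Fit all genes and Wald-test the contrast coefficient.

        theta is the log2 fold-change threshold of the composite null
        (0 tests against a baseline fold change of 0, the default).
        """
        y = self.counts.to_numpy(dtype=float)
        X = self.design.to_numpy(dtype=float)
        offset = np.log(self.sizes)
        j = list(self.design.columns).index(self.contrast)
        norm = y / self.sizes
        base_mean = norm.mean(axis=1)

        if dispersion is not None:
            alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), (y.shape[0],)).copy()
            if (alpha <= 0).any():
                raise ValueError("dispersion must be positive")
            beta, se, mu, conv = _irls(y, X, offset, alpha)
            df = None  # known dispersion: SE carries no estimation noise
        else:
            # moment start, then two rounds of (IRLS | profile-ML dispersion)
            mom = (norm.var(axis=1, ddof=1) - base_mean) / np.maximum(base_mean, 1e-8) ** 2
            alpha = np.clip(mom, 0.01, 2.0)
            beta, se, mu, conv = _irls(y, X, offset, alpha)
            for _ in range(2):
                alpha = _profile_dispersion(y, mu, X)
                if shrink_dispersion:
                    alpha = _moderate_dispersion(alpha, base_mean, X.shape[0], X.shape[1])
                beta, se, mu, conv = _irls(y, X, offset, alpha)
            df = X.shape[0] - X.shape[1]

        log2_effect = beta[:, j] / _LN2
        se_log2 = np.maximum(se[:, j] / _LN2, 1e-12)
        stat = _wald_stat(log2_effect, se_log2, theta)
        p = wald_test(log2_effect, se_log2, theta, df=df)
        ok = conv & np.isfinite(p) & (se[:, j] > 0)
        p_use = np.where(ok, p, np.nan)
        p_adj = np.full_like(p, np.nan)
        if ok.any():
            p_adj[ok] = bh_adjust(p_use[ok])
        table = pd.DataFrame(
            {
                "base_mean": base_mean,
                "log2_effect": log2_effect,
                "SE": se_log2,
                "wald_stat": stat,
                "p": p,
                "p_adj": p_adj,
                "theta": theta,
                "dispersion": alpha,
                "converged": ok,
            },
            index=self.counts.index,
        )
        return DEResults(table, theta, self.contrast, design_info=list(self.design.columns))


def run_de(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    design: DesignSpec | str,
    theta: float = 0.0,
    contrast: str | None = None,
    grouping_col: str = "rank_pre",
    filter_low: bool = True,
    shrink_dispersion: bool = True,
) -> DEResults:
    """Filter -> normalize -> fit -> Wald test -> BH, in one call.

    ``design`` is a :class:`DesignSpec` or a patsy formula string (in
    which case ``contrast`` must name the covariate of interest).
    Genes are declared differentially expressed at BH-adjusted p < .05
    via :meth:`DEResults.significant`.
    """
    meta = metadata.loc[list(counts.columns)]
    if isinstance(design, DesignSpec):
        formula, contrast = design.formula(), design.contrast
    else:
        formula = design
        if contrast is None:
            raise ValueError("contrast required with a formula design")
    if filter_low:
        if grouping_col not in meta.columns:
            raise ValueError(f"grouping column {grouping_col!r} missing from metadata")
        counts = filter_low_expression(counts, meta[grouping_col])
    model = NBExpressionModel.from_formula(counts, meta, formula, contrast)
    return model.fit(theta=theta, shrink_dispersion=shrink_dispersion)
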