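"""Signed-hybrid weighted co-expression network analysis.

Builds a weighted network over genes from a variance-stabilized
expression matrix: adjacency = cor^beta for positive correlations (0
otherwise), topological overlap, average-linkage clustering of
1 - TOM with a fixed-height cut, eigengene-based module merging,
module-trait correlation and module membership (kME).

:class:`CoexpressionNetwork` is the model object; :meth:`fit` returns a
:class:`CoexpressionResults` carrying assignments, eigengenes, kME and
the module-trait table.  The individual steps are also exposed as
functions for piecemeal use and for oracle testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .de import bh_adjust, size_factors as _size_factors

__all__ = [
    "CoexpressionNetwork",
    "CoexpressionResults",
    "ModuleTraitTable",
    "detect_modules",
    "merge_modules",
    "module_eigengene",
    "module_membership",
    "module_set_overlap",
    "module_trait_correlation",
    "network_gene_filter",
    "pick_soft_threshold",
    "signed_hybrid_adjacency",
    "topological_overlap",
    "variance_stabilize",
]

BACKGROUND = "grey"


def network_gene_filter(counts: pd.DataFrame, min_count: int = 10,
                        max_low_fraction: float = 0.90) -> pd.DataFrame:
    """Drop genes with < ``min_count`` reads in > ``max_low_fraction`` of
    samples (the network's stricter second-round filter)."""
    low_frac = (counts < min_count).mean(axis=1)
    return counts.loc[low_frac <= max_low_fraction]


def variance_stabilize(counts: pd.DataFrame, sizes=None, method: str = "log",
                       dispersion: float = 0.1) -> pd.DataFrame:
    """Variance-stabilizing transform of normalized counts.

    method='log' (default): log2(count / size_factor + 1).
    method='asinh': the closed-form NB transform
    2 asinh(sqrt(alpha x)) / (sqrt(alpha) ln 2) with a common
    dispersion ``alpha``, which flattens the variance-mean slope for
    NB-distributed counts.
    """
    if sizes is None:
        sizes = _size_factors(counts)
    sizes = np.asarray(sizes, dtype=float)
    if (sizes <= 0).any():
        raise ValueError("size factors must be positive")
    norm = counts.to_numpy(dtype=float) / sizes
    if method == "log":
        out = np.log2(norm + 1.0)
    elif method == "asinh":
        out = 2.0 * np.arcsinh(np.sqrt(dispersion * norm)) / (np.sqrt(dispersion) * np.log(2.0))
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def _gene_correlations(expr: pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    """Pearson correlations between gene rows; constant genes dropped."""
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant gene(s) from the network")
    values = values[keep]
    cor = np.corrcoef(values)
    cor = np.clip(cor, -1.0, 1.0)
    return cor, expr.index[keep]


def signed_hybrid_adjacency(expr: pd.DataFrame, beta: float = 6.0) -> pd.DataFrame:
    """Signed-hybrid adjacency: cor^beta where cor > 0, else 0; diagonal 1."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    if expr.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    cor, idx = _gene_correlations(expr)
    adj = np.where(cor > 0, cor, 0.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=idx, columns=idx)


def _scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10(freq) on log10(mean connectivity) over
    equal-count bins of the connectivity distribution."""
    k = connectivity[connectivity > 0]
    if k.size < n_bins:
        return 0.0, 0.0
    edges = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if edges.size < 3:
        return 0.0, 0.0
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, edges.size - 2)
    means, freqs = [], []
    for b in range(edges.size - 1):
        sel = which == b
        if sel.sum() > 0:
            means.append(k[sel].mean())
            freqs.append(sel.mean())
    x = np.log10(np.asarray(means))
    y = np.log10(np.asarray(freqs) + 1e-12)
    if np.ptp(x) == 0:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(x, y)
    return float(r**2), float(slope)


@dataclass
class SoftThresholdResult:
    beta: float
    table: pd.DataFrame  # power, r_squared, slope, mean_connectivity
    reached_target: bool


def pick_soft_threshold(expr: pd.DataFrame, candidate_powers=(1, 2, 3, 4, 5, 6, 7, 8, 10, 12),
                        target_r2: float = 0.8) -> SoftThresholdResult:
    """Smallest power whose scale-free topology fit reaches
    ``target_r2`` (with negative slope); otherwise the argmax power,
    flagged ``reached_target=False`` with a warning."""
    powers = list(candidate_powers)
    if len(powers) < 3:
        raise ValueError("need >= 3 candidate powers")
    cor, _ = _gene_correlations(expr)
    pos = np.where(cor > 0, cor, 0.0)
    np.fill_diagonal(pos, 0.0)
    rows = []
    for b in powers:
        adj = pos**b
        k = adj.sum(axis=1)
        r2, slope = _scale_free_fit(k)
        rows.append({"power": b, "r_squared": r2, "slope": slope, "mean_connectivity": k.mean()})
    table = pd.DataFrame(rows).set_index("power")
    ok = table[(table["r_squared"] >= target_r2) & (table["slope"] < 0)]
    if len(ok):
        return SoftThresholdResult(float(ok.index[0]), table, True)
    warnings.warn("no candidate power reached the scale-free fit target; returning argmax")
    signed = table["r_squared"].where(table["slope"] < 0, 0.0)
    return SoftThresholdResult(float(signed.idxmax()), table, False)


def topological_overlap(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j with k the row sums excluding the diagonal; TOM_ii = 1.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    Ad = A.copy()
    np.fill_diagonal(Ad, 0.0)
    k = Ad.sum(axis=1)
    shared = Ad @ Ad
    num = shared + Ad
    den = np.minimum.outer(k, k) + 1.0 - Ad
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


def detect_modules(tom: pd.DataFrame, min_module_size: int = 20,
                   cut_height: float = 0.995) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a fixed-height cut.

    The dendrogram is cut at dissimilarity ``cut_height`` on the
    absolute [0, 1] scale of 1 - TOM (so tightly interconnected inputs
    stay a single module); branches smaller than ``min_module_size``
    fall into the background ('grey').  Modules are labelled M1, M2,
    ... in decreasing size order.  Deterministic given the input.
    """
    genes = tom.index
    dist = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    raw = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_module_size].index
    ordered = sizes.loc[keep].sort_values(ascending=False).index
    mapping = {c: f"M{i + 1}" for i, c in enumerate(ordered)}
    return labels.map(lambda c: mapping.get(c, BACKGROUND))


def module_eigengene(expr: pd.DataFrame, module_genes) -> pd.Series:
    """First principal component of the standardized module expression.

    Unit-norm sample vector, sign aligned so its correlation with the
    mean module profile is non-negative.
    """
    genes = [g for g in module_genes if g in expr.index]
    if not genes:
        raise ValueError("module is empty")
    values = expr.loc[genes].to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    # samples x genes SVD; first right singular vector of gene-space
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=expr.columns)


def _eigengene_table(expr: pd.DataFrame, assignments: pd.Series) -> pd.DataFrame:
    mods = sorted(m for m in assignments.unique() if m != BACKGROUND)
    return pd.DataFrame(
        {m: module_eigengene(expr, assignments.index[assignments == m]) for m in mods}
    )


def merge_modules(expr: pd.DataFrame, assignments: pd.Series,
                  merge_threshold: float = 0.75) -> pd.Series:
    """Iteratively merge the module pair with the highest eigengene
    correlation while any pair exceeds ``merge_threshold``; eigengenes
    are recomputed after each merge.  The fixed point has no eigengene
    pair correlated above the threshold."""
    if not 0.0 < merge_threshold < 1.0:
        raise ValueError("merge_threshold must lie in (0, 1)")
    labels = assignments.copy()
    while True:
        eig = _eigengene_table(expr, labels)
        if eig.shape[1] < 2:
            break
        cor = eig.corr().to_numpy()
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] <= merge_threshold:
            break
        a, b = eig.columns[i], eig.columns[j]
        labels = labels.replace(b, a)
    # relabel by size for stable naming
    sizes = labels[labels != BACKGROUND].value_counts()
    mapping = {c: f"M{i + 1}" for i, c in enumerate(sizes.index)}
    return labels.map(lambda c: mapping.get(c, BACKGROUND))


@dataclass
class ModuleTraitTable:
    """Pearson r, raw p and BH-adjusted p for each module x trait cell.

    BH is applied across all defined cells of the table at once.
    Constant traits yield NaN cells (flagged undefined).
    """

    r: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> list[tuple[str, str]]:
        out = []
        for m in self.p_adj.index:
            for t in self.p_adj.columns:
                if self.p_adj.loc[m, t] < alpha:
                    out.append((m, t))
        return out

    def to_tsv(self, path) -> None:
        long = (
            self.r.stack().rename("r").to_frame()
            .join(self.p.stack().rename("p"))
            .join(self.p_adj.stack().rename("p_adj"))
        )
        long.index.names = ["module", "trait"]
        long.to_csv(path, sep="\t")


def module_trait_correlation(eigengenes: pd.DataFrame, traits: pd.DataFrame) -> ModuleTraitTable:
    """Correlate each module eigengene with each numeric trait.

    Missing trait values are dropped pairwise; p-values are two-sided.
    """
    r = pd.DataFrame(index=eigengenes.columns, columns=traits.columns, dtype=float)
    p = r.copy()
    for m in eigengenes.columns:
        e = eigengenes[m]
        for t in traits.columns:
            tv = pd.to_numeric(traits[t], errors="coerce")
            mask = tv.notna() & e.notna()
            if mask.sum() < 3 or tv[mask].std() == 0 or e[mask].std() == 0:
                continue  # undefined cell stays NaN
            rr, pp = stats.pearsonr(e[mask], tv[mask])
            r.loc[m, t] = rr
            p.loc[m, t] = pp
    flat = p.to_numpy().ravel()
    adj = np.full_like(flat, np.nan)
    ok = np.isfinite(flat)
    if ok.any():
        adj[ok] = bh_adjust(flat[ok])
    p_adj = pd.DataFrame(adj.reshape(p.shape), index=p.index, columns=p.columns)
    return ModuleTraitTable(r=r, p=p, p_adj=p_adj)


def module_membership(expr: pd.DataFrame, eigengene: pd.Series) -> pd.Series:
    """kME: Pearson correlation of each gene's profile with an eigengene.
    Constant genes give NaN."""
    values = expr.to_numpy(dtype=float)
    e = eigengene.loc[expr.columns].to_numpy(dtype=float)
    ez = (e - e.mean()) / e.std()
    sd = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
        kme = (z * ez).mean(axis=1)
    kme[sd == 0] = np.nan
    return pd.Series(kme, index=expr.index, name="kME")


def module_set_overlap(module_genes, gene_set, universe) -> float:
    """Two-sided hypergeometric p for the overlap of a module with a
    gene set inside a declared universe: the sum of point probabilities
    no larger than the observed table's."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(module_genes) & universe
    b = set(gene_set) & universe
    if set(module_genes) - universe or set(gene_set) - universe:
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    x = len(a & b)
    table = [[x, len(a) - x], [len(b) - x, n - len(a) - len(b) + x]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


class CoexpressionResults:
    """Fitted network: module assignments, eigengenes, kME and (when
    traits were supplied) the module-trait correlation table."""

    def __init__(self, assignments: pd.Series, eigengenes: pd.DataFrame,
                 kme: pd.DataFrame, module_trait: ModuleTraitTable | None,
                 power: float, n_initial_modules: int):
        self.assignments = assignments
        self.eigengenes = eigengenes
        self.kme = kme
        self.module_trait = module_trait
        self.power = power
        self.n_initial_modules = n_initial_modules

    @property
    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.columns]

    def module_genes(self, module: str) -> pd.Index:
        return self.assignments.index[self.assignments == module]

    def summary(self) -> str:
        sizes = self.assignments[self.assignments != BACKGROUND].value_counts()
        lines = [
            "Signed-hybrid co-expression network",
            f"  soft-threshold power: {self.power:g}",
            f"  genes:                {len(self.assignments)}"
            f" ({int((self.assignments == BACKGROUND).sum())} background)",
            f"  modules:              {len(sizes)} (initial {self.n_initial_modules})",
        ]
        if len(sizes):
            lines.append(f"  module sizes:         {sizes.min()}-{sizes.max()}")
        if self.module_trait is not None:
            hits = self.module_trait.significant()
            lines.append(f"  module-trait cells with p_adj<.05: {len(hits)}")
        return "\n".join(lines)


class CoexpressionNetwork:
    """Model object for the full network pipeline over a variance-
    stabilized expression matrix (genes x samples).

    Parameters mirror the study's construction: soft-threshold power 6,
    signed-hybrid adjacency, eigengene-correlation merging above 0.75.
    """

    def __init__(self, expr: pd.DataFrame, power: float = 6.0,
                 min_module_size: int = 20, merge_threshold: float = 0.75,
                 traits: pd.DataFrame | None = None):
        self.expr = expr
        self.power = float(power)
        self.min_module_size = int(min_module_size)
        self.merge_threshold = float(merge_threshold)
        self.traits = traits

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, traits: pd.DataFrame | None = None,
                    power: float = 6.0, vst_method: str = "log", **kw) -> "CoexpressionNetwork":
        filtered = network_gene_filter(counts)
        expr = variance_stabilize(filtered, method=vst_method)
        return cls(expr, power=power, traits=traits, **kw)

    def fit(self) -> CoexpressionResults:
        adj = signed_hybrid_adjacency(self.expr, self.power)
        tom = topological_overlap(adj)
        assignments = detect_modules(tom, self.min_module_size)
        n_initial = int((assignments != BACKGROUND).sum() and assignments[assignments != BACKGROUND].nunique())
        merged = merge_modules(self.expr.loc[assignments.index], assignments, self.merge_threshold)
        eigengenes = _eigengene_table(self.expr.loc[merged.index], merged)
        kme = pd.DataFrame({m: module_membership(self.expr.loc[merged.index], eigengenes[m])
                            for m in eigengenes.columns})
        mt = None
        if self.traits is not None:
            traits = self.traits.loc[self.expr.columns]
            mt = module_trait_correlation(eigengenes, traits)
        return CoexpressionResults(merged, eigengenes, kme, mt, self.power, n_initial)
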