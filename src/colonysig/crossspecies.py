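"""Cross-lineage comparison of role-biased expression.

Joins per-ortholog log2 fold changes from two species, measures their
Kendall rank correlation against a permutation null, and tests gene-set
overlaps with Fisher's exact test inside an explicitly declared
ortholog universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .orthology import OrthologMap

__all__ = [
    "PermutationNull",
    "join_fold_changes",
    "kendall_correlation",
    "overlap_fisher",
    "permutation_null",
]


def join_fold_changes(results_A: pd.DataFrame | pd.Series, results_B: pd.DataFrame | pd.Series,
                      ortholog_map: OrthologMap,
                      column: str = "log2_effect") -> pd.DataFrame:
    """One row per ortholog pair with both species' fold changes.

    ``results_A``/``results_B`` are per-gene tables (or Series) indexed
    by each species' gene ids; pairs missing a finite fold change on
    either side are dropped.
    """
    fa = results_A[column] if isinstance(results_A, pd.DataFrame) else results_A
    fb = results_B[column] if isinstance(results_B, pd.DataFrame) else results_B
    rows = []
    for a, b in ortholog_map.as_dict().items():
        va, vb = fa.get(a, np.nan), fb.get(b, np.nan)
        if np.isfinite(va) and np.isfinite(vb):
            rows.append({"gene_A": a, "gene_B": b, "fc_A": float(va), "fc_B": float(vb)})
    return pd.DataFrame(rows, columns=["gene_A", "gene_B", "fc_A", "fc_B"])


def kendall_correlation(x, y) -> tuple[float, float]:
    """Kendall tau-b with tie correction.

    Exact p by enumeration for n <= 8 (no ties needed beyond scipy's
    handling), asymptotic normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equal-length vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    method = "exact" if x.size <= 8 and (np.unique(x).size == x.size
                                         and np.unique(y).size == y.size) else "asymptotic"
    res = stats.kendalltau(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PermutationNull:
    """Null distribution of tau under random pairing of fold changes."""

    tau_observed: float
    null_taus: np.ndarray
    empirical_p: float
    null_mean: float
    seed: int

    def summary(self) -> str:
        return (
            f"Kendall tau = {self.tau_observed:.4g}; permutation null mean tau = "
            f"{self.null_mean:.4g} over {len(self.null_taus)} permutations; "
            f"empirical p = {self.empirical_p:.4g}"
        )


def permutation_null(x, y, n_perm: int = 100, seed: int = 0) -> PermutationNull:
    """Permute ``y`` ``n_perm`` times and compare |tau| to the observed.

    Empirical p uses the plus-one rule
    (1 + #{|tau_null| >= |tau_obs|}) / (n_perm + 1), so it is never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    tau_obs, _ = kendall_correlation(x, y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = stats.kendalltau(x, rng.permutation(y), method="asymptotic").statistic
    p = (1.0 + np.sum(np.abs(null) >= abs(tau_obs))) / (n_perm + 1.0)
    return PermutationNull(tau_obs, null, float(p), float(null.mean()), seed)


def overlap_fisher(list_A, list_B, universe, alternative: str = "greater",
                   family=None) -> pd.DataFrame:
    """Fisher's exact overlap test(s) inside a declared universe.

    For a single test pass ``list_A``/``list_B``; to declare a BH
    family of tests corrected together, pass ``family`` as a list of
    (name, list_A, list_B) triples (the positional lists are then
    ignored).  One-sided enrichment by default.  Returns a DataFrame
    with overlap, odds_ratio, p and p_adj per test.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    tests = family if family is not None else [("overlap", list_A, list_B)]
    rows = []
    for name, la, lb in tests:
        sa, sb = set(la), set(lb)
        if sa - universe or sb - universe:
            raise ValueError(f"test {name!r}: lists must be subsets of the universe")
        n = len(universe)
        x = len(sa & sb)
        table = [[x, len(sa) - x], [len(sb) - x, n - len(sa) - len(sb) + x]]
        odds, p = stats.fisher_exact(table, alternative=alternative)
        rows.append({"test": name, "overlap": x, "n_A": len(sa), "n_B": len(sb),
                     "universe": n, "odds_ratio": float(odds), "p": float(p)})
    out = pd.DataFrame(rows).set_index("test")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
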