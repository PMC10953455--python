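"""Top-variable-gene principal component summary of samples."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["pca_top_variable"]


def pca_top_variable(expr: pd.DataFrame, k: int = 1000, n_components: int = 10):
    """PCA of samples over the ``k`` most variable genes.

    ``expr`` is a logged (or otherwise variance-stabilized) genes x
    samples matrix.  Genes are ranked by descending variance, the
    selected submatrix is centred per gene, and components come from
    the SVD.  Returns (scores, explained) where ``scores`` is a samples
    x components DataFrame and ``explained`` the variance-explained
    fractions.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > expr.shape[0]:
        raise ValueError(f"k={k} exceeds gene count {expr.shape[0]}")
    variances = expr.var(axis=1)
    top = variances.sort_values(ascending=False).index[:k]
    X = expr.loc[top].to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    n_components = min(n_components, s.size)
    scores = u[:, :n_components] * s[:n_components]
    explained = (s**2) / np.sum(s**2)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=expr.columns, columns=cols),
        pd.Series(explained[:n_components], index=cols, name="explained"),
    )
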