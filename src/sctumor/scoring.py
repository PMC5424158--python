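"""Single-sample rank-based gene-set scoring.

A per-cell enrichment statistic in the ssGSEA family: genes are ranked by
expression within each cell, and the score contrasts the weighted cumulative
distribution of in-set genes (weights = rank magnitude^alpha) against the
uniform cumulative distribution of out-of-set genes, summed over the ranked
list and normalised by the number of genes. Being rank-based, the score is
invariant under any strictly increasing transform of a cell's expression
vector.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["ssgsea_score", "score_gene_sets"]


def ssgsea_score(expr: pd.DataFrame, gene_set, alpha: float = 0.25) -> pd.Series:
    """Per-cell enrichment score of ``gene_set`` in a genes x cells matrix.

    Parameters
    ----------
    expr
        Genes x cells expression (log scale conventionally, but any monotone
        transform gives the same score). Ties receive average ranks.
    gene_set
        Iterable of gene ids; members absent from ``expr`` are ignored, at
        least one must be measured.
    alpha
        Rank-weighting exponent for in-set genes (0 = unweighted ECDF).
    """
    in_set = expr.index.isin(set(gene_set))
    k = int(in_set.sum())
    if len(set(gene_set)) == 0:
        raise ValueError("empty gene set")
    if k == 0:
        raise ValueError("no gene of the set is measured in the matrix")
    n = expr.shape[0]
    if k == n:
        raise ValueError("gene set covers every measured gene; no out-set to contrast")

    X = expr.to_numpy(dtype=float)
    ranks = rankdata(X, axis=0)  # 1..n, average ties, per cell
    order = np.argsort(-ranks, axis=0, kind="stable")  # descending expression
    cols = np.arange(X.shape[1])
    r_ord = ranks[order, cols]
    s_ord = in_set[order]

    w = np.where(s_ord, r_ord ** alpha, 0.0)
    p_in = np.cumsum(w, axis=0) / w.sum(axis=0)
    p_out = np.cumsum(~s_ord, axis=0) / (n - k)
    score = (p_in - p_out).sum(axis=0) / n
    return pd.Series(score, index=expr.columns, name="score")


def score_gene_sets(expr: pd.DataFrame, gene_sets: dict, alpha: float = 0.25) -> pd.DataFrame:
    """Cells x sets table of per-cell enrichment scores."""
    return pd.DataFrame({name: ssgsea_score(expr, genes, alpha=alpha)
                         for name, genes in gene_sets.items()})
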