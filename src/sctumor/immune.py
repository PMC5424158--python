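"""Tumour-infiltrating immune cell profiling.

Non-carcinoma cells are clustered into immune lineages by non-negative
matrix factorisation over a curated immune-signature gene panel. Lineage
markers are extracted one-vs-rest with a zero-inflated likelihood-ratio test
combined with ROC AUC and fold-change criteria; marker sets feed a
hypergeometric over-representation analysis; T cells are profiled over
functional-state gene sets (naive, costimulatory, regulatory, exhaustion,
cytotoxicity) and hierarchically clustered on those scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.stats import rankdata

from .containers import ExpressionMatrix
from .scoring import score_gene_sets

__all__ = [
    "NmfResult",
    "MarkerResult",
    "TcellStateProfile",
    "nmf_cluster",
    "zero_inflated_lrt",
    "roc_auc",
    "select_markers",
    "hypergeometric_ora",
    "tcell_state_scores",
]

log = logging.getLogger(__name__)

_SIGMA_FLOOR = 1e-3


@dataclass
class NmfResult:
    W: pd.DataFrame                 # gene x k
    H: pd.DataFrame                 # k x cell
    assignment: pd.Series           # cell -> component index (0..k-1)
    k: int
    seed: int
    n_restarts: int
    reconstruction_error: float
    error_trace: np.ndarray = field(repr=False, default=None)


def _mu_nmf(X: np.ndarray, k: int, rng, max_iter: int, tol: float):
    """Multiplicative-update NMF for Frobenius loss; returns (W, H, trace)."""
    g, c = X.shape
    scale = np.sqrt(X.mean() / k) or 1.0
    W = rng.uniform(0.1, 1.0, (g, k)) * scale
    H = rng.uniform(0.1, 1.0, (k, c)) * scale
    eps = 1e-12
    trace = [float(np.linalg.norm(X - W @ H, "fro"))]
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + eps)
        W *= (X @ H.T) / (W @ H @ H.T + eps)
        err = float(np.linalg.norm(X - W @ H, "fro"))
        trace.append(err)
        if trace[-2] - err < tol * trace[0]:
            break
    return W, H, np.array(trace)


def nmf_cluster(matrix: ExpressionMatrix, signature_genes, k: int = 3, seed: int = 0,
                n_restarts: int = 10, max_iter: int = 500, tol: float = 1e-6) -> NmfResult:
    """NMF clustering of cells on the non-negative log layer restricted to a
    signature gene panel; cells are assigned to the argmax component of H.

    Runs ``n_restarts`` random initialisations and keeps the factorisation
    with the lowest Frobenius reconstruction error. Multiplicative updates
    guarantee the error never increases across iterations.
    """
    genes = [g for g in signature_genes if g in matrix.tpm.index]
    if not genes:
        raise ValueError("no signature gene is present in the matrix")
    X = matrix.log.loc[genes].to_numpy(dtype=float)
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(X.shape)}")
    if not X.any():
        raise ValueError("signature submatrix is all zero")
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_restarts):
        W, H, trace = _mu_nmf(X, k, np.random.default_rng(child), max_iter, tol)
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace)
    W, H, trace = best
    Wd = pd.DataFrame(W, index=genes, columns=range(k))
    Hd = pd.DataFrame(H, index=range(k), columns=matrix.cell_ids)
    assignment = pd.Series(np.argmax(H, axis=0), index=matrix.cell_ids, name="component")
    return NmfResult(W=Wd, H=Hd, assignment=assignment, k=k, seed=seed,
                     n_restarts=n_restarts, reconstruction_error=float(trace[-1]),
                     error_trace=trace)


def _zin_loglik(x: np.ndarray, pi: float, mu: float, sigma: float) -> float:
    """Log likelihood of a zero-inflated log-normal-on-log-scale sample.

    Zeros arise with probability 1 - pi; positive values are Normal(mu,
    sigma) on the log scale. Boundary detection rates (pi in {0, 1}) are
    handled by dropping the vanishing terms.
    """
    n0 = int((x == 0).sum())
    pos = x[x > 0]
    ll = 0.0
    if n0:
        ll += n0 * np.log(max(1.0 - pi, 1e-300))
    if len(pos):
        ll += len(pos) * np.log(max(pi, 1e-300))
        ll += float(stats.norm.logpdf(pos, loc=mu, scale=sigma).sum())
    return ll


def zero_inflated_lrt(values_a, values_b, pooled_sigma: bool = True) -> float:
    """P-value of a two-group zero-inflated likelihood-ratio test.

    Each group's expression is modelled as a point mass at zero (detection
    probability pi) plus a Normal on the log scale for positive values. The
    alternative fits group-specific (pi, mu) with a sigma pooled over both
    groups' positives; the null shares (pi, mu, sigma). The statistic
    2*(l_alt - l_null) is referred to chi-square with df=2 (df=3 with
    ``pooled_sigma=False``, which also frees sigma per group).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 cells")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("log-layer values must be non-negative")

    pos_a, pos_b = a[a > 0], b[b > 0]
    pooled = np.concatenate([a, b])
    pos_all = pooled[pooled > 0]

    # detection-rate-only test when there is no positive mass to model
    if len(pos_all) < 2:
        pi_a, pi_b = len(pos_a) / len(a), len(pos_b) / len(b)
        pi_0 = len(pos_all) / len(pooled)
        lam = 2 * (_binom_ll(len(pos_a), len(a), pi_a) + _binom_ll(len(pos_b), len(b), pi_b)
                   - _binom_ll(len(pos_a), len(a), pi_0) - _binom_ll(len(pos_b), len(b), pi_0))
        return float(stats.chi2.sf(max(lam, 0.0), df=1))

    mu_0 = float(pos_all.mean())
    sigma_0 = max(float(np.sqrt(((pos_all - mu_0) ** 2).mean())), _SIGMA_FLOOR)
    pi_0 = len(pos_all) / len(pooled)
    ll_null = (_zin_loglik(a, pi_0, mu_0, sigma_0) + _zin_loglik(b, pi_0, mu_0, sigma_0))

    mu_a = float(pos_a.mean()) if len(pos_a) else mu_0
    mu_b = float(pos_b.mean()) if len(pos_b) else mu_0
    if pooled_sigma:
        sse = (((pos_a - mu_a) ** 2).sum() + ((pos_b - mu_b) ** 2).sum())
        sig_a = sig_b = max(float(np.sqrt(sse / len(pos_all))), _SIGMA_FLOOR)
        df = 2
    else:
        sig_a = max(float(np.sqrt(((pos_a - mu_a) ** 2).mean())) if len(pos_a) > 1 else _SIGMA_FLOOR,
                    _SIGMA_FLOOR)
        sig_b = max(float(np.sqrt(((pos_b - mu_b) ** 2).mean())) if len(pos_b) > 1 else _SIGMA_FLOOR,
                    _SIGMA_FLOOR)
        df = 3
    ll_alt = (_zin_loglik(a, len(pos_a) / len(a), mu_a, sig_a)
              + _zin_loglik(b, len(pos_b) / len(b), mu_b, sig_b))
    lam = max(2.0 * (ll_alt - ll_null), 0.0)
    return float(stats.chi2.sf(lam, df=df))


def _binom_ll(k: int, n: int, p: float) -> float:
    p = min(max(p, 1e-300), 1 - 1e-12)
    return k * np.log(p) + (n - k) * np.log(1 - p)


def roc_auc(values, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) identity.

    ``labels`` are truthy for the positive class; ties contribute 1/2.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    r = rankdata(v)
    u = r[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def select_markers(matrix: ExpressionMatrix, assignment: pd.Series,
                   min_fold: float = 2.0, min_auc: float = 0.7,
                   max_p: float = 0.05, min_cells: int = 3) -> pd.DataFrame:
    """Cluster-specific marker genes under the fold>2 / AUC>0.7 / LRT p<0.05 rule.

    One-vs-rest per cluster on the log layer; the fold-change criterion is a
    difference of group means > log2(min_fold). Clusters with fewer than
    ``min_cells`` cells are skipped with a warning. Result is sorted by
    (cluster, AUC descending) and invariant to cell and gene order.
    """
    assignment = assignment.reindex(matrix.cell_ids)
    clusters = sorted(assignment.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    logm = matrix.log
    lfc_min = np.log2(min_fold)
    rows = []
    for cid in clusters:
        in_mask = (assignment == cid).to_numpy()
        if in_mask.sum() < min_cells or (~in_mask).sum() < min_cells:
            log.warning("cluster %s has <%d cells on a side; skipped", cid, min_cells)
            continue
        X = logm.to_numpy()
        lfc = X[:, in_mask].mean(axis=1) - X[:, ~in_mask].mean(axis=1)
        for gi in np.nonzero(lfc > lfc_min)[0]:
            vals = X[gi]
            auc = roc_auc(vals, in_mask)
            if auc <= min_auc:
                continue
            p = zero_inflated_lrt(vals[in_mask], vals[~in_mask])
            if p < max_p:
                rows.append((str(logm.index[gi]), cid, float(lfc[gi]), float(auc), float(p)))
    out = pd.DataFrame(rows, columns=["gene_id", "cluster", "log_fold_change", "auc", "p_lrt"])
    return out.sort_values(["cluster", "auc", "gene_id"],
                           ascending=[True, False, True]).reset_index(drop=True)


def hypergeometric_ora(marker_genes, term_map: dict, universe) -> pd.Series:
    """Upper-tail hypergeometric over-representation p per term.

    ``universe`` is the background gene list; markers must be contained in
    it. Terms with zero overlap report p = 1.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uset = set(universe)
    markers = set(marker_genes)
    stray = markers - uset
    if stray:
        raise ValueError(f"markers outside the universe: {sorted(stray)[:5]}")
    N, n = len(uset), len(markers)
    out = {}
    for term, genes in term_map.items():
        term_genes = set(genes) & uset
        k = len(term_genes & markers)
        out[term] = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, len(term_genes), n))
    return pd.Series(out, name="p").sort_values()


@dataclass
class TcellStateProfile:
    scores: pd.DataFrame            # cells x 5 state sets
    linkage_matrix: np.ndarray
    labels: pd.Series | None = None


def tcell_state_scores(matrix: ExpressionMatrix, state_sets: dict,
                       n_clusters: int | None = None, alpha: float = 0.25,
                       linkage: str = "ward", distance: str = "euclidean") -> TcellStateProfile:
    """Functional-state scores for T cells plus hierarchical clustering on them.

    ``state_sets`` conventionally holds the naive / costimulatory /
    regulatory / exhaustion / cytotoxicity sets, but any GMT works (the same
    machinery profiles B-cell subclasses with B-cell sets).
    """
    if matrix.n_cells == 0:
        raise ValueError("no cells supplied")
    if not state_sets:
        raise ValueError("no state gene sets supplied")
    scores = score_gene_sets(matrix.log, state_sets, alpha=alpha)
    Z = hierarchy.linkage(scores.to_numpy(), method=linkage, metric=distance)
    labels = None
    if n_clusters is not None:
        labels = pd.Series(hierarchy.fcluster(Z, n_clusters, criterion="maxclust"),
                           index=scores.index, name="state_cluster")
    return TcellStateProfile(scores=scores, linkage_matrix=Z, labels=labels)
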