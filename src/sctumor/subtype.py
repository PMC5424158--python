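"""Carcinoma-cell subtype classification and aggressiveness scoring.

Single tumour cells are placed into ER+/HER2+/TNBC compartments from signed
ER- and HER2-signalling module scores with two axis-aligned thresholds (HER2
takes precedence, mirroring clinical practice where HER2 amplification
dominates the call). TNBC cells are further assigned to transcriptional
subgroups by Spearman correlation against reference centroids, allowing
multiple or no memberships. Rank-based signature scores quantify EMT,
stemness, angiogenesis, proliferation and recurrence programmes and flag
rare co-activated cells.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .scoring import score_gene_sets

__all__ = [
    "module_score",
    "fit_subtype_thresholds",
    "classify_subtype",
    "centroid_classify",
    "aggressiveness_scores",
    "SubtypeThresholds",
]


@dataclass
class SubtypeThresholds:
    t_er: float
    t_her2: float


def module_score(expr: pd.DataFrame, module: pd.Series) -> pd.Series:
    """Signed weighted-average module score per cell.

    ``module`` maps gene id -> weight (+1/-1 signs or arbitrary finite
    weights); the score is sum(w_i * x_i) / sum(|w_i|) over measured module
    genes of the (conventionally mean-centred) log matrix.
    """
    genes = [g for g in module.index if g in expr.index]
    if not genes:
        raise ValueError("no module gene is measured in the matrix")
    w = module.loc[genes].astype(float)
    if not np.isfinite(w).all():
        raise ValueError("module weights must be finite")
    return expr.loc[genes].mul(w, axis=0).sum(axis=0) / w.abs().sum()


def classify_subtype(er_score: pd.Series, her2_score: pd.Series,
                     t_er: float, t_her2: float) -> pd.DataFrame:
    """ER+/HER2+/TNBC call from the two module scores.

    HER2+ if her2 > t_her2; else ER+ if er > t_er; else TNBC. Cells positive
    for both are called HER2+ by precedence, with the ER score kept as
    evidence.
    """
    er_score, her2_score = er_score.align(her2_score)
    call = np.where(her2_score > t_her2, "HER2+",
                    np.where(er_score > t_er, "ER+", "TNBC"))
    return pd.DataFrame({
        "er_score": er_score,
        "her2_score": her2_score,
        "call": call,
        "er_positive": er_score > t_er,
        "her2_positive": her2_score > t_her2,
    })


def fit_subtype_thresholds(reference_scores: pd.DataFrame,
                           reference_labels: pd.Series,
                           grid_size: int = 256) -> SubtypeThresholds:
    """Grid-search the (t_ER, t_HER2) pair maximising accuracy on a labelled
    reference cohort; ties resolve to the smallest thresholds.

    ``reference_scores`` needs columns er_score/her2_score; labels must
    contain all three classes.
    """
    labels = reference_labels.reindex(reference_scores.index)
    present = set(labels.unique())
    if not {"ER+", "HER2+", "TNBC"} <= present:
        raise ValueError(f"reference must contain all three classes, got {sorted(present)}")
    er, her2 = reference_scores["er_score"], reference_scores["her2_score"]

    def candidates(s: pd.Series) -> np.ndarray:
        vals = np.unique(s)
        cand = np.concatenate([[vals[0] - 1.0], (vals[:-1] + vals[1:]) / 2.0, [vals[-1] + 1.0]])
        if len(cand) > grid_size:
            # thin by selection (not interpolation) so real boundaries survive
            cand = cand[np.unique(np.linspace(0, len(cand) - 1, grid_size).astype(int))]
        return np.sort(cand)

    best = (-1.0, np.inf, np.inf)
    best_t = None
    for t_e, t_h in itertools.product(candidates(er), candidates(her2)):
        acc = float((classify_subtype(er, her2, t_e, t_h)["call"] == labels).mean())
        key = (acc, -t_e, -t_h)  # higher accuracy, then smaller thresholds
        if best_t is None or key > (best[0], -best[1], -best[2]):
            best, best_t = (acc, t_e, t_h), SubtypeThresholds(float(t_e), float(t_h))
    return best_t


def _spearman(x: np.ndarray, y: np.ndarray, n_resamples: int | None,
              rng) -> tuple[float, float]:
    res = stats.spearmanr(x, y)
    rho, p = float(res.statistic), float(res.pvalue)
    if n_resamples:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = 0
        for _ in range(n_resamples):
            if abs(np.corrcoef(rng.permutation(rx), ry)[0, 1]) >= obs - 1e-12:
                hits += 1
        p = (hits + 1) / (n_resamples + 1)
    return rho, p


def centroid_classify(matrix: ExpressionMatrix, centroids: pd.DataFrame,
                      alpha: float = 0.05, min_genes: int = 10,
                      permutation_below: int = 12, n_resamples: int = 9999,
                      seed: int = 0) -> pd.DataFrame:
    """Assign each cell to every centroid it correlates with significantly.

    Uses the un-centred log layer (centring would fabricate apparent ER
    positivity in cells with zero receptor expression). Genes never expressed
    in any cell are removed first; per (cell, subtype), Spearman rho and p
    are computed over the intersecting genes, and a cell is assigned every
    subtype with rho > 0 and p < alpha — possibly several, possibly none.
    P-values use the t-approximation, switching to a seeded Monte-Carlo
    permutation when fewer than ``permutation_below`` genes intersect.
    """
    if centroids.shape[1] < 2:
        raise ValueError("need at least 2 centroids")
    logm = matrix.log
    expressed = logm.index[(logm > 0).any(axis=1)]
    logm = logm.loc[expressed]
    shared = [g for g in centroids.index if g in logm.index]
    rng = np.random.default_rng(seed)

    rows = []
    for cell in logm.columns:
        x = logm.loc[shared, cell]
        measured = [g for g in shared]
        if len(measured) < min_genes:
            raise ValueError(f"cell {cell}: only {len(measured)} genes intersect the centroids "
                             f"(need >= {min_genes})")
        use_perm = len(measured) < permutation_below
        row = {"cell_id": cell}
        assigned = []
        for sub in centroids.columns:
            rho, p = _spearman(x.to_numpy(), centroids.loc[measured, sub].to_numpy(),
                               n_resamples if use_perm else None, rng)
            row[f"rho_{sub}"] = rho
            row[f"p_{sub}"] = p
            if rho > 0 and p < alpha:
                assigned.append(sub)
        row["assigned"] = tuple(assigned)
        rows.append(row)
    return pd.DataFrame(rows).set_index("cell_id")


def aggressiveness_scores(matrix: ExpressionMatrix, gene_sets: dict,
                          alpha: float = 0.25, top_fraction: float = 0.05) -> dict:
    """Per-cell signature scores, their pairwise correlations, and rare-cell flags.

    Scores every set (EMT, stemness, angiogenesis, proliferation, recurrence
    or any user GMT) with the rank-based scorer on the log layer; reports the
    cells at or above the (1 - top_fraction) quantile on *both* members of
    each set pair — candidate rare co-activated subpopulations.
    """
    if not gene_sets:
        raise ValueError("no gene sets supplied")
    scores = score_gene_sets(matrix.log, gene_sets, alpha=alpha)
    corr = scores.corr(method="pearson")
    cutoffs = scores.quantile(1.0 - top_fraction)
    above = scores.ge(cutoffs, axis=1)
    flags = {}
    for a, b in itertools.combinations(scores.columns, 2):
        flags[(a, b)] = list(scores.index[above[a] & above[b]])
    return {"scores": scores, "correlations": corr, "cutoffs": cutoffs,
            "double_flagged": flags}
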