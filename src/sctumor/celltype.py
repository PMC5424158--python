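"""Marker-free separation of carcinoma from immune and stromal cells.

Cells are clustered on their smoothed chromosomal expression profiles.
Clusters with strong copy-number signal (profile energy) that are dominated
by a single tumour are called carcinoma — tumour cells are patient-specific,
while normal cell types mix across patients. Remaining cells are labelled
immune or stromal from rank-based signature scores. Intratumoral correlation
structure before/after removing non-carcinoma cells quantifies how much
apparent heterogeneity the normal cells contributed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_score

from .containers import CnvProfiles, ExpressionMatrix
from .scoring import score_gene_sets, ssgsea_score  # noqa: F401  (re-exported)

__all__ = [
    "ClusterResult",
    "CellTypeThresholds",
    "cluster_profiles",
    "cnv_signal_score",
    "assign_cell_types",
    "correlation_structure",
    "linkage_to_newick",
]

log = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    labels: pd.Series            # cell -> cluster id (1..n_clusters)
    linkage_matrix: np.ndarray
    n_clusters: int
    linkage: str = "ward"
    distance: str = "euclidean"

    def cells_in(self, cluster_id: int) -> list:
        return list(self.labels.index[self.labels == cluster_id])


@dataclass
class CellTypeThresholds:
    """Decision thresholds for the marker-free classification rule.

    ``t_cnv`` is the minimum median profile energy of a carcinoma-like
    cluster, ``f_dom`` the minimum fraction of its members coming from one
    tumour; ``t_immune``/``t_stromal``/``t_epithelial`` cut the rank-based
    signature scores. Defaults were calibrated on the bundled synthetic
    generator at its default settings.
    """

    t_cnv: float = 0.05
    f_dom: float = 0.60
    t_immune: float = 0.12
    t_stromal: float = 0.20
    t_epithelial: float = 0.20
    unclassified_as_stromal: bool = True


def cluster_profiles(profiles: CnvProfiles, n_clusters: int | None = None,
                     linkage: str = "ward", distance: str = "euclidean",
                     max_auto_clusters: int = 10) -> ClusterResult:
    """Agglomerative clustering of cells on their smoothed CNV profiles.

    With ``n_clusters=None`` the cut is chosen by silhouette score over
    2..``max_auto_clusters``. Deterministic given its inputs.
    """
    X = profiles.values.T.to_numpy()
    n_cells = X.shape[0]
    if n_cells < 2:
        raise ValueError("need at least 2 cells to cluster")
    if n_clusters is not None and n_clusters > n_cells:
        raise ValueError(f"n_clusters={n_clusters} exceeds {n_cells} cells")
    Z = hierarchy.linkage(X, method=linkage, metric=distance)
    if n_clusters is None:
        best, best_s = 2, -np.inf
        for k in range(2, min(max_auto_clusters, n_cells - 1) + 1):
            lab = hierarchy.fcluster(Z, k, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            s = silhouette_score(X, lab, metric=distance)
            if s > best_s:
                best, best_s = k, s
        n_clusters = best
    lab = hierarchy.fcluster(Z, n_clusters, criterion="maxclust")
    labels = pd.Series(lab, index=profiles.values.columns, name="cluster")
    return ClusterResult(labels=labels, linkage_matrix=Z, n_clusters=int(n_clusters),
                         linkage=linkage, distance=distance)


def linkage_to_newick(Z: np.ndarray, leaf_names) -> str:
    """Dendrogram as a Newick string (branch lengths from merge heights)."""
    tree = hierarchy.to_tree(Z)
    names = list(leaf_names)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def cnv_signal_score(profiles: CnvProfiles) -> pd.Series:
    """Per-cell profile energy: mean of squared smoothed (centred) values.

    Operationalises "coherent chromosomal deviation": diploid cells have flat
    profiles and near-zero energy, aneuploid cells do not.
    """
    return (profiles.values ** 2).mean(axis=0).rename("cnv_signal")


def assign_cell_types(clusters: ClusterResult, profiles: CnvProfiles,
                      scores: pd.DataFrame, groups: pd.Series,
                      thresholds: CellTypeThresholds | None = None) -> pd.DataFrame:
    """Call every cell carcinoma / immune / stromal.

    A cluster is carcinoma-like iff its median profile energy exceeds
    ``t_cnv`` AND at least ``f_dom`` of its members come from one tumour
    group; its members are called carcinoma. Each remaining cell is immune if
    its immune score clears ``t_immune``, else stromal if its stromal score
    clears ``t_stromal``, else flagged unclassified (counted as stromal when
    its epithelial score is also low, if so configured).

    ``scores`` must hold cells x {immune, stromal, epithelial} columns.
    """
    t = thresholds or CellTypeThresholds()
    for col in ("immune", "stromal", "epithelial"):
        if col not in scores.columns:
            raise KeyError(f"scores table is missing the {col!r} signature")
    signal = cnv_signal_score(profiles)
    cells = clusters.labels.index

    carcinoma_clusters = set()
    for cid in np.unique(clusters.labels):
        members = clusters.cells_in(cid)
        med = float(signal.loc[members].median())
        dom = float(groups.loc[members].value_counts(normalize=True).max())
        if med > t.t_cnv and dom >= t.f_dom:
            carcinoma_clusters.add(cid)

    rows = []
    for cell in cells:
        cid = int(clusters.labels[cell])
        imm, stro, epi = (float(scores.at[cell, c]) for c in ("immune", "stromal", "epithelial"))
        unclassified = False
        if cid in carcinoma_clusters:
            call = "carcinoma"
        elif imm > t.t_immune:
            call = "immune"
        elif stro > t.t_stromal:
            call = "stromal"
        else:
            unclassified = True
            call = "stromal" if (t.unclassified_as_stromal and epi <= t.t_epithelial) else "unclassified"
        rows.append((cell, call, cid, float(signal[cell]), imm, stro, epi, unclassified))
    return pd.DataFrame(
        rows,
        columns=["cell_id", "call", "cluster", "cnv_signal",
                 "immune_score", "stromal_score", "epithelial_score", "unclassified"],
    ).set_index("cell_id")


def _pairwise_r(block: np.ndarray) -> np.ndarray:
    # block: genes x cells; returns the upper triangle of the cell-cell
    # Pearson correlation matrix
    r = np.corrcoef(block.T)
    iu = np.triu_indices_from(r, k=1)
    return r[iu]


def correlation_structure(matrix: ExpressionMatrix, labels: pd.DataFrame,
                          groups: pd.Series | None = None) -> pd.DataFrame:
    """Within-tumour pairwise cell-cell Pearson r before and after restricting
    to carcinoma cells.

    Uses the *un-centred* log layer — intratumoral correlation is one of the
    analyses that deliberately skips gene centring. Groups with fewer than 2
    cells (in either condition) are skipped with a log entry.
    """
    groups = matrix.groups if groups is None else groups
    logm = matrix.log
    carcinoma = set(labels.index[labels["call"] == "carcinoma"])
    rows = {}
    for grp, cells in groups.groupby(groups).groups.items():
        cells = [c for c in cells if c in logm.columns]
        if len(cells) < 2:
            log.info("group %s has <2 cells; skipped", grp)
            continue
        before = _pairwise_r(logm[cells].to_numpy())
        carc = [c for c in cells if c in carcinoma]
        row = {
            "n_before": len(cells),
            "median_before": float(np.median(before)),
            "iqr_before": float(np.subtract(*np.percentile(before, [75, 25]))),
            "mean_before": float(np.mean(before)),
            "n_after": len(carc),
        }
        if len(carc) >= 2:
            after = _pairwise_r(logm[carc].to_numpy())
            row.update(
                median_after=float(np.median(after)),
                iqr_after=float(np.subtract(*np.percentile(after, [75, 25]))),
                mean_after=float(np.mean(after)),
            )
        else:
            log.info("group %s has <2 carcinoma cells; 'after' stats omitted", grp)
            row.update(median_after=np.nan, iqr_after=np.nan, mean_after=np.nan)
        rows[grp] = row
    out = pd.DataFrame(rows).T
    out["rank_by_mean_before"] = out["mean_before"].rank(ascending=False).astype(int)
    return out
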