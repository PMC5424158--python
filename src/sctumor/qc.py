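"""Cell- and gene-level quality control and transformations.

Cells are kept only if they pass four criteria (total reads, mapping rate,
detected genes, intergenic fraction — computed upstream of this package and
supplied as a table). Gene expression below 1 TPM is treated as unreliable
and zeroed before log2(TPM+1); genes not reaching a minimum expressed
fraction in any tumour group are removed. Spike-in consistency is checked via
pairwise log-ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io
from .containers import ExpressionMatrix

__all__ = [
    "CellQcMetrics",
    "QcThresholds",
    "load_expression",
    "filter_cells",
    "filter_genes",
    "mean_centre",
    "check_spikeins",
]


@dataclass
class CellQcMetrics:
    total_reads: int
    mapping_rate: float
    detected_genes: int
    intergenic_fraction: float

    def __post_init__(self):
        if not (0 <= self.mapping_rate <= 1 and 0 <= self.intergenic_fraction <= 1):
            raise ValueError("rates must be fractions in [0, 1]")


@dataclass
class QcThresholds:
    """Cutoffs for the four cell filters plus the gene-level expressed-fraction rule.

    The cell-level defaults are configuration, not dogma: they are a
    reasonable operating point for full-length plate/IFC scRNA-seq and should
    be tuned per study.
    """

    min_total_reads: float = 1e6
    min_mapping_rate: float = 0.5
    min_detected_genes: int = 1000
    max_intergenic_fraction: float = 0.3
    min_expressed_fraction_per_group: float = 0.10
    #: "max": keep gene if expressed in >= fraction of cells of at least one
    #: group; "mean": keep if the across-group mean expressed fraction passes.
    gene_rule: str = "max"

    def __post_init__(self):
        if not (0 < self.min_expressed_fraction_per_group < 1):
            raise ValueError("min_expressed_fraction_per_group must be in (0, 1)")
        if self.gene_rule not in ("max", "mean"):
            raise ValueError("gene_rule must be 'max' or 'mean'")


def load_expression(matrix_path, annotation_path, groups_path,
                    spike_prefix: str = "SPIKE") -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Load a TSV expression matrix plus annotation (BED or GTF) and groups.

    Genes absent from the annotation are retained but flagged (excluded from
    gene filtering and CNV inference). Returns (matrix, annotation).
    """
    tpm = io.read_matrix_tsv(matrix_path)
    path = str(annotation_path)
    annotation = io.read_gtf(path) if path.endswith((".gtf", ".gff")) else io.read_bed(path)
    groups = io.read_groups(groups_path)
    spikes = tuple(g for g in tpm.index if str(g).startswith(spike_prefix))
    unannot = tuple(g for g in tpm.index if g not in annotation.index and g not in spikes)
    matrix = ExpressionMatrix(tpm=tpm, groups=groups, spike_ids=spikes, unannotated=unannot)
    return matrix, annotation


def cell_passes(m: CellQcMetrics, t: QcThresholds) -> bool:
    return (
        m.total_reads >= t.min_total_reads
        and m.mapping_rate >= t.min_mapping_rate
        and m.detected_genes >= t.min_detected_genes
        and m.intergenic_fraction <= t.max_intergenic_fraction
    )


def filter_cells(matrix: ExpressionMatrix, qc: dict, thresholds: QcThresholds) -> ExpressionMatrix:
    """Keep exactly the cells passing all four QC criteria; order preserved."""
    missing = [c for c in matrix.cell_ids if c not in qc]
    if missing:
        raise KeyError(f"no QC record for cell(s): {missing[:5]}")
    keep = [c for c in matrix.cell_ids if cell_passes(qc[c], thresholds)]
    return matrix.subset_cells(keep)


def expressed_fraction_by_group(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Fraction of each tumour group's cells with non-zero log expression, per gene."""
    groups = matrix.groups
    if groups.isna().any():
        raise ValueError("every cell needs a group label")
    detected = matrix.log > 0
    out = {}
    for grp, cells in groups.groupby(groups).groups.items():
        if len(cells) == 0:
            raise ValueError(f"group {grp!r} has zero cells")
        out[grp] = detected[list(cells)].mean(axis=1)
    return pd.DataFrame(out)


def filter_genes(matrix: ExpressionMatrix, thresholds: QcThresholds) -> ExpressionMatrix:
    """Remove genes under-expressed across all tumour groups.

    Under the default ``max`` rule a gene survives if expressed (log > 0) in
    at least ``min_expressed_fraction_per_group`` of the cells of *some*
    group, so group-restricted genes are kept. Spike-ins and unannotated
    genes are exempt and carried through.
    """
    frac = expressed_fraction_by_group(matrix)
    stat = frac.max(axis=1) if thresholds.gene_rule == "max" else frac.mean(axis=1)
    exempt = set(matrix.spike_ids) | set(matrix.unannotated)
    keep = [g for g in matrix.gene_ids
            if g in exempt or stat[g] >= thresholds.min_expressed_fraction_per_group]
    return matrix.subset_genes(keep)


def mean_centre(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Materialise the per-gene mean-centred log layer; raw layers untouched.

    Several analyses (spike-in checks, intratumoral correlations, chromosomal
    patterns, self-normalising scorers) deliberately read the un-centred log
    layer instead.
    """
    return matrix.centred


def check_spikeins(matrix: ExpressionMatrix, spike_ids=None, expected_copies=None,
                   flag_sd: float = 3.0) -> dict:
    """Per-cell pairwise spike-in log ratios against the cohort.

    For each pair of detected spikes the per-cell log2 TPM ratio should be
    constant across cells (and close to log2 of the copy ratio). Cells whose
    ratio deviates more than ``flag_sd`` cohort standard deviations are
    flagged. Spikes never detected are reported with ``detected=False``.
    """
    spike_ids = list(spike_ids if spike_ids is not None else matrix.spike_ids)
    if len(spike_ids) < 2:
        raise ValueError("need at least two spike-ins")
    absent = [s for s in spike_ids if s not in matrix.tpm.index]
    if absent:
        raise KeyError(f"spike-in ids absent from matrix: {absent}")
    log = matrix.log.loc[spike_ids]
    detected = (log > 0).any(axis=1)
    report = {"detected": detected.to_dict(), "pairs": {}, "flagged_cells": set()}
    for i, a in enumerate(spike_ids):
        for b in spike_ids[i + 1:]:
            if not (detected[a] and detected[b]):
                continue
            both = (log.loc[a] > 0) & (log.loc[b] > 0)
            ratio = (log.loc[a] - log.loc[b])[both]
            if ratio.empty:
                continue
            mean, sd = float(ratio.mean()), float(ratio.std(ddof=1)) if len(ratio) > 1 else 0.0
            entry = {"mean": mean, "sd": sd, "n_cells": int(both.sum())}
            if expected_copies is not None:
                ca, cb = expected_copies[spike_ids.index(a)], expected_copies[spike_ids.index(b)]
                entry["expected_log2_copy_ratio"] = float(np.log2(ca / cb))
            if sd > 0:
                bad = ratio[(ratio - mean).abs() > flag_sd * sd].index
                report["flagged_cells"].update(bad)
            report["pairs"][(a, b)] = entry
    report["flagged_cells"] = sorted(report["flagged_cells"])
    return report
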