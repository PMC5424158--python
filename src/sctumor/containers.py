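"""Core in-memory containers shared across the pipeline.

The central object is :class:`ExpressionMatrix`, a gene x cell TPM matrix with
derived log and mean-centred layers. Genes are rows, cells are columns —
chromosome-ordered operations (CNV smoothing) are gene-major, so this
orientation is kept throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SegmentSet",
    "CnvProfiles",
    "BinnedTrack",
    "sort_annotation",
    "chromosome_sort_key",
]


_CHROM_RE = re.compile(r"^(chr)?(\d+|[XYM]T?)$", re.IGNORECASE)


def chromosome_sort_key(chrom: str):
    """Natural ordering for chromosome names: chr1 < chr2 < ... < chr10 < chrX < chrY."""
    m = _CHROM_RE.match(str(chrom))
    if m:
        body = m.group(2).upper()
        if body.isdigit():
            return (0, int(body), "")
        return (1, {"X": 0, "Y": 1, "M": 2, "MT": 2}.get(body, 9), body)
    return (2, 0, str(chrom))


def sort_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Sort a gene annotation table by (chromosome, start).

    Parameters
    ----------
    annotation
        DataFrame indexed by gene id with columns ``chromosome``, ``start``,
        ``end``. Coordinates are 1-based inclusive in memory.
    """
    if annotation.index.has_duplicates:
        dupes = annotation.index[annotation.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in annotation: {dupes[:5]}")
    if annotation[["start", "end"]].isna().any().any():
        raise ValueError("annotation has missing coordinates")
    if (annotation["start"] < 1).any():
        raise ValueError("annotation start positions must be >= 1 (1-based)")
    if (annotation["end"] < annotation["start"]).any():
        raise ValueError("annotation end < start")
    key = annotation["chromosome"].map(chromosome_sort_key)
    order = sorted(annotation.index, key=lambda g: (key.loc[g], annotation.at[g, "start"]))
    return annotation.loc[order]


@dataclass
class ExpressionMatrix:
    """Gene x cell expression with raw-TPM, log and mean-centred layers.

    Attributes
    ----------
    tpm
        Raw TPM, genes x cells, non-negative.
    groups
        Per-cell tumour-group (patient) label, indexed like ``tpm.columns``.
    spike_ids
        Gene ids that are RNA spike-ins. Exempt from gene filtering and
        excluded from CNV inference.
    unannotated
        Gene ids present in the matrix but absent from the annotation;
        retained but flagged, excluded from CNV inference.
    """

    tpm: pd.DataFrame
    groups: pd.Series
    spike_ids: tuple = ()
    unannotated: tuple = ()
    _log_cache: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.tpm.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.tpm.columns.has_duplicates:
            raise ValueError("duplicate cell ids")
        if (self.tpm.values < 0).any():
            raise ValueError("negative TPM values")
        self.groups = self.groups.reindex(self.tpm.columns)
        self.spike_ids = tuple(g for g in self.spike_ids if g in self.tpm.index)
        self.unannotated = tuple(g for g in self.unannotated if g in self.tpm.index)

    # -- layers ---------------------------------------------------------------

    @property
    def log(self) -> pd.DataFrame:
        """log2(TPM+1) with TPM < 1 treated as unreliable and zeroed first."""
        if self._log_cache is None:
            t = self.tpm.where(self.tpm >= 1.0, 0.0)
            self._log_cache = np.log2(t + 1.0)
        return self._log_cache

    @property
    def centred(self) -> pd.DataFrame:
        """Per-gene mean-centred log layer (row means 0 over retained cells)."""
        log = self.log
        return log.sub(log.mean(axis=1), axis=0)

    # -- basic geometry -------------------------------------------------------

    @property
    def gene_ids(self) -> list:
        return list(self.tpm.index)

    @property
    def cell_ids(self) -> list:
        return list(self.tpm.columns)

    @property
    def n_genes(self) -> int:
        return self.tpm.shape[0]

    @property
    def n_cells(self) -> int:
        return self.tpm.shape[1]

    @property
    def analysis_genes(self) -> list:
        """Gene ids subject to filtering and CNV inference (no spikes, no unannotated)."""
        side = set(self.spike_ids) | set(self.unannotated)
        return [g for g in self.tpm.index if g not in side]

    # -- subsetting -----------------------------------------------------------

    def subset_cells(self, cells) -> "ExpressionMatrix":
        cells = [c for c in self.tpm.columns if c in set(cells)]
        return replace(
            self,
            tpm=self.tpm[cells],
            groups=self.groups.loc[cells],
            _log_cache=None,
        )

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = set(genes)
        genes = [g for g in self.tpm.index if g in keep]
        return replace(self, tpm=self.tpm.loc[genes], _log_cache=None)


@dataclass
class SegmentSet:
    """WES-derived copy-number segments (chrom, start, end, log2_ratio).

    Segments shorter than ``min_length`` base pairs are dropped on
    construction; comparisons with inferred CNV use only large-scale events.
    Coordinates are 0-based half-open.
    """

    segments: pd.DataFrame
    min_length: int = 10_000

    def __post_init__(self):
        seg = self.segments.reset_index(drop=True)
        required = {"chromosome", "start", "end", "log2_ratio"}
        missing = required - set(seg.columns)
        if missing:
            raise ValueError(f"segment table missing columns: {sorted(missing)}")
        if (seg["end"] <= seg["start"]).any():
            raise ValueError("malformed segment: end <= start")
        seg = seg[(seg["end"] - seg["start"]) > self.min_length].reset_index(drop=True)
        self.segments = seg

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class CnvProfiles:
    """Per-cell smoothed chromosomal expression tracks (the inferred CNV).

    ``values`` is annotation-ordered genes x cells. When ``centred`` each
    cell's genome-wide mean is zero.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame
    window: int = 150
    centred: bool = True

    @property
    def cell_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class BinnedTrack:
    """Fixed-width genomic bins with one value per bin (NaN = missing).

    ``bins`` has columns chromosome/start/end (0-based half-open, tiling each
    chromosome); ``values`` is aligned to its rows. Used to place WES segments
    and inferred CNV on a common 10 Mb grid.
    """

    bins: pd.DataFrame
    values: pd.Series
    bin_size: int = 10_000_000

    def __post_init__(self):
        self.values = pd.Series(np.asarray(self.values, dtype=float), index=self.bins.index)

    def to_frame(self) -> pd.DataFrame:
        out = self.bins.copy()
        out["value"] = self.values
        return out
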