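"""Copy-number inference from chromosomal expression patterns.

Single-cell log2(TPM+1) values are converted to Z-scores against a bulk
normal-tissue reference, sorted by genomic position, and smoothed with a
moving average of 150 genes per chromosome. The resulting per-cell track is
re-centred genome-wide; coherent regional deviations are the inferred CNV.
Concordance with orthogonal WES segments is measured after placing both on a
common 10 Mb grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BinnedTrack, CnvProfiles, ExpressionMatrix, SegmentSet, sort_annotation

__all__ = [
    "NormalReference",
    "build_reference",
    "zscore",
    "smooth_chromosomal",
    "bin_profile",
    "bin_segments",
    "cnv_concordance",
    "make_bins",
]

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 150
DEFAULT_BIN_SIZE = 10_000_000
DEFAULT_CLAMP = 3.0
DEFAULT_SD_FLOOR = 0.1


@dataclass
class NormalReference:
    """Per-gene mean and sd of log2(TPM+1) over normal-tissue samples.

    Standard deviations are floored at ``sd_floor`` so near-invariant
    reference genes cannot blow up single-cell Z-scores.
    """

    stats: pd.DataFrame  # columns: mean_log, sd_log
    sd_floor: float = DEFAULT_SD_FLOOR

    @property
    def gene_ids(self) -> pd.Index:
        return self.stats.index


def build_reference(normal_matrix: ExpressionMatrix, sd_floor: float = DEFAULT_SD_FLOOR) -> NormalReference:
    """Summarise a normal-tissue expression matrix into a Z-score reference."""
    if normal_matrix.n_cells < 2:
        raise ValueError("need at least 2 normal samples to estimate variation")
    logm = normal_matrix.log
    st = pd.DataFrame({
        "mean_log": logm.mean(axis=1),
        "sd_log": logm.std(axis=1, ddof=1).clip(lower=sd_floor),
    })
    return NormalReference(stats=st, sd_floor=sd_floor)


def zscore(matrix: ExpressionMatrix, reference: NormalReference,
           clamp: float = DEFAULT_CLAMP) -> pd.DataFrame:
    """Gene x cell Z of single-cell log expression against the normal reference.

    Genes missing from the reference (plus spike-ins and unannotated genes)
    are dropped with a log entry; Z is clamped to ``[-clamp, clamp]`` so
    single-gene dropouts cannot dominate a 150-gene average.
    """
    genes = [g for g in matrix.analysis_genes if g in reference.stats.index]
    if not genes:
        raise ValueError("no overlap between matrix genes and reference")
    frac = len(genes) / max(1, len(matrix.analysis_genes))
    if frac < 0.5:
        log.warning("only %.0f%% of analysis genes found in reference", 100 * frac)
    dropped = len(matrix.analysis_genes) - len(genes)
    if dropped:
        log.info("dropping %d genes absent from reference", dropped)
    lg = matrix.log.loc[genes]
    ref = reference.stats.loc[genes]
    z = lg.sub(ref["mean_log"], axis=0).div(ref["sd_log"], axis=0)
    return z.clip(lower=-clamp, upper=clamp)


def _window_bounds(n: int, window: int):
    """Half-open [lo, hi) gene-index bounds of the window centred on each gene,
    truncated (shrunk) at chromosome ends."""
    i = np.arange(n)
    lo = np.maximum(0, i - (window - 1) // 2)
    hi = np.minimum(n, i + window // 2 + 1)
    return lo, hi


def smooth_chromosomal(z_matrix: pd.DataFrame, annotation: pd.DataFrame,
                       window: int = DEFAULT_WINDOW, centre: str = "cell") -> CnvProfiles:
    """Moving average of ``window`` genes along each chromosome, per cell.

    Windows never span chromosome boundaries and shrink at chromosome ends so
    the profile keeps one value per gene. ``centre='cell'`` subtracts each
    cell's genome-wide mean of the smoothed track (``'gene'`` subtracts
    per-gene means across cells instead; ``'none'`` skips centring).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    ann = sort_annotation(annotation.loc[[g for g in annotation.index if g in z_matrix.index]])
    if ann.empty:
        raise ValueError("no annotated genes in the Z matrix")
    z = z_matrix.loc[ann.index]
    out = np.empty_like(z.values, dtype=float)
    row = 0
    for chrom, sub in ann.groupby("chromosome", sort=False):
        n = len(sub)
        if n == 0:  # pragma: no cover - groupby never yields empty
            log.info("chromosome %s has no genes; skipped", chrom)
            continue
        block = z.values[row:row + n]
        csum = np.vstack([np.zeros((1, block.shape[1])), np.cumsum(block, axis=0)])
        lo, hi = _window_bounds(n, window)
        out[row:row + n] = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
        row += n
    smoothed = pd.DataFrame(out, index=ann.index, columns=z.columns)
    if centre == "cell":
        smoothed = smoothed - smoothed.mean(axis=0)
    elif centre == "gene":
        smoothed = smoothed.sub(smoothed.mean(axis=1), axis=0)
    elif centre != "none":
        raise ValueError("centre must be 'cell', 'gene' or 'none'")
    return CnvProfiles(values=smoothed, annotation=ann, window=window, centred=centre != "none")


def make_bins(chrom_lengths: dict, bin_size: int = DEFAULT_BIN_SIZE) -> pd.DataFrame:
    """Half-open fixed-width bins tiling each chromosome [0, L)."""
    rows = []
    for chrom, L in chrom_lengths.items():
        for start in range(0, int(L), bin_size):
            rows.append((chrom, start, min(start + bin_size, int(L))))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end"])


def bin_profile(profiles: CnvProfiles, chrom_lengths: dict,
                bin_size: int = DEFAULT_BIN_SIZE, average_cells: bool = True):
    """Place smoothed profiles on the genomic grid.

    A bin's value is the mean smoothed value of genes whose start falls in
    the bin; empty bins are missing (NaN) and excluded from correlations.
    With ``average_cells`` the cell-averaged track is returned as a
    BinnedTrack, otherwise a bins x cells DataFrame alongside the bin table.
    """
    bins = make_bins(chrom_lengths, bin_size)
    ann = profiles.annotation
    pos = ann["start"].astype(int) - 1  # back to 0-based for bin arithmetic
    key = pd.Series(
        [f"{c}:{p // bin_size}" for c, p in zip(ann["chromosome"], pos)], index=ann.index
    )
    per_bin = profiles.values.groupby(key).mean()
    bin_keys = [f"{c}:{s // bin_size}" for c, s in zip(bins["chromosome"], bins["start"])]
    table = per_bin.reindex(bin_keys)
    table.index = bins.index
    if average_cells:
        return BinnedTrack(bins=bins, values=table.mean(axis=1), bin_size=bin_size)
    return bins, table


def bin_segments(segs: SegmentSet, chrom_lengths: dict,
                 bin_size: int = DEFAULT_BIN_SIZE) -> BinnedTrack:
    """Overlap-length-weighted mean segment log2 ratio per bin.

    Genome not covered by any retained segment counts as diploid (ratio 0),
    so a half-covered bin at ratio 2 scores 1.
    """
    seg = segs.segments
    if (seg["start"] < 0).any():
        raise ValueError("malformed segment coordinates")
    bins = make_bins(chrom_lengths, bin_size)
    values = np.zeros(len(bins))
    for i, (chrom, bstart, bend) in bins.iterrows():
        width = bend - bstart
        sub = seg[seg["chromosome"] == chrom]
        ov = np.minimum(sub["end"], bend) - np.maximum(sub["start"], bstart)
        ov = ov.clip(lower=0)
        values[i] = float((ov * sub["log2_ratio"]).sum() / width)
    return BinnedTrack(bins=bins, values=pd.Series(values, index=bins.index), bin_size=bin_size)


def cnv_concordance(profiles: CnvProfiles, segs: SegmentSet, chrom_lengths: dict,
                    bin_size: int = DEFAULT_BIN_SIZE) -> float:
    """Pearson r between the cell-averaged binned inferred track and the
    binned WES track over bins where both are defined."""
    inferred = bin_profile(profiles, chrom_lengths, bin_size)
    genomic = bin_segments(segs, chrom_lengths, bin_size)
    a, b = inferred.values, genomic.values
    shared = a.notna() & b.notna()
    if shared.sum() < 3:
        raise ValueError(f"only {int(shared.sum())} shared non-missing bins; need >= 3")
    x, y = a[shared].to_numpy(), b[shared].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate variance: one track is constant over shared bins")
    return float(stats.pearsonr(x, y).statistic)
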