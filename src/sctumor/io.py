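"""Readers and writers for the plain-text formats the pipeline consumes.

Expression matrices travel as TSV (genes x cells) or MatrixMarket triplets
with sidecar row/column files; gene annotation as BED (0-based half-open on
disk, 1-based inclusive in memory) or GTF gene records; copy-number segments
as SEG-style TSV; gene sets as GMT; centroids and gene modules as TSV.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp
import yaml

from .containers import SegmentSet, sort_annotation

__all__ = [
    "read_matrix_tsv", "write_matrix_tsv",
    "read_matrix_mtx", "write_matrix_mtx",
    "read_bed", "write_bed", "read_gtf",
    "read_groups", "write_groups",
    "read_seg", "write_seg",
    "read_gmt", "write_gmt",
    "read_centroids", "write_centroids",
    "read_module", "read_yaml", "write_yaml",
]


# -- expression matrices ------------------------------------------------------

def read_matrix_tsv(path) -> pd.DataFrame:
    """Genes x cells TSV with gene ids in the first column, cell ids as header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene ids")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate cell ids")
    return df.astype(float)


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_matrix_mtx(mtx_path, genes_path, cells_path) -> pd.DataFrame:
    """MatrixMarket triplet plus one-id-per-line row (gene) and column (cell) files."""
    mat = spio.mmread(mtx_path)
    genes = [ln.strip().split("\t")[0] for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
    cells = [ln.strip().split("\t")[0] for ln in Path(cells_path).read_text().splitlines() if ln.strip()]
    dense = np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=float)
    if dense.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {dense.shape} does not match {len(genes)} genes x {len(cells)} cells"
        )
    return pd.DataFrame(dense, index=genes, columns=cells)


def write_matrix_mtx(df: pd.DataFrame, mtx_path, genes_path, cells_path) -> None:
    spio.mmwrite(str(mtx_path), sp.csr_matrix(df.values))
    Path(genes_path).write_text("\n".join(map(str, df.index)) + "\n")
    Path(cells_path).write_text("\n".join(map(str, df.columns)) + "\n")


# -- gene annotation ----------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """BED4 (chrom, start, end, gene_id); converts to 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chromosome", "start", "end", "gene_id"],
                     usecols=[0, 1, 2, 3])
    ann = pd.DataFrame({
        "chromosome": df["chromosome"].astype(str).to_numpy(),
        "start": df["start"].astype(int).to_numpy() + 1,
        "end": df["end"].astype(int).to_numpy(),
    }, index=pd.Index(df["gene_id"].astype(str).to_numpy(), name="gene_id"))
    return sort_annotation(ann)


def write_bed(annotation: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "chromosome": annotation["chromosome"],
        "start": annotation["start"].astype(int) - 1,
        "end": annotation["end"].astype(int),
        "gene_id": annotation.index,
    })
    out.to_csv(path, sep="\t", header=False, index=False)


_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def read_gtf(path) -> pd.DataFrame:
    """Minimal GTF reader: keeps `gene` feature records (GTF is 1-based inclusive)."""
    rows = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            m = _GTF_GENE_ID.search(parts[8])
            if not m:
                continue
            rows[m.group(1)] = (parts[0], int(parts[3]), int(parts[4]))
    if not rows:
        raise ValueError(f"{path}: no gene records found")
    ann = pd.DataFrame.from_dict(rows, orient="index", columns=["chromosome", "start", "end"])
    ann.index.name = "gene_id"
    return sort_annotation(ann)


# -- groups / labels ----------------------------------------------------------

def read_groups(path) -> pd.Series:
    """Two-column TSV (cell_id, group), with or without header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.iloc[0, 0] in ("cell_id", "cell"):
        df = df.iloc[1:]
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    if s.index.has_duplicates:
        raise ValueError(f"{path}: duplicate cell ids")
    return s


def write_groups(groups: pd.Series, path) -> None:
    groups.rename("group").to_csv(path, sep="\t", header=True, index_label="cell_id")


# -- copy-number segments -----------------------------------------------------

def read_seg(path, min_length: int = 10_000) -> SegmentSet:
    """SEG-style TSV: chromosome, start, end, log2_ratio (0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    try:
        seg = pd.DataFrame({
            "chromosome": df[cols.get("chromosome", cols.get("chrom"))].astype(str),
            "start": df[cols["start"]].astype(int),
            "end": df[cols["end"]].astype(int),
            "log2_ratio": df[cols.get("log2_ratio", cols.get("ratio", ""))].astype(float),
        })
    except KeyError as e:  # pragma: no cover - defensive
        raise ValueError(f"{path}: missing segment column {e}") from e
    return SegmentSet(seg, min_length=min_length)


def write_seg(segset: SegmentSet, path) -> None:
    segset.segments.to_csv(path, sep="\t", index=False)


# -- gene sets ----------------------------------------------------------------

def read_gmt(path) -> dict:
    """GMT: one set per line, name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *map(str, genes)]) + "\n")


# -- centroids and modules ----------------------------------------------------

def read_centroids(path) -> pd.DataFrame:
    """Signature-gene x subtype TSV of centroid expression values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 subtype columns")
    return df.astype(float)


def write_centroids(centroids: pd.DataFrame, path) -> None:
    centroids.to_csv(path, sep="\t", index_label="gene_id")


def read_module(path) -> pd.Series:
    """Two-column TSV (gene_id, weight) defining a signed gene module."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if isinstance(df.iloc[0, 1], str):
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].astype(float).values, index=df.iloc[:, 0].astype(str).values)


# -- config -------------------------------------------------------------------

def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
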