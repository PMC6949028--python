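"""Reading and writing the pipeline's on-disk formats.

Single-cell UMI matrices travel as 10x-style triplets: a MatrixMarket
coordinate file (genes as rows, 1-based indices), a ``features.tsv`` with
gene id / symbol / chromosome, and a ``barcodes.tsv``, plus a per-cell
metadata table keyed by barcode. In memory everything is an
:class:`anndata.AnnData` with counts in ``.X`` (CSR, genes come in as rows
on disk but AnnData is cells x genes), gene annotation in ``.var`` and
cell annotation in ``.obs``.

Result tables are plain delimited text with deterministic row order and
``NA`` for missing values, so runs are diff-able.
"""

from __future__ import annotations

import re
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .config import CHROMOSOMES

RIBO_RE = re.compile(r"^RP[LS]")

CELL_META_COLS = ["barcode", "library_id", "compartment", "group", "subject_id", "fetal_sex"]


class FormatError(ValueError):
    """Input file violates the declared format."""


def _check_genes(genes: pd.DataFrame) -> pd.DataFrame:
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene_id {dup!r} in features table")
    bad = set(genes["chromosome"].astype(str)) - set(CHROMOSOMES)
    if bad:
        raise FormatError(f"chromosome label(s) outside allowed set: {sorted(bad)}")
    genes = genes.copy()
    genes["is_ribosomal"] = genes["symbol"].astype(str).str.match(RIBO_RE)
    return genes


def read_10x_triplet(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    metadata_path: str | Path,
) -> ad.AnnData:
    """Read a 10x-convention triplet plus cell metadata into an AnnData.

    The MatrixMarket file has genes as rows and cells as columns with
    1-based indices; values must be non-negative integers. The metadata
    table must cover every barcode.
    """
    mat = scipy.io.mmread(str(matrix_path))
    if not sp.issparse(mat):
        mat = sp.coo_matrix(mat)
    data = np.asarray(mat.tocoo().data)
    if data.size and (np.any(data < 0) or not np.allclose(data, np.round(data))):
        raise FormatError("matrix entries must be non-negative integers")
    counts = sp.csr_matrix(mat.T.astype(np.int64))  # cells x genes

    genes = pd.read_csv(features_path, sep="\t", header=None,
                        names=["gene_id", "symbol", "chromosome"], dtype=str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, names=["barcode"], dtype=str)
    if counts.shape[1] != len(genes):
        raise FormatError(
            f"matrix declares {counts.shape[1]} genes but features table has {len(genes)}")
    if counts.shape[0] != len(barcodes):
        raise FormatError(
            f"matrix declares {counts.shape[0]} cells but barcodes table has {len(barcodes)}")

    genes = _check_genes(genes)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = set(CELL_META_COLS) - set(meta.columns)
    if missing_cols:
        raise FormatError(f"metadata table missing column(s): {sorted(missing_cols)}")
    meta = meta.set_index("barcode")
    absent = [b for b in barcodes["barcode"] if b not in meta.index]
    if absent:
        raise FormatError(f"barcode {absent[0]!r} missing from metadata table")
    obs = meta.loc[barcodes["barcode"]].reset_index()
    obs.index = obs["barcode"].astype(str)
    obs.index.name = None

    var = genes.set_index(genes["gene_id"].astype(str))
    var.index.name = None
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    return adata


def write_10x_triplet(adata: ad.AnnData, out_dir: str | Path) -> None:
    """Write an AnnData back out as matrix.mtx + features/barcodes/metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = sp.coo_matrix(adata.X.T.astype(np.int64))  # genes x cells on disk
    scipy.io.mmwrite(str(out / "matrix.mtx"), counts, field="integer")
    adata.var[["gene_id", "symbol", "chromosome"]].to_csv(
        out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs["barcode"].astype(str)).to_csv(
        out / "barcodes.tsv", sep="\t", header=False, index=False)
    adata.obs[CELL_META_COLS].to_csv(out / "cell_metadata.tsv", sep="\t", index=False)


def read_10x_dir(in_dir: str | Path) -> ad.AnnData:
    """Convenience reader for a directory written by :func:`write_10x_triplet`."""
    d = Path(in_dir)
    return read_10x_triplet(d / "matrix.mtx", d / "features.tsv",
                            d / "barcodes.tsv", d / "cell_metadata.tsv")


def write_results_table(table: pd.DataFrame, path: str | Path, sort_by: list[str] | None = None) -> None:
    """Write a result table as TSV: sorted rows, NA for missing.

    Rows are sorted by ``sort_by`` (default: all non-float columns in order),
    so output is deterministic regardless of upstream dict/group ordering.
    """
    df = table.copy()
    if sort_by is None:
        sort_by = [c for c in df.columns if not pd.api.types.is_float_dtype(df[c])]
    if sort_by:
        df = df.sort_values(sort_by, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA", keep_default_na=True)


def write_bulk_expression(expr: pd.DataFrame, samples: pd.DataFrame, prefix: str | Path) -> None:
    """Write a bulk set as <prefix>_expression.tsv (gene x sample) and
    <prefix>_samples.tsv."""
    prefix = Path(prefix)
    expr.to_csv(f"{prefix}_expression.tsv", sep="\t", na_rep="NA")
    samples.to_csv(f"{prefix}_samples.tsv", sep="\t", index=False, na_rep="NA")


def read_bulk_expression(prefix: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    prefix = Path(prefix)
    expr = pd.read_csv(f"{prefix}_expression.tsv", sep="\t", index_col=0, na_values="NA")
    samples = pd.read_csv(f"{prefix}_samples.tsv", sep="\t", na_values="NA")
    return expr, samples
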