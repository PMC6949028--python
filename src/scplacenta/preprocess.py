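"""Single-cell QC filtering, log-normalization, and variable-gene selection.

The QC rule set: keep cells with at least ``min_genes_per_cell`` detected
(count>0) genes and mitochondrial count fraction at or below
``max_mito_fraction``; then keep genes detected in at least
``min_cells_per_gene`` of the retained cells. Both cell filters run on
the raw matrix, the gene filter once on the survivors — a single pass,
no iteration to a fixpoint.

Normalization: value = ln(1 + count * scale_factor / cell_total), with
scale_factor 10,000 by default; zeros stay zero.

Variable genes: per gene, the mean and the log variance/mean ratio of the
exponentiated (count-scale) values, z-scored within 20 equal-width mean
bins; genes inside the mean window with z-dispersion above the cutoff are
selected, then ribosomal (RPL/RPS) and mitochondrial genes are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import scipy.sparse as sp

from .config import RunConfig

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Reconciled filter tallies: in - removed = out on both axes."""

    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    n_cells_low_genes: int
    n_cells_high_mito: int
    n_genes_low_cells: int

    def __post_init__(self) -> None:
        assert self.n_cells_in - self.n_cells_low_genes - self.n_cells_high_mito == self.n_cells_out
        assert self.n_genes_in - self.n_genes_low_cells == self.n_genes_out

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _counts(adata: ad.AnnData) -> sp.csr_matrix:
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    return X.tocsr()


def filter_cells_genes(adata: ad.AnnData, cfg: RunConfig) -> tuple[ad.AnnData, QCReport]:
    """Apply the cell filters then the gene filter; return the kept matrix
    and a reconciled report.

    A cell failing both rules is tallied once, under the detected-gene
    rule (applied first).
    """
    X = _counts(adata)
    n_cells, n_genes = X.shape

    detected = (X > 0).sum(axis=1).A1
    total = np.asarray(X.sum(axis=1)).ravel().astype(float)
    mt_mask = (adata.var["chromosome"].astype(str) == "MT").to_numpy()
    if not mt_mask.any() and cfg.max_mito_fraction < 1.0:
        logger.warning("no MT-annotated genes: mitochondrial filter is vacuous")
    mt_total = np.asarray(X[:, mt_mask].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mt_total / np.maximum(total, 1), 0.0)

    low_genes = detected < cfg.min_genes_per_cell
    high_mito = (mito_frac > cfg.max_mito_fraction) & ~low_genes
    keep_cells = ~low_genes & ~high_mito

    Xc = X[keep_cells]
    detected_per_gene = (Xc > 0).sum(axis=0).A1
    keep_genes = detected_per_gene >= cfg.min_cells_per_gene

    out = adata[keep_cells, keep_genes].copy()
    report = QCReport(
        n_cells_in=n_cells,
        n_cells_out=int(keep_cells.sum()),
        n_genes_in=n_genes,
        n_genes_out=int(keep_genes.sum()),
        n_cells_low_genes=int(low_genes.sum()),
        n_cells_high_mito=int(high_mito.sum()),
        n_genes_low_cells=int((~keep_genes).sum()),
    )
    return out, report


def log_normalize(adata: ad.AnnData, cfg: RunConfig) -> ad.AnnData:
    """Library-size normalize to ``scale_factor`` counts per cell and take
    ln(1 + x). Sparsity is preserved; raw counts are kept in
    ``layers['counts']``."""
    X = _counts(adata).astype(float)
    total = np.asarray(X.sum(axis=1)).ravel()
    if np.any(total <= 0):
        raise ValueError("cell(s) with zero total counts: run filter_cells_genes first")
    norm = X.multiply(cfg.scale_factor / total[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out = adata.copy()
    out.layers["counts"] = _counts(adata)
    out.X = norm
    out.uns["normalization"] = {"method": "log_normalize", "scale_factor": cfg.scale_factor}
    return out


def select_hvg(adata: ad.AnnData, cfg: RunConfig) -> list[str]:
    """Select highly variable genes on the dispersion-of-exponentiated-values
    criterion, then drop ribosomal and mitochondrial genes.

    Returns the selected gene_ids (matrix order).
    """
    if adata.n_obs < 2:
        raise ValueError("need at least 2 cells for dispersion estimates")
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    E = X.copy().tocsr()
    E.data = np.expm1(E.data)

    n = E.shape[0]
    mean = np.asarray(E.mean(axis=0)).ravel()
    sq = E.copy()
    sq.data = sq.data ** 2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = (ex2 - mean ** 2) * n / max(n - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.log(var / mean)
    dispersion[~np.isfinite(dispersion)] = np.nan  # constant/zero genes drop out

    n_bins = cfg.hvg_n_bins
    finite_means = mean[np.isfinite(mean)]
    if np.unique(finite_means).size < n_bins:
        n_bins = max(int(np.unique(finite_means).size), 1)
        logger.warning("fewer distinct gene means than bins; reducing to %d bins", n_bins)
    edges = np.linspace(mean.min(), mean.max(), n_bins + 1)
    bin_of = np.clip(np.digitize(mean, edges[1:-1]), 0, n_bins - 1)

    z = np.full(mean.shape, np.nan)
    for b in range(n_bins):
        in_bin = (bin_of == b) & ~np.isnan(dispersion)
        if in_bin.sum() == 0:
            continue
        d = dispersion[in_bin]
        sd = d.std(ddof=1) if in_bin.sum() > 1 else 0.0
        if sd == 0:
            z[in_bin] = 0.0
        else:
            z[in_bin] = (d - d.mean()) / sd

    selected = ((mean >= cfg.hvg_mean_low) & (mean <= cfg.hvg_mean_high)
                & (z >= cfg.hvg_dispersion_z))
    ribo = adata.var["is_ribosomal"].to_numpy(dtype=bool)
    mito = (adata.var["chromosome"].astype(str) == "MT").to_numpy()
    selected &= ~ribo & ~mito
    return list(adata.var.loc[selected, "gene_id"])
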