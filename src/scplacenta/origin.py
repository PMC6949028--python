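"""Maternal/fetal origin of cell clusters via the Y-read fetal index.

In pregnancies with a male fetus, fetal cells carry a Y chromosome and
maternal cells do not, so the ratio of UMIs on Y-chromosome genes to
UMIs on autosomal genes (chromosomes 1-22; X and MT excluded) separates
fetal from maternal clusters. The index is computed per cluster over
cells from male-fetus pregnancies only.

The origin call is an artifact of this package, not a published rule:
clusters are split into two groups on log10(index + eps) at the
threshold maximizing between-group variance (Otsu's criterion in one
dimension); the higher-mean group is called fetal, and clusters within
``origin_margin`` log10 units of the threshold are left indeterminate.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import AUTOSOMES, RunConfig

logger = logging.getLogger(__name__)


def compute_fetal_index(adata: ad.AnnData, labels: pd.Series,
                        per_cell: bool = False) -> pd.DataFrame:
    """Per-cluster Y/autosome UMI ratio over male-fetus cells.

    Parameters
    ----------
    labels : cluster assignment indexed like ``adata.obs`` (or aligned
        positionally).
    per_cell : also return a per-cell index table for diagnostics
        (columns barcode, cluster_id, y_count, autosome_count, fetal_index).
    """
    chrom = adata.var["chromosome"].astype(str).to_numpy()
    y_mask = chrom == "Y"
    auto_mask = np.isin(chrom, AUTOSOMES)

    male = (adata.obs["fetal_sex"].astype(str) == "male").to_numpy()
    if not male.any():
        raise ValueError("no male-fetus samples: the Y-read fetal index is undefined")

    labels = pd.Series(np.asarray(labels), index=adata.obs_names)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    y_counts = np.asarray(X[:, y_mask].sum(axis=1)).ravel()
    auto_counts = np.asarray(X[:, auto_mask].sum(axis=1)).ravel()

    rows = []
    cell_rows = []
    for cl in sorted(pd.unique(labels)):
        in_cl = (labels == cl).to_numpy() & male
        y = int(y_counts[in_cl].sum())
        a = int(auto_counts[in_cl].sum())
        if a == 0:
            logger.warning("cluster %s has zero autosomal counts among male-fetus cells", cl)
            idx = np.nan
        else:
            idx = y / a
        rows.append({"cluster_id": cl, "y_count": y, "autosome_count": a,
                     "fetal_index": idx, "n_cells_used": int(in_cl.sum()),
                     "origin_call": "indeterminate"})
        if per_cell:
            for i in np.where(in_cl)[0]:
                ac = auto_counts[i]
                cell_rows.append({"barcode": adata.obs_names[i], "cluster_id": cl,
                                  "y_count": int(y_counts[i]), "autosome_count": int(ac),
                                  "fetal_index": y_counts[i] / ac if ac > 0 else np.nan})
    table = pd.DataFrame(rows)
    if per_cell:
        return table, pd.DataFrame(cell_rows)
    return table


def _otsu_split(values: np.ndarray) -> float | None:
    """Threshold maximizing between-class variance for a 1-d sample.

    Candidate thresholds are midpoints between consecutive sorted unique
    values; returns None when no split exists (fewer than 2 distinct
    values)."""
    v = np.sort(values)
    uniq = np.unique(v)
    if uniq.size < 2:
        return None
    best_t, best_score = None, -np.inf
    for a, b in zip(uniq[:-1], uniq[1:]):
        t = (a + b) / 2.0
        lo, hi = v[v <= t], v[v > t]
        w0, w1 = lo.size / v.size, hi.size / v.size
        score = w0 * w1 * (hi.mean() - lo.mean()) ** 2
        if score > best_score:
            best_score, best_t = score, t
    return best_t


def classify_origin(table: pd.DataFrame, cfg: RunConfig | None = None) -> pd.DataFrame:
    """Call maternal/fetal per cluster from the fetal-index table.

    Otsu split on log10(fetal_index + eps); higher group is fetal;
    clusters within ``origin_margin`` of the split are indeterminate.
    Calls are invariant to uniform depth scaling (the index is a ratio).
    """
    cfg = cfg or RunConfig()
    out = table.copy()
    out["origin_call"] = "indeterminate"
    valid = out["fetal_index"].notna()
    if valid.sum() < 2:
        return out
    logv = np.log10(out.loc[valid, "fetal_index"].to_numpy() + cfg.origin_epsilon)
    t = _otsu_split(logv)
    if t is None:  # all indices identical
        return out
    calls = np.where(logv > t, "fetal", "maternal")
    calls[np.abs(logv - t) < cfg.origin_margin] = "indeterminate"
    out.loc[valid, "origin_call"] = calls
    return out
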