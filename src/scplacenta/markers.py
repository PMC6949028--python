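"""One-vs-rest marker detection and construction of cell-type signatures.

For each cluster, genes passing the expression prefilters (detected in at
least 25% of cells inside or outside the cluster, and absolute log fold
change of at least 0.25) are tested with a two-sided Wilcoxon rank-sum
test of their log-normalized values, cluster vs all other cells, with BH
correction within each cluster's tested genes.

The log fold change is the difference of mean log-normalized values
(natural-log scale), cluster minus rest — not the log of the ratio of
means. This choice affects signature membership and is therefore the
documented ranking convention throughout the package.

Signatures are the top genes per cluster — up to ``signature_size`` (20),
q below ``signature_q_threshold`` and positive fold change, ranked by
decreasing fold change, ties broken lexicographically by gene_id.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import RunConfig
from .stats import bh_fdr, rank_sum_test

logger = logging.getLogger(__name__)

MIN_CELLS_PER_CLUSTER = 3


def find_markers(adata: ad.AnnData, labels: pd.Series, cfg: RunConfig | None = None) -> pd.DataFrame:
    """One-vs-rest marker table over all clusters.

    ``adata`` must hold log-normalized values in ``.X``. Returns columns
    cluster_id, gene_id, log_fc, pct_in, pct_out, p_value, q_value.
    Clusters with fewer than 3 cells are skipped with a warning.
    """
    cfg = cfg or RunConfig()
    labels = pd.Series(np.asarray(labels), index=adata.obs_names)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    X = X.tocsr()
    dense = np.asarray(X.todense())
    gene_ids = adata.var["gene_id"].to_numpy()

    frames = []
    for cl in sorted(pd.unique(labels)):
        in_cl = (labels == cl).to_numpy()
        n_in = int(in_cl.sum())
        if n_in < MIN_CELLS_PER_CLUSTER:
            logger.warning("cluster %s has %d cells (<%d); skipped", cl, n_in, MIN_CELLS_PER_CLUSTER)
            continue
        mean_in = dense[in_cl].mean(axis=0)
        mean_out = dense[~in_cl].mean(axis=0)
        log_fc = mean_in - mean_out
        pct_in = (dense[in_cl] > 0).mean(axis=0)
        pct_out = (dense[~in_cl] > 0).mean(axis=0)

        tested = (((pct_in >= cfg.marker_min_pct) | (pct_out >= cfg.marker_min_pct))
                  & (np.abs(log_fc) >= cfg.marker_min_logfc))
        if not tested.any():
            continue
        p = rank_sum_test(dense[:, tested], in_cl)
        q = bh_fdr(p)
        frames.append(pd.DataFrame({
            "cluster_id": cl,
            "gene_id": gene_ids[tested],
            "log_fc": log_fc[tested],
            "pct_in": pct_in[tested],
            "pct_out": pct_out[tested],
            "p_value": p,
            "q_value": q,
        }))
    if not frames:
        return pd.DataFrame(columns=["cluster_id", "gene_id", "log_fc", "pct_in",
                                     "pct_out", "p_value", "q_value"])
    return pd.concat(frames, ignore_index=True)


def build_signatures(markers: pd.DataFrame, cfg: RunConfig | None = None) -> dict[str, pd.DataFrame]:
    """Top fold-change-ranked signature per cluster.

    Returns cluster_id -> DataFrame (gene_id, log_fc), sorted by
    decreasing log_fc (gene_id breaks ties), at most ``signature_size``
    rows, all with q < ``signature_q_threshold`` and log_fc > 0.
    """
    cfg = cfg or RunConfig()
    out: dict[str, pd.DataFrame] = {}
    for cl, sub in markers.groupby("cluster_id", sort=True):
        qual = sub[(sub["q_value"] < cfg.signature_q_threshold) & (sub["log_fc"] > 0)]
        qual = qual.sort_values(["log_fc", "gene_id"], ascending=[False, True],
                                kind="mergesort")
        if qual.empty:
            logger.warning("cluster %s has no qualifying markers; empty signature", cl)
        out[str(cl)] = qual.head(cfg.signature_size)[["gene_id", "log_fc"]].reset_index(drop=True)
    return out


def signatures_to_table(signatures: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Flatten a signature set to a (cluster_id, rank, gene_id, log_fc) table."""
    rows = []
    for cl in sorted(signatures):
        for rank, rec in enumerate(signatures[cl].itertuples(index=False), start=1):
            rows.append({"cluster_id": cl, "rank": rank,
                         "gene_id": rec.gene_id, "log_fc": rec.log_fc})
    return pd.DataFrame(rows, columns=["cluster_id", "rank", "gene_id", "log_fc"])


def table_to_signatures(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    out = {}
    for cl, sub in table.groupby("cluster_id", sort=True):
        sub = sub.sort_values("rank")
        out[str(cl)] = sub[["gene_id", "log_fc"]].reset_index(drop=True)
    return out
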