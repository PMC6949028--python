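#!/usr/bin/env python
"""QC-filter and log-normalize the simulated single-cell dataset.

Applies the study's filters (>=200 detected genes per cell, mito fraction
<=10%, genes detected in >=10 cells), log-normalizes to 10,000 counts per
cell, and selects highly variable genes. Writes the QC report and HVG
list under results/qc/.
"""

from pathlib import Path

import pandas as pd

from scplacenta import RunConfig, filter_cells_genes, log_normalize, select_hvg
from scplacenta.io import read_10x_dir, write_results_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig()
    adata = read_10x_dir(ROOT / "data" / "sc")
    truth = pd.read_csv(ROOT / "data" / "sc" / "truth_cells.tsv", sep="\t")

    filtered, rep = filter_cells_genes(adata, cfg)
    pd.DataFrame([rep.to_dict()]).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    print(f"cells: {rep.n_cells_in} -> {rep.n_cells_out} "
          f"({rep.n_cells_low_genes} below the gene floor, "
          f"{rep.n_cells_high_mito} above the mito cutoff); "
          f"genes: {rep.n_genes_in} -> {rep.n_genes_out}")

    lq = set(truth.loc[truth["low_quality"], "barcode"])
    kept = set(filtered.obs["barcode"])
    print(f"all {len(lq)} injected low-quality cells removed: {kept.isdisjoint(lq)}")

    nm = log_normalize(filtered, cfg)
    hvg = select_hvg(nm, cfg)
    write_results_table(pd.DataFrame({"gene_id": hvg}), out / "hvg.tsv",
                        sort_by=["gene_id"])
    print(f"{len(hvg)} highly variable genes after removing ribosomal/mito genes")


if __name__ == "__main__":
    main()
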