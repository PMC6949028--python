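#!/usr/bin/env python
"""Generate the synthetic study inputs every later step consumes.

Emits, under results/data/:
  * a single-cell UMI dataset (10x-style triplet + cell metadata + ground
    truth): 6 cell types x 3 placental compartments (BP/PV/CAM) x 3 study
    groups (TNL/TIL/PTL), 40 cells per block, with a maternal/fetal
    mixture, mitochondrial content and ~5% injected low-quality cells;
  * a longitudinal maternal-blood cohort (8 TIL + 8 TNL subjects, 3
    samples each, 12-40 weeks) with gestational-age and labor effects
    planted on half of the 10 signature gene sets;
  * a cross-sectional preterm cohort (15 PTL vs 23 GA-matched controls,
    24-34 weeks) with a mean shift planted on 3 signatures.
"""

from pathlib import Path

import pandas as pd

from scplacenta import (BulkSimConfig, ScSimConfig, simulate_bulk_crosssection,
                        simulate_bulk_longitudinal, simulate_sc_dataset)
from scplacenta import io as pio

SEED = 2026
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    adata, truth = simulate_sc_dataset(ScSimConfig(seed=SEED))
    pio.write_10x_triplet(adata, OUT / "sc")
    pio.write_results_table(truth.cells, OUT / "sc" / "truth_cells.tsv",
                            sort_by=["barcode"])
    pio.write_results_table(truth.genes.fillna("NA"), OUT / "sc" / "truth_genes.tsv",
                            sort_by=["gene_id"])
    lq = truth.cells["low_quality"].mean()
    print(f"single-cell: {adata.n_obs} cells x {adata.n_vars} genes, "
          f"{lq:.1%} injected low-quality cells")

    bulk, btruth = simulate_bulk_longitudinal(BulkSimConfig(seed=SEED + 1))
    pio.write_bulk_expression(bulk.expression, bulk.samples, OUT / "bulk_long")
    pio.write_results_table(btruth.signatures, OUT / "bulk_long_truth.tsv",
                            sort_by=["signature_id"])
    rows = [{"signature_id": s, "gene_id": g}
            for s, genes in btruth.signature_genes.items() for g in genes]
    pio.write_results_table(pd.DataFrame(rows), OUT / "bulk_signature_genes.tsv",
                            sort_by=["signature_id", "gene_id"])
    print(f"longitudinal blood: {bulk.expression.shape[1]} samples, "
          f"{int((btruth.signatures['ga_slope'] != 0).sum())} GA-modulated signatures")

    xbulk, xtruth = simulate_bulk_crosssection(
        BulkSimConfig(seed=SEED + 2, design="crosssection_preterm"))
    pio.write_bulk_expression(xbulk.expression, xbulk.samples, OUT / "bulk_cross")
    pio.write_results_table(xtruth.signatures, OUT / "bulk_cross_truth.tsv",
                            sort_by=["signature_id"])
    print(f"cross-sectional blood: {xbulk.expression.shape[1]} samples, "
          f"{int((xtruth.signatures['ptl_shift'] != 0).sum())} shifted signatures")


if __name__ == "__main__":
    main()
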