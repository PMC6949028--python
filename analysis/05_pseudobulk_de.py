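#!/usr/bin/env python
"""Pseudobulk NB differential expression across compartments and labor groups.

Aggregates cells per (subject, compartment, cell type) for the
compartment contrast (CAM vs PV, subject as fixed effect) and per
(subject, cell type) pooled across compartments for the labor contrasts
(TIL vs TNL, PTL vs TNL), under the 100-cell rule. Effect sizes of the
two labor contrasts are then compared per gene and cell type at q<0.01
(shared / TIL-only / PTL-only). Writes results/de/*.tsv.

Note: the default generator plants cluster markers but no labor effects,
so the labor contrasts here are a calibration readout (few or no calls
expected); planted-effect power is exercised in the test suite and
acceptance script at pseudobulk level.
"""

from pathlib import Path

import pandas as pd

from scplacenta import (RunConfig, aggregate_pseudobulk, compare_labor_effects,
                        nb_glm_de)
from scplacenta.io import read_10x_dir, write_results_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "de"
    out.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig()
    adata = read_10x_dir(ROOT / "data" / "sc")
    cells = pd.read_csv(ROOT / "data" / "sc" / "truth_cells.tsv", sep="\t")
    labels = cells.set_index("barcode")["true_cluster"].reindex(adata.obs["barcode"])

    pb_loc = aggregate_pseudobulk(adata, labels, "by_location", cfg)
    de_loc = nb_glm_de(pb_loc, ["subject_id", "compartment"],
                       ("compartment", "CAM", "PV"), cfg)
    write_results_table(de_loc, out / "de_cam_vs_pv.tsv",
                        sort_by=["cell_type", "gene_id"])
    print(f"CAM vs PV: {int(de_loc['significant'].sum())} significant genes "
          f"of {len(de_loc)} tests across {de_loc['cell_type'].nunique()} cell types")

    pb_grp = aggregate_pseudobulk(adata, labels, "by_group", cfg)
    de_til = nb_glm_de(pb_grp, ["group"], ("group", "TIL", "TNL"), cfg)
    de_ptl = nb_glm_de(pb_grp, ["group"], ("group", "PTL", "TNL"), cfg)
    write_results_table(de_til, out / "de_til_vs_tnl.tsv",
                        sort_by=["cell_type", "gene_id"])
    write_results_table(de_ptl, out / "de_ptl_vs_tnl.tsv",
                        sort_by=["cell_type", "gene_id"])
    print(f"TIL vs TNL: {int(de_til['significant'].sum())} significant; "
          f"PTL vs TNL: {int(de_ptl['significant'].sum())} significant "
          f"(no labor effects planted: calls reflect the null)")

    # 3 fetal trophoblast-like + 3 maternal decidual-like clusters
    class_map = {"CT0": "trophoblast", "CT1": "trophoblast", "CT2": "trophoblast",
                 "CT3": "stromal/endothelial", "CT4": "immune", "CT5": "immune"}
    pairs, corr = compare_labor_effects(de_til, de_ptl, class_map, cfg)
    write_results_table(pairs, out / "labor_effect_pairs.tsv",
                        sort_by=["cell_type", "gene_id"])
    write_results_table(corr, out / "labor_effect_correlation.tsv",
                        sort_by=["cell_class"])
    print("effect-size correlation by major cell class:")
    print(corr.to_string(index=False))


if __name__ == "__main__":
    main()
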