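#!/usr/bin/env python
"""Project signatures into the maternal-blood cohorts and test them.

Longitudinal cohort: mean-log2 signature scores, mixed-effects quadratic
spline in gestational age (LRT vs flat, BH q<0.1) and the TIL vs TNL
equal-variance t-test. Cross-sectional cohort: control-anchored mean-Z
scores, PTL vs control Wilcoxon. Compares every call against the planted
truth and writes results/projection/*.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from scplacenta import (BulkExpressionSet, RunConfig, compare_ptl_control,
                        compare_til_tnl, fit_ga_trajectory, score_signatures_mean,
                        score_signatures_zscore)
from scplacenta.io import read_bulk_expression, write_results_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def _signatures():
    table = pd.read_csv(ROOT / "data" / "bulk_signature_genes.tsv", sep="\t")
    return {s: pd.DataFrame({"gene_id": grp["gene_id"].tolist(), "log_fc": np.nan})
            for s, grp in table.groupby("signature_id")}


def main() -> None:
    out = ROOT / "projection"
    out.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig()
    sigs = _signatures()

    expr, samples = read_bulk_expression(ROOT / "data" / "bulk_long")
    bulk = BulkExpressionSet(expression=expr, samples=samples)
    truth = pd.read_csv(ROOT / "data" / "bulk_long_truth.tsv", sep="\t"
                        ).set_index("signature_id")

    scores = score_signatures_mean(bulk, sigs, cfg)
    fit = fit_ga_trajectory(scores, bulk, cfg)
    write_results_table(fit.drop(columns=["coef"], errors="ignore"),
                        out / "ga_trajectories.tsv", sort_by=["signature_id"])
    flagged = set(fit.loc[fit["significant"], "signature_id"])
    planted = set(truth.index[truth["ga_slope"] != 0])
    print(f"GA trajectories: flagged {sorted(flagged)}; planted {sorted(planted)}")

    # the term-labor comparison is at delivery: use each subject's last visit
    last = samples.sort_values("gestational_age").groupby("subject_id").tail(1)
    term = BulkExpressionSet(expression=expr[last["sample_id"]],
                             samples=last.reset_index(drop=True))
    ttest = compare_til_tnl(scores.loc[last["sample_id"]], term, cfg)
    write_results_table(ttest, out / "til_vs_tnl.tsv", sort_by=["signature_id"])
    labor_planted = set(truth.index[truth["labor_effect"] != 0])
    print(f"TIL vs TNL t-test (term visits): flagged "
          f"{sorted(ttest.loc[ttest['significant'], 'signature_id'])}; "
          f"planted labor effect on {sorted(labor_planted)}")

    xexpr, xsamples = read_bulk_expression(ROOT / "data" / "bulk_cross")
    xbulk = BulkExpressionSet(expression=xexpr, samples=xsamples)
    xtruth = pd.read_csv(ROOT / "data" / "bulk_cross_truth.tsv", sep="\t"
                         ).set_index("signature_id")
    zscores = score_signatures_zscore(xbulk, sigs, "GA_control", cfg)
    wil = compare_ptl_control(zscores, xbulk, cfg)
    write_results_table(wil, out / "ptl_vs_control.tsv", sort_by=["signature_id"])
    shifted = set(xtruth.index[xtruth["ptl_shift"] != 0])
    print(f"PTL vs control Wilcoxon: flagged "
          f"{sorted(wil.loc[wil['significant'], 'signature_id'])}; "
          f"planted shift on {sorted(shifted)}")


if __name__ == "__main__":
    main()
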