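"""Projection of single-cell signatures into bulk maternal-blood expression.

A cluster's signature (up to 20 genes ranked by fold change) is scored in
each bulk sample either as the plain mean of the member genes' log2
values, or as the mean of per-gene Z-scores standardized against a
control group. Scores are then tested three ways, mirroring the three
blood analyses:

* gestational-age trajectories — linear mixed-effects model with a
  quadratic (degree-2) B-spline in gestational age and a per-subject
  random intercept, fitted by maximum likelihood and compared by
  likelihood-ratio test to the intercept-only mixed model; restricted to
  subjects with exactly three longitudinal samples;
* term labor (TIL vs TNL) — two-tailed equal-variance t-tests;
* preterm labor (PTL vs GA-matched controls) — two-tailed Wilcoxon
  rank-sum tests.

All three are BH-corrected across signatures at q < 0.1.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.stats
from scipy.interpolate import BSpline
import statsmodels.api as sm

from .config import RunConfig
from .simulate import BulkExpressionSet
from .stats import bh_fdr, pooled_t_test, rank_sum_test

logger = logging.getLogger(__name__)

SPLINE_DEGREE = 2


def _score_table(bulk: BulkExpressionSet, signatures: dict, cfg: RunConfig,
                 values: pd.DataFrame) -> pd.DataFrame:
    """Mean of `values` rows over each signature's measured member genes."""
    rows = {}
    n_used = {}
    measured = set(values.index)
    any_overlap = False
    for sig_id in sorted(signatures):
        genes = [g for g in signatures[sig_id]["gene_id"]] \
            if isinstance(signatures[sig_id], pd.DataFrame) else list(signatures[sig_id])
        present = [g for g in genes if g in measured]
        n_used[sig_id] = len(present)
        if present:
            any_overlap = True
        if len(present) < cfg.min_signature_genes_bulk:
            rows[sig_id] = pd.Series(np.nan, index=values.columns)
        else:
            rows[sig_id] = values.loc[present].mean(axis=0)
    if not any_overlap:
        missing = {s: list(signatures[s]["gene_id"]) if isinstance(signatures[s], pd.DataFrame)
                   else list(signatures[s]) for s in signatures}
        raise ValueError(f"no signature gene measured in the bulk panel; missing: {missing}")
    out = pd.DataFrame(rows)          # samples x signatures
    out.index.name = "sample_id"
    out.attrs["n_genes_used"] = n_used
    return out


def score_signatures_mean(bulk: BulkExpressionSet, signatures: dict,
                          cfg: RunConfig | None = None) -> pd.DataFrame:
    """Mean-log2 signature scores: samples x signatures DataFrame.

    Member genes absent from the bulk panel are dropped; a score is NaN
    when fewer than ``min_signature_genes_bulk`` member genes are
    measured. Per-signature measured-gene counts are in
    ``.attrs['n_genes_used']``.
    """
    cfg = cfg or RunConfig()
    return _score_table(bulk, signatures, cfg, bulk.expression)


def score_signatures_zscore(bulk: BulkExpressionSet, signatures: dict,
                            control_group: str,
                            cfg: RunConfig | None = None) -> pd.DataFrame:
    """Mean-Z signature scores standardized against ``control_group``.

    Per gene, Z = (x - control mean) / control sd; genes with zero
    control sd are dropped with a warning.
    """
    cfg = cfg or RunConfig()
    ctrl = bulk.samples.loc[bulk.samples["group"] == control_group, "sample_id"]
    if len(ctrl) == 0:
        raise ValueError(f"control group {control_group!r} absent from samples")
    if len(ctrl) < 3:
        raise ValueError(f"control group {control_group!r} has {len(ctrl)} samples (<3)")
    mu = bulk.expression[ctrl].mean(axis=1)
    sd = bulk.expression[ctrl].std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning("dropping %d zero-variance gene(s) from Z-scoring", int((~keep).sum()))
    z = bulk.expression.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return _score_table(bulk, signatures, cfg, z)


def quadratic_spline_basis(ga: np.ndarray, knot: float,
                           lo: float, hi: float) -> np.ndarray:
    """Degree-2 B-spline basis on [lo, hi] with one interior knot.

    Returns an (n, 4) design block (4 = 1 interior knot + degree + 1);
    the model using it carries no separate intercept since the basis
    sums to one.
    """
    t = np.concatenate([[lo] * (SPLINE_DEGREE + 1), [knot], [hi] * (SPLINE_DEGREE + 1)])
    ga = np.clip(np.asarray(ga, float), lo, hi)
    return BSpline.design_matrix(ga, t, SPLINE_DEGREE).toarray()


def fit_ga_trajectory(scores: pd.DataFrame, bulk: BulkExpressionSet,
                      cfg: RunConfig | None = None) -> pd.DataFrame:
    """Mixed-effects quadratic-spline test for gestational-age trajectories.

    Subjects contribute only if they have exactly three longitudinal
    samples. Per signature: ML fit of score ~ spline(GA) + (1|subject),
    LRT against score ~ 1 + (1|subject); BH across signatures; q < 0.1.
    On a singular random-effects fit the model falls back to fixed
    effects only (OLS) with a warning.
    """
    cfg = cfg or RunConfig()
    samples = bulk.samples.copy()
    counts = samples.groupby("subject_id")["sample_id"].count()
    keep_subj = counts.index[counts == 3]
    samples = samples[samples["subject_id"].isin(keep_subj)]
    if samples["subject_id"].nunique() < 6:
        raise ValueError("need at least 6 subjects with exactly 3 samples")

    ga = samples["gestational_age"].to_numpy(float)
    knot = float(np.median(ga))
    basis = quadratic_spline_basis(ga, knot, ga.min(), ga.max())
    groups = samples["subject_id"].to_numpy()
    n_fixed_full, n_fixed_null = basis.shape[1], 1
    df_lrt = n_fixed_full - n_fixed_null

    rows = []
    for sig_id in scores.columns:
        y = scores.loc[samples["sample_id"], sig_id].to_numpy(float)
        ok = ~np.isnan(y)
        rec = {"signature_id": sig_id, "knot_ga": knot, "lrt_stat": np.nan,
               "p_value": np.nan, "used_mixed": True,
               "n_samples": int(ok.sum()),
               "n_subjects": int(pd.Series(groups[ok]).nunique())}
        if ok.sum() < 3 * 6:
            rec["used_mixed"] = False
            rows.append(rec)
            continue
        yv, Xv, gv = y[ok], basis[ok], groups[ok]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = sm.MixedLM(yv, Xv, groups=gv).fit(reml=False)
                null = sm.MixedLM(yv, np.ones((yv.size, 1)), groups=gv).fit(reml=False)
            if not (np.isfinite(full.llf) and np.isfinite(null.llf)):
                raise np.linalg.LinAlgError("non-finite likelihood")
            lrt = 2.0 * (full.llf - null.llf)
            rec["coef"] = list(full.fe_params)
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("signature %s: mixed fit failed (%s); fixed-effects fallback",
                           sig_id, exc)
            rec["used_mixed"] = False
            full = sm.OLS(yv, Xv).fit()
            null = sm.OLS(yv, np.ones((yv.size, 1))).fit()
            lrt = 2.0 * (full.llf - null.llf)
            rec["coef"] = list(full.params)
        lrt = max(lrt, 0.0)
        rec["lrt_stat"] = lrt
        rec["p_value"] = float(scipy.stats.chi2.sf(lrt, df_lrt))
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["bh_q"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = (out["bh_q"] < cfg.projection_q_threshold).fillna(False)
    return out


def _group_scores(scores: pd.DataFrame, bulk: BulkExpressionSet,
                  group_a: str, group_b: str):
    sa = bulk.samples.loc[bulk.samples["group"] == group_a, "sample_id"]
    sb = bulk.samples.loc[bulk.samples["group"] == group_b, "sample_id"]
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(f"both groups need >=2 samples ({group_a}: {len(sa)}, "
                         f"{group_b}: {len(sb)})")
    return scores.loc[sa], scores.loc[sb]


def compare_til_tnl(scores: pd.DataFrame, bulk: BulkExpressionSet,
                    cfg: RunConfig | None = None,
                    group_a: str = "TIL", group_b: str = "TNL") -> pd.DataFrame:
    """Equal-variance two-tailed t-test per signature, group_a vs group_b."""
    cfg = cfg or RunConfig()
    A, B = _group_scores(scores, bulk, group_a, group_b)
    rows = []
    for sig_id in scores.columns:
        a = A[sig_id].dropna().to_numpy()
        b = B[sig_id].dropna().to_numpy()
        rec = {"signature_id": sig_id, "test": "t_equal_var",
               "statistic": np.nan, "p_value": np.nan, "direction": "none"}
        if a.size >= 2 and b.size >= 2:
            pooled_var = (np.var(a, ddof=1) * (a.size - 1)
                          + np.var(b, ddof=1) * (b.size - 1))
            if pooled_var == 0:
                logger.warning("signature %s: zero pooled variance; p left missing", sig_id)
            else:
                t, p = pooled_t_test(a, b)
                rec.update(statistic=t, p_value=p,
                           direction="up" if a.mean() > b.mean() else
                                     ("down" if a.mean() < b.mean() else "none"))
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["bh_q"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = (out["bh_q"] < cfg.projection_q_threshold).fillna(False)
    return out


def compare_ptl_control(scores: pd.DataFrame, bulk: BulkExpressionSet,
                        cfg: RunConfig | None = None,
                        group_a: str = "PTL", group_b: str = "GA_control") -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum per signature, group_a vs group_b."""
    cfg = cfg or RunConfig()
    A, B = _group_scores(scores, bulk, group_a, group_b)
    rows = []
    for sig_id in scores.columns:
        a = A[sig_id].dropna().to_numpy()
        b = B[sig_id].dropna().to_numpy()
        rec = {"signature_id": sig_id, "test": "wilcoxon",
               "statistic": np.nan, "p_value": np.nan, "direction": "none"}
        if a.size >= 2 and b.size >= 2:
            x = np.concatenate([a, b])
            mask = np.zeros(x.size, bool)
            mask[: a.size] = True
            p = float(rank_sum_test(x[:, None], mask)[0])
            ranks = scipy.stats.rankdata(x)
            u1 = ranks[mask].sum() - a.size * (a.size + 1) / 2.0
            rec.update(statistic=u1, p_value=p,
                       direction="up" if np.median(a) > np.median(b) else
                                 ("down" if np.median(a) < np.median(b) else "none"))
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["bh_q"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = (out["bh_q"] < cfg.projection_q_threshold).fillna(False)
    return out
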