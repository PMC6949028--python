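"""Pseudobulk aggregation and negative-binomial differential expression.

Cells of the same cell type are summed into pseudobulk units — per
(subject, compartment, cell type) for the compartment analysis, per
(subject, cell type) with counts pooled across compartments for the
study-group analysis. A cell type enters an analysis only if it has at
least ``min_cells_per_pseudobulk`` (100) cells in every compartment
(respectively every study group).

Per cell type and gene, expression is modeled as NB(mu, alpha) with
variance mu + alpha*mu^2, log link, and an offset of log size factors
(median-of-ratios across units, total-count fallback). The dispersion
alpha is estimated by maximizing the Cox-Reid-adjusted profile
log-likelihood (the NB log-likelihood at the profile coefficient
estimates minus 0.5*logdet(X'WX)), floored at 1e-8, then moderated
across genes by an empirical-Bayes normal prior on log dispersion
(trendless: the prior is centered at the across-gene median rather than
on a fitted mean-dispersion trend). Inference is a Wald test on the
contrast coefficient, BH-corrected across genes within each (cell type,
contrast); a gene is called differentially expressed when q < 0.1 and
fold change > 2. No independent filtering and no fold-change shrinkage
are applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
import scipy.special
import scipy.stats

from .config import RunConfig
from .stats import bh_fdr

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 10.0
MIN_RATIO_GENES = 50


@dataclass
class PseudobulkDataset:
    """Gene x unit aggregated counts with unit covariates.

    counts : genes x units integer DataFrame (columns = unit ids).
    units : per-unit covariates: unit_id, subject_id, compartment
        (NA for the pooled grouping), group, cell_type, n_cells.
    """

    counts: pd.DataFrame
    units: pd.DataFrame
    grouping: str

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.units["unit_id"]):
            raise ValueError("counts columns must match units.unit_id order")


def aggregate_pseudobulk(adata: ad.AnnData, labels: pd.Series, grouping: str,
                         cfg: RunConfig | None = None) -> PseudobulkDataset:
    """Sum cells into pseudobulk units under the 100-cell rule.

    grouping='by_location': units (subject, compartment, cell type); a
    cell type is kept only if it has >= min_cells_per_pseudobulk cells in
    each compartment. grouping='by_group': counts pooled across
    compartments into (subject, cell type) units; kept only with
    >= min cells in each study group.
    """
    cfg = cfg or RunConfig()
    if grouping not in ("by_location", "by_group"):
        raise ValueError(f"unknown grouping {grouping!r}")
    labels = pd.Series(np.asarray(labels), index=adata.obs_names, name="cell_type")
    obs = adata.obs.assign(cell_type=labels.to_numpy())

    stratum = "compartment" if grouping == "by_location" else "group"
    strata = obs[stratum].unique()
    tallies = obs.groupby(["cell_type", stratum], observed=True).size().unstack(fill_value=0)
    keep_types = tallies.index[
        (tallies.reindex(columns=strata, fill_value=0) >= cfg.min_cells_per_pseudobulk).all(axis=1)
    ]
    if len(keep_types) == 0:
        raise ValueError("no cell type satisfies the minimum-cells rule for this grouping")

    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    X = X.tocsr()

    unit_keys = (["subject_id", "compartment", "cell_type"] if grouping == "by_location"
                 else ["subject_id", "cell_type"])
    rows = []
    cols = {}
    mask_type = obs["cell_type"].isin(keep_types)
    for key, sub in obs[mask_type].groupby(unit_keys, observed=True, sort=True):
        idx = obs.index.get_indexer(sub.index)
        unit_id = "|".join(str(k) for k in key)
        cols[unit_id] = np.asarray(X[idx].sum(axis=0)).ravel().astype(np.int64)
        rec = dict(zip(unit_keys, key))
        rows.append({
            "unit_id": unit_id,
            "subject_id": rec["subject_id"],
            "compartment": rec.get("compartment", pd.NA),
            "group": sub["group"].iloc[0],
            "cell_type": rec["cell_type"],
            "n_cells": len(sub),
        })
    units = pd.DataFrame(rows)
    counts = pd.DataFrame(cols, index=adata.var["gene_id"].to_numpy())
    return PseudobulkDataset(counts=counts, units=units, grouping=grouping)


def size_factors_median_ratio(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (genes x units), computed over genes
    with all-nonzero counts; total-count fallback (scaled to geometric
    mean 1) when fewer than MIN_RATIO_GENES such genes exist."""
    counts = np.asarray(counts, dtype=float)
    all_nz = (counts > 0).all(axis=1)
    if all_nz.sum() >= MIN_RATIO_GENES:
        sub = counts[all_nz]
        log_geo = np.mean(np.log(sub), axis=1)
        sf = np.exp(np.median(np.log(sub) - log_geo[:, None], axis=0))
    else:
        tot = counts.sum(axis=0)
        sf = tot / np.exp(np.mean(np.log(tot)))
    return sf


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB log-likelihood with variance mu + alpha*mu^2 (alpha > 0 uses the
    gamma-Poisson form; alpha at the floor falls back to Poisson)."""
    y = np.asarray(y, float)
    mu = np.maximum(np.asarray(mu, float), 1e-300)
    if alpha <= DISPERSION_FLOOR:
        return float(np.sum(scipy.stats.poisson.logpmf(y, mu)))
    r = 1.0 / alpha
    p = r / (r + mu)
    return float(np.sum(scipy.stats.nbinom.logpmf(y, r, p)))


def _build_design(units: pd.DataFrame, design_factors: list[str],
                  contrast: tuple[str, str, str]) -> tuple[np.ndarray, list[str], str]:
    """Treatment-coded design matrix with the contrast's reference level
    as baseline for the contrast factor."""
    factor, level_a, level_b = contrast
    if factor not in design_factors:
        raise ValueError(f"contrast factor {factor!r} not among design factors {design_factors}")
    cols = [np.ones(len(units))]
    names = ["intercept"]
    for f in design_factors:
        values = units[f].astype(str)
        levels = sorted(values.unique())
        if f == factor:
            for lv in (level_a, level_b):
                if lv not in levels:
                    raise ValueError(
                        f"contrast level {lv!r} absent; available {f} levels: {levels}")
            ref = level_b
        else:
            ref = levels[0]
        for lv in levels:
            if lv == ref:
                continue
            cols.append((values == lv).to_numpy(float))
            names.append(f"{f}[{lv}]")
    X = np.column_stack(cols)
    coef = f"{factor}[{level_a}]"
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient after subsetting")
    return X, names, coef


class FitError(RuntimeError):
    """IRLS failed to converge or produced a singular weighted design."""


def irls_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float,
            maxiter: int = 50, tol: float = 1e-10):
    """Fisher-scoring IRLS for an NB GLM with log link and fixed dispersion.

    Weights are the expected-information weights mu/(1 + alpha*mu), so
    the returned covariance (X'WX)^-1 is the Fisher covariance of the
    coefficients. Returns (beta, mu, cov).
    """
    y = np.asarray(y, float)
    alpha = max(alpha, DISPERSION_FLOOR)
    mu = np.maximum(y, 0.5) + 1e-8
    eta = np.log(mu)
    beta = None
    ll = -np.inf
    for _ in range(maxiter):
        w = mu / (1.0 + alpha * mu)
        z = eta - offset + (y - mu) / mu
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError as exc:
            raise FitError(str(exc))
        eta = np.clip(X @ beta_new + offset, -30.0, 30.0)
        mu = np.exp(eta)
        ll_new = nb_loglik(y, mu, alpha)
        # coefficient convergence, or likelihood plateau (separation: the
        # fitted means converge while a coefficient drifts to infinity)
        if beta is not None and (np.max(np.abs(beta_new - beta)) < tol
                                 or abs(ll_new - ll) < 1e-9 * (abs(ll_new) + 1.0)):
            beta = beta_new
            break
        beta = beta_new
        ll = ll_new
    else:
        raise FitError("IRLS did not converge")
    w = mu / (1.0 + alpha * mu)
    xtwx = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:
        raise FitError(str(exc))
    return beta, mu, cov


def _cr_adjusted_profile_ll(y, X, offset, alpha) -> float:
    try:
        _, mu, _ = irls_nb(y, X, offset, alpha)
    except FitError:
        return -np.inf
    ll = nb_loglik(y, mu, alpha)
    w = mu / (1.0 + alpha * mu)
    xtwx = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return -np.inf
    return ll - 0.5 * logdet


def estimate_dispersion(y, X, offset, prior: tuple[float, float] | None = None) -> float:
    """Cox-Reid-adjusted profile ML dispersion, floored at 1e-8.

    With ``prior=(mean_log_alpha, var_log_alpha)`` the estimate is the
    maximum a posteriori value under a normal prior on log dispersion
    (empirical-Bayes moderation across genes).
    """
    def obj(la):
        val = -_cr_adjusted_profile_ll(y, X, offset, np.exp(la))
        if prior is not None:
            val += 0.5 * (la - prior[0]) ** 2 / prior[1]
        return val

    with np.errstate(all="ignore"):
        res = scipy.optimize.minimize_scalar(
            obj, bounds=(np.log(DISPERSION_FLOOR), np.log(DISPERSION_CEIL)),
            method="bounded", options={"xatol": 1e-3})
        alpha = float(np.exp(res.x))
        # compare against the floor explicitly: profile can be flat near zero
        if prior is None and -obj(np.log(DISPERSION_FLOOR)) >= -res.fun:
            alpha = DISPERSION_FLOOR
    return max(alpha, DISPERSION_FLOOR)


def dispersion_prior(alphas: np.ndarray, n_units: int, n_params: int
                     ) -> tuple[float, float] | None:
    """Empirical-Bayes prior on log dispersion from per-gene estimates.

    Prior mean is the median log estimate over genes away from the floor;
    prior variance is the observed spread minus the approximate sampling
    variance of a log-dispersion estimate, trigamma((m - p)/2), floored
    at 0.25. Returns None when too few genes inform the prior.
    """
    ok = np.asarray(alphas)[np.asarray(alphas) > 10 * DISPERSION_FLOOR]
    if ok.size < 10:
        return None
    la = np.log(ok)
    s_samp = float(scipy.special.polygamma(1, max(n_units - n_params, 1) / 2.0))
    prior_var = max(float(np.var(la)) - s_samp, 0.25)
    return float(np.median(la)), prior_var


def nb_glm_de(pb: PseudobulkDataset, design_factors: list[str],
              contrast: tuple[str, str, str], cfg: RunConfig | None = None,
              dispersion: float | None = None) -> pd.DataFrame:
    """Per-cell-type, per-gene NB GLM Wald test on the contrast coefficient.

    Parameters
    ----------
    design_factors : unit covariate names entering as fixed effects
        (e.g. ``["subject_id", "compartment"]`` for the compartment
        analysis, ``["group"]`` for the study-group analysis).
    contrast : (factor, level_a, level_b); the reported log2 fold change
        is level_a relative to level_b.
    dispersion : if given, fixes alpha for every gene (0 is floored to
        1e-8, the Poisson limit) instead of per-gene estimation.

    Returns a table with columns cell_type, contrast, gene_id, log2_fc,
    se, wald_p, bh_q, significant, dispersion, converged.
    """
    cfg = cfg or RunConfig()
    factor, level_a, level_b = contrast
    if factor not in pb.units.columns:
        raise ValueError(f"contrast factor {factor!r} not a unit covariate")
    available = sorted(pb.units[factor].astype(str).unique())
    for lv in (level_a, level_b):
        if lv not in available:
            raise ValueError(f"contrast level {lv!r} absent from design; "
                             f"available {factor} levels: {available}")
    contrast_label = f"{level_a}_vs_{level_b}"
    ln2 = np.log(2.0)
    frames = []
    for ct, units_ct in pb.units.groupby("cell_type", sort=True):
        sub_levels = units_ct[factor].astype(str)
        if (sub_levels == level_a).sum() < 2 or (sub_levels == level_b).sum() < 2:
            logger.warning("cell type %s: <2 units per contrast level; skipped", ct)
            continue
        # pairwise contrast: only units at the two contrasted levels enter the fit
        units_sub = units_ct[sub_levels.isin([level_a, level_b])]
        X, names, coef_name = _build_design(units_sub, design_factors, contrast)
        j = names.index(coef_name)
        Y = pb.counts[units_sub["unit_id"]].to_numpy()
        sf = size_factors_median_ratio(Y)
        offset = np.log(sf)

        nonzero = [g for g in range(Y.shape[0]) if Y[g].sum() > 0]

        # two-pass dispersion estimation: per-gene CR profile estimates,
        # then empirical-Bayes moderation toward their common center so a
        # handful of units cannot produce wild per-gene dispersions
        gene_alpha: dict[int, float] = {}
        if dispersion is not None:
            for g in nonzero:
                gene_alpha[g] = max(dispersion, DISPERSION_FLOOR)
        else:
            raw = {}
            for g in nonzero:
                raw[g] = estimate_dispersion(Y[g].astype(float), X, offset)
            prior = dispersion_prior(np.array(list(raw.values())),
                                     X.shape[0], X.shape[1])
            for g in nonzero:
                gene_alpha[g] = (estimate_dispersion(Y[g].astype(float), X, offset,
                                                     prior=prior)
                                 if prior is not None else raw[g])

        recs = []
        for g in nonzero:
            y = Y[g].astype(float)
            rec = {"cell_type": ct, "contrast": contrast_label,
                   "gene_id": pb.counts.index[g]}
            try:
                alpha = gene_alpha[g]
                beta, _, cov = irls_nb(y, X, offset, alpha)
                se = float(np.sqrt(cov[j, j]))
                rec.update(log2_fc=beta[j] / ln2, se=se / ln2,
                           wald_p=2.0 * scipy.stats.norm.sf(abs(beta[j] / se)),
                           dispersion=alpha, converged=True)
            except FitError as exc:
                logger.warning("gene %s in %s: %s", pb.counts.index[g], ct, exc)
                rec.update(log2_fc=np.nan, se=np.nan, wald_p=np.nan,
                           dispersion=np.nan, converged=False)
            recs.append(rec)
        if not recs:
            continue
        df = pd.DataFrame(recs)
        df["bh_q"] = bh_fdr(df["wald_p"].to_numpy())
        df["significant"] = ((df["bh_q"] < cfg.de_q_threshold)
                             & (np.abs(df["log2_fc"]) > np.log2(cfg.de_fc_threshold)))
        df["significant"] = df["significant"].fillna(False)
        frames.append(df)
    if not frames:
        raise ValueError("no cell type yielded a testable contrast")
    return pd.concat(frames, ignore_index=True)


def compare_labor_effects(de_til: pd.DataFrame, de_ptl: pd.DataFrame,
                          cell_class_map: dict[str, str],
                          cfg: RunConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify per-(gene, cell type) effects as shared/TIL-only/PTL-only/
    neither at the shared q threshold, and correlate effect sizes within
    major cell classes.

    Both-significant pairs with opposite signs are classed 'neither'
    (shared requires concordant direction).
    Returns (per-pair table, per-class Pearson correlation table).
    """
    cfg = cfg or RunConfig()
    key = ["cell_type", "gene_id"]
    a = de_til[key + ["log2_fc", "bh_q"]].rename(
        columns={"log2_fc": "beta_TIL", "bh_q": "q_TIL"})
    b = de_ptl[key + ["log2_fc", "bh_q"]].rename(
        columns={"log2_fc": "beta_PTL", "bh_q": "q_PTL"})
    merged = a.merge(b, on=key, how="inner")
    if merged.empty:
        raise ValueError("no shared (cell type, gene) keys between the two DE tables")

    sig_t = merged["q_TIL"] < cfg.shared_q_threshold
    sig_p = merged["q_PTL"] < cfg.shared_q_threshold
    same_sign = np.sign(merged["beta_TIL"]) == np.sign(merged["beta_PTL"])
    cls = np.where(sig_t & sig_p & same_sign, "shared",
          np.where(sig_t & ~sig_p, "TIL-only",
          np.where(~sig_t & sig_p, "PTL-only", "neither")))
    merged["class"] = cls
    merged["cell_class"] = merged["cell_type"].map(cell_class_map)

    rows = []
    for cc, sub in merged.dropna(subset=["beta_TIL", "beta_PTL"]).groupby("cell_class"):
        if len(sub) >= 3:
            r = float(np.corrcoef(sub["beta_TIL"], sub["beta_PTL"])[0, 1])
        else:
            r = np.nan
        rows.append({"cell_class": cc, "pearson_r": r, "n_pairs": len(sub)})
    return merged, pd.DataFrame(rows)
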