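"""Synthetic data generators emulating the study's two kinds of input.

Single-cell side: multi-cell-type UMI count matrices over three placental
compartments (basal plate BP, placental villous PV, chorioamniotic
membranes CAM) and three study groups (term no labor TNL, term in labor
TIL, preterm labor PTL), with a maternal/fetal mixture encoded through
Y-chromosome and XIST expression, mitochondrial content, and injected
low-quality cells. Counts are negative binomial with mean mu and
dispersion alpha (variance mu + alpha*mu^2), matching the downstream
GLM's parameterization, with a lognormal(0, 0.3) per-cell size factor.

Bulk side: maternal whole-blood log2 expression cohorts — a longitudinal
term cohort (8 in-labor + 8 no-labor subjects, 3 samples each across
12-40 weeks of gestation, one sample per trimester window) and a
cross-sectional preterm cohort (15 preterm-labor vs 23 gestational-age
matched controls, 24-34 weeks) — with planted gestational-age and labor
effects on designated signature gene sets.

Every generator returns the dataset plus a :class:`GroundTruth` recording
what was planted, so downstream recovery is checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import COMPARTMENTS, GROUPS, ConfigError

SIZE_FACTOR_SDLOG = 0.3
GA_CENTER_WEEKS = 26.0
TRIMESTER_WINDOWS = ((12.0, 20.0), (21.0, 30.0), (31.0, 40.0))


@dataclass
class GroundTruth:
    """What the generator planted.

    cells : per-cell true cluster, origin (maternal/fetal) and low-quality flag.
    genes : per-gene marker-of cluster (or NA).
    signatures : per-signature planted gestational-age and labor effects
        (bulk generators only).
    """

    cells: Optional[pd.DataFrame] = None
    genes: Optional[pd.DataFrame] = None
    signatures: Optional[pd.DataFrame] = None
    signature_genes: Optional[dict] = None


@dataclass
class ScSimConfig:
    """Single-cell generator settings.

    ``cells_per_type`` cells are emitted for every
    (cell type, compartment, group) block; subjects (three per group, one
    with a male fetus, as in a 9-woman / 3-male design) are assigned
    round-robin within each group. ``fraction_fetal_per_type`` defaults to
    the first half of the types being fetal (trophoblast-like) and the
    rest maternal (decidual-like).
    """

    n_cell_types: int = 6
    cells_per_type: int = 40
    n_genes: int = 1000
    dispersion: float = 0.1
    n_marker_genes_per_type: int = 25
    marker_fold_change: float = 4.0
    marker_min_rate: float = 0.25
    fraction_fetal_per_type: Optional[list] = None
    y_gene_count: int = 5
    y_expression_rate: float = 2.0
    n_mito_genes: int = 10
    mito_beta_a: float = 2.0
    mito_beta_b: float = 38.0
    low_quality_cell_fraction: float = 0.05
    baseline_log_mean: float = -1.0
    baseline_log_sd: float = 1.0
    xist_rate_maternal: float = 3.0
    xist_rate_fetal_male: float = 0.1
    subjects_per_group: int = 3
    male_subjects_per_group: int = 1
    qc_min_genes: int = 200
    qc_max_mito: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fraction_fetal_per_type is None:
            half = self.n_cell_types // 2
            self.fraction_fetal_per_type = [1.0 if i < half else 0.0
                                            for i in range(self.n_cell_types)]
        self.validate()

    def validate(self) -> None:
        if self.n_cell_types < 1 or self.cells_per_type < 1 or self.n_genes < 1:
            raise ConfigError("n_cell_types, cells_per_type, n_genes must be >= 1")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if self.marker_fold_change <= 1:
            raise ConfigError("marker_fold_change must exceed 1")
        if len(self.fraction_fetal_per_type) != self.n_cell_types:
            raise ConfigError("fraction_fetal_per_type length must equal n_cell_types")
        for f in list(self.fraction_fetal_per_type) + [self.low_quality_cell_fraction]:
            if not (0.0 <= f <= 1.0):
                raise ConfigError(f"fraction {f} outside [0, 1]")
        if self.y_gene_count < 1 or self.n_mito_genes < 1:
            raise ConfigError("need at least one Y gene and one MT gene")
        needed = self.n_marker_genes_per_type * self.n_cell_types
        special = self.y_gene_count + self.n_mito_genes + 1
        if needed + special > self.n_genes:
            raise ConfigError("n_genes too small for requested markers plus Y/MT/XIST genes")


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) with variance mu + alpha*mu^2, via gamma-Poisson."""
    shape = 1.0 / alpha
    lam = rng.gamma(shape, np.maximum(mu, 0.0) * alpha)
    return rng.poisson(lam)


def simulate_sc_dataset(config: ScSimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Draw a UMI count matrix with planted clusters, origin, and QC failures.

    Cells not flagged low-quality are guaranteed to pass the default QC
    (>=``qc_min_genes`` detected genes, mito fraction <= ``qc_max_mito``):
    rare NB draws below the detected-gene floor are topped up with
    single counts and mito overshoot is trimmed. Flagged cells are forced
    to violate exactly one of the two rules.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- gene panel ---------------------------------------------------
    n_genes = cfg.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n_genes)])
    chromosome = np.empty(n_genes, dtype=object)
    mito_idx = np.arange(cfg.n_mito_genes)
    y_idx = np.arange(cfg.n_mito_genes, cfg.n_mito_genes + cfg.y_gene_count)
    xist_idx = cfg.n_mito_genes + cfg.y_gene_count
    chromosome[mito_idx] = "MT"
    chromosome[y_idx] = "Y"
    chromosome[xist_idx] = "X"
    rest = np.arange(xist_idx + 1, n_genes)
    chromosome[rest] = rng.choice([str(i) for i in range(1, 23)], size=rest.size)
    symbols = gene_ids.copy()
    symbols[mito_idx] = [f"MT-G{i}" for i in range(cfg.n_mito_genes)]
    symbols[y_idx] = [f"YG{i}" for i in range(cfg.y_gene_count)]
    symbols[xist_idx] = "XIST"

    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n_genes)

    # markers: disjoint blocks of ordinary autosomal genes. A marker is by
    # definition detectably expressed in its own type, so blocks are drawn
    # from genes whose baseline rate clears marker_min_rate (topped up with
    # the most-expressed remainder if the eligible pool runs short).
    marker_of = np.full(n_genes, None, dtype=object)
    eligible = rest[baseline[rest] >= cfg.marker_min_rate]
    if eligible.size < cfg.n_marker_genes_per_type * cfg.n_cell_types:
        extra = rest[baseline[rest] < cfg.marker_min_rate]
        extra = extra[np.argsort(-baseline[extra])]
        eligible = np.concatenate([eligible, extra])
    marker_pool = rng.permutation(eligible)
    markers_per_type = {}
    for t in range(cfg.n_cell_types):
        block = marker_pool[t * cfg.n_marker_genes_per_type:(t + 1) * cfg.n_marker_genes_per_type]
        markers_per_type[t] = np.sort(block)
        marker_of[np.sort(block)] = f"CT{t}"
    baseline[mito_idx] = 0.0   # set per cell from the drawn mito fraction
    baseline[y_idx] = 0.0      # set per cell from origin
    baseline[xist_idx] = 0.0   # set per cell from origin/fetal sex

    type_rates = np.tile(baseline, (cfg.n_cell_types, 1))
    for t, block in markers_per_type.items():
        type_rates[t, block] *= cfg.marker_fold_change

    # --- cell sheet ---------------------------------------------------
    subjects = {g: [f"{g}_S{j}" for j in range(cfg.subjects_per_group)] for g in GROUPS}
    male_subjects = {s for g in GROUPS for s in subjects[g][: cfg.male_subjects_per_group]}

    rows = []
    for comp in COMPARTMENTS:
        for grp in GROUPS:
            for t in range(cfg.n_cell_types):
                for k in range(cfg.cells_per_type):
                    subj = subjects[grp][k % cfg.subjects_per_group]
                    rows.append((comp, grp, subj, t))
    cells = pd.DataFrame(rows, columns=["compartment", "group", "subject_id", "true_cluster_i"])
    n_cells = len(cells)
    cells["barcode"] = [f"BC{i:06d}" for i in range(n_cells)]
    cells["library_id"] = cells["subject_id"] + "_" + cells["compartment"]
    cells["fetal_sex"] = np.where(cells["subject_id"].isin(male_subjects), "male", "female")
    frac_fetal = np.asarray(cfg.fraction_fetal_per_type)
    cells["fetal"] = rng.random(n_cells) < frac_fetal[cells["true_cluster_i"]]
    cells["low_quality"] = rng.random(n_cells) < cfg.low_quality_cell_fraction

    size_factors = rng.lognormal(0.0, SIZE_FACTOR_SDLOG, size=n_cells)
    mito_frac = rng.beta(cfg.mito_beta_a, cfg.mito_beta_b, size=n_cells)

    # --- expected rates and sampling ----------------------------------
    mu = type_rates[cells["true_cluster_i"].to_numpy()] * size_factors[:, None]

    is_male_subj = cells["fetal_sex"].to_numpy() == "male"
    is_fetal = cells["fetal"].to_numpy()
    # Y genes: only fetal cells of male-fetus pregnancies transcribe them
    y_cells = is_fetal & is_male_subj
    mu[np.ix_(y_cells, y_idx)] = cfg.y_expression_rate * size_factors[y_cells, None]
    # XIST: high in any female cell (maternal, or fetal with a female fetus)
    xist_hi = ~(is_fetal & is_male_subj)
    mu[xist_hi, xist_idx] = cfg.xist_rate_maternal * size_factors[xist_hi]
    mu[~xist_hi, xist_idx] = cfg.xist_rate_fetal_male * size_factors[~xist_hi]
    # mito genes carry the drawn fraction of each cell's expected counts
    non_mito_total = mu.sum(axis=1)
    mito_total = mito_frac / (1.0 - mito_frac) * non_mito_total
    mu[:, mito_idx] = (mito_total / cfg.n_mito_genes)[:, None]

    counts = _nb_sample(rng, mu, cfg.dispersion).astype(np.int64)

    # --- enforce the QC contract --------------------------------------
    lq = cells["low_quality"].to_numpy()
    mito_mask = np.zeros(n_genes, bool)
    mito_mask[mito_idx] = True

    special = np.zeros(n_genes, bool)
    special[mito_idx] = True
    special[y_idx] = True  # top-ups must not fabricate Y or MT expression
    for i in np.where(~lq)[0]:
        tot = counts[i].sum()
        mt = counts[i, mito_idx].sum()
        if tot > 0 and mt / tot > cfg.qc_max_mito:
            # trim mito counts just under the cutoff
            target = int(np.floor(cfg.qc_max_mito * (tot - mt) / (1.0 - cfg.qc_max_mito)))
            scale = target / mt if mt > 0 else 0.0
            counts[i, mito_idx] = np.floor(counts[i, mito_idx] * scale).astype(np.int64)
        detected = int((counts[i] > 0).sum())
        if detected < cfg.qc_min_genes:
            zeros = np.where((counts[i] == 0) & ~special)[0]
            add = rng.choice(zeros, size=min(cfg.qc_min_genes - detected, zeros.size),
                             replace=False)
            counts[i, add] = 1

    for i in np.where(lq)[0]:
        if rng.random() < 0.5:
            # starve: keep a random subset of < qc_min_genes genes
            keep_n = int(rng.integers(50, min(150, cfg.qc_min_genes - 1)))
            nz = np.where(counts[i] > 0)[0]
            if nz.size > keep_n:
                drop = rng.choice(nz, size=nz.size - keep_n, replace=False)
                counts[i, drop] = 0
            else:  # already sparse enough; make sure it is below the floor
                counts[i, counts[i] > 0] = counts[i, counts[i] > 0]
        else:
            # drown in mito: push fraction well above the cutoff
            f = rng.uniform(0.15, 0.5)
            non_mt = counts[i, ~mito_mask].sum()
            target = max(int(np.ceil(f / (1.0 - f) * max(non_mt, 1))), 1)
            per_gene = np.full(cfg.n_mito_genes, target // cfg.n_mito_genes)
            per_gene[: target % cfg.n_mito_genes] += 1
            counts[i, mito_idx] = per_gene

    var = pd.DataFrame({
        "gene_id": gene_ids,
        "symbol": symbols,
        "chromosome": chromosome.astype(str),
    })
    var["is_ribosomal"] = var["symbol"].str.match(r"^RP[LS]")
    var.index = pd.Index(gene_ids)

    obs = cells[["barcode", "library_id", "compartment", "group",
                 "subject_id", "fetal_sex"]].copy()
    obs.index = pd.Index(cells["barcode"].astype(str))

    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)

    truth_cells = pd.DataFrame({
        "barcode": cells["barcode"],
        "true_cluster": "CT" + cells["true_cluster_i"].astype(str),
        "true_origin": np.where(is_fetal, "fetal", "maternal"),
        "low_quality": lq,
    })
    truth_genes = pd.DataFrame({"gene_id": gene_ids, "marker_of": marker_of})
    return adata, GroundTruth(cells=truth_cells, genes=truth_genes)


# ----------------------------------------------------------------------
# bulk maternal-blood cohorts
# ----------------------------------------------------------------------

@dataclass
class BulkExpressionSet:
    """Bulk log2-normalized expression with sample annotation.

    expression : genes x samples DataFrame of log2 values.
    samples : one row per sample with sample_id, subject_id,
        gestational_age (weeks), group.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.samples["sample_id"]):
            raise ValueError("expression columns must match samples.sample_id order")


@dataclass
class BulkSimConfig:
    """Bulk blood-cohort generator settings.

    ``design`` picks the cohort: ``longitudinal_term`` (8 TIL + 8 TNL
    subjects, 3 samples each, one per trimester window of 12-40 weeks) or
    ``crosssection_preterm`` (15 PTL + 23 GA-matched controls, one sample
    each at 24-34 weeks). Planted effects act on whole signature gene
    sets: a linear (and optionally quadratic) gestational-age trend on
    the GA-affected signatures, a term-labor shift on the TIL arm's
    third-trimester samples, and a mean shift on the PTL arm.
    """

    design: str = "longitudinal_term"
    n_subjects_arm1: int = 8     # TIL  (longitudinal) / PTL (cross-section: 15)
    n_subjects_arm2: int = 8     # TNL  (longitudinal) / GA controls (cross-section: 23)
    samples_per_subject: int = 3
    ga_range: tuple = (12.0, 40.0)
    n_genes: int = 3000
    n_signatures: int = 10
    signature_size: int = 20
    n_ga_affected: int = 5
    n_labor_affected: int = 3
    ga_slope: float = 0.05          # log2 units per week
    ga_quadratic: float = 0.0       # log2 units per week^2
    labor_effect: float = 1.0       # log2 shift, TIL third-trimester samples
    ptl_shift: float = 0.3          # log2 shift on PTL arm (1 residual sd)
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    residual_sd: float = 0.3
    subject_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design == "crosssection_preterm":
            # study defaults for the preterm cohort
            if self.n_subjects_arm1 == 8 and self.n_subjects_arm2 == 8:
                self.n_subjects_arm1, self.n_subjects_arm2 = 15, 23
            if self.ga_range == (12.0, 40.0):
                self.ga_range = (24.0, 34.0)
        self.validate()

    def validate(self) -> None:
        if self.design not in ("longitudinal_term", "crosssection_preterm"):
            raise ConfigError(f"unknown design {self.design!r}")
        if self.n_subjects_arm1 < 2 or self.n_subjects_arm2 < 2:
            raise ConfigError("need at least 2 subjects per arm")
        for f in (self.ga_slope, self.ga_quadratic, self.labor_effect, self.ptl_shift):
            if not np.isfinite(f):
                raise ConfigError("effect sizes must be finite")
        if self.n_signatures * self.signature_size > self.n_genes:
            raise ConfigError("n_genes too small for requested signatures")
        if self.n_ga_affected > self.n_signatures or self.n_labor_affected > self.n_signatures:
            raise ConfigError("affected signature counts exceed n_signatures")


def _bulk_panel(cfg: BulkSimConfig, rng: np.random.Generator):
    genes = np.array([f"BG{i:05d}" for i in range(cfg.n_genes)])
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    sig_genes = {}
    for s in range(cfg.n_signatures):
        sig_genes[f"SIG{s}"] = list(genes[s * cfg.signature_size:(s + 1) * cfg.signature_size])
    ga_affected = [f"SIG{s}" for s in range(cfg.n_ga_affected)]
    labor_affected = [f"SIG{s}" for s in range(cfg.n_labor_affected)]
    return genes, baseline, sig_genes, ga_affected, labor_affected


def _signature_truth(cfg: BulkSimConfig, sig_genes, ga_affected, labor_affected) -> pd.DataFrame:
    rows = []
    for sid in sig_genes:
        rows.append({
            "signature_id": sid,
            "ga_slope": cfg.ga_slope if sid in ga_affected else 0.0,
            "ga_quadratic": cfg.ga_quadratic if sid in ga_affected else 0.0,
            "labor_effect": cfg.labor_effect if sid in labor_affected else 0.0,
            "ptl_shift": cfg.ptl_shift if sid in labor_affected else 0.0,
        })
    return pd.DataFrame(rows)


def simulate_bulk_longitudinal(config: BulkSimConfig) -> tuple[BulkExpressionSet, GroundTruth]:
    """Longitudinal term cohort: per subject one sample per trimester window,
    log2 expression = baseline + GA trend (GA-affected signature genes)
    + labor shift (TIL arm, third-trimester samples) + subject random
    intercept + Gaussian noise."""
    cfg = config
    if cfg.design != "longitudinal_term":
        raise ConfigError("simulate_bulk_longitudinal requires design='longitudinal_term'")
    rng = np.random.default_rng(cfg.seed)
    genes, baseline, sig_genes, ga_affected, labor_affected = _bulk_panel(cfg, rng)

    ga_gene = np.zeros(cfg.n_genes)
    quad_gene = np.zeros(cfg.n_genes)
    labor_gene = np.zeros(cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for sid in ga_affected:
        for g in sig_genes[sid]:
            ga_gene[gene_pos[g]] = cfg.ga_slope
            quad_gene[gene_pos[g]] = cfg.ga_quadratic
    for sid in labor_affected:
        for g in sig_genes[sid]:
            labor_gene[gene_pos[g]] = cfg.labor_effect

    rows = []
    cols = {}
    for arm, grp, n_subj in (("T", "TIL", cfg.n_subjects_arm1),
                             ("N", "TNL", cfg.n_subjects_arm2)):
        for j in range(n_subj):
            subj = f"{grp}_{j:02d}"
            intercept = rng.normal(0.0, cfg.subject_sd)
            for k, (lo, hi) in enumerate(TRIMESTER_WINDOWS[: cfg.samples_per_subject]):
                ga = rng.uniform(lo, hi)
                sid = f"{subj}_V{k + 1}"
                x = (baseline
                     + ga_gene * (ga - GA_CENTER_WEEKS)
                     + quad_gene * (ga - GA_CENTER_WEEKS) ** 2
                     + intercept
                     + rng.normal(0.0, cfg.residual_sd, size=cfg.n_genes))
                if grp == "TIL" and k == cfg.samples_per_subject - 1:
                    x = x + labor_gene
                cols[sid] = x
                rows.append({"sample_id": sid, "subject_id": subj,
                             "gestational_age": ga, "group": grp})
    samples = pd.DataFrame(rows)
    expr = pd.DataFrame(cols, index=genes)
    truth = _signature_truth(cfg, sig_genes, ga_affected, labor_affected)
    return (BulkExpressionSet(expression=expr, samples=samples),
            GroundTruth(signatures=truth, signature_genes=sig_genes))


def simulate_bulk_crosssection(config: BulkSimConfig) -> tuple[BulkExpressionSet, GroundTruth]:
    """Cross-sectional preterm cohort: both arms drawn from the same GA
    distribution (GA matching), one sample per subject, planted mean
    shift on designated signatures in the PTL arm."""
    cfg = config
    if cfg.design != "crosssection_preterm":
        raise ConfigError("simulate_bulk_crosssection requires design='crosssection_preterm'")
    rng = np.random.default_rng(cfg.seed)
    genes, baseline, sig_genes, ga_affected, labor_affected = _bulk_panel(cfg, rng)

    shift_gene = np.zeros(cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for sid in labor_affected:
        for g in sig_genes[sid]:
            shift_gene[gene_pos[g]] = cfg.ptl_shift

    rows = []
    cols = {}
    lo, hi = cfg.ga_range
    for grp, n_subj in (("PTL", cfg.n_subjects_arm1), ("GA_control", cfg.n_subjects_arm2)):
        for j in range(n_subj):
            subj = f"{grp}_{j:02d}"
            sid = f"{subj}_V1"
            ga = rng.uniform(lo, hi)
            x = baseline + rng.normal(0.0, cfg.residual_sd, size=cfg.n_genes)
            if grp == "PTL":
                x = x + shift_gene
            cols[sid] = x
            rows.append({"sample_id": sid, "subject_id": subj,
                         "gestational_age": ga, "group": grp})
    samples = pd.DataFrame(rows)
    expr = pd.DataFrame(cols, index=genes)
    truth = _signature_truth(cfg, sig_genes, ga_affected, labor_affected)
    return (BulkExpressionSet(expression=expr, samples=samples),
            GroundTruth(signatures=truth, signature_genes=sig_genes))
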