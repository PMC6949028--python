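# Methods

This note records the statistical models the package implements, the
choices made where the procedure was genuinely open, and what the
synthetic data do and do not establish.

## Single-cell QC and normalization

A cell is kept if it has at least `min_genes_per_cell` (default 200) genes
with nonzero counts **and** a mitochondrial count fraction at or below
`max_mito_fraction` (0.10, strict inequality for removal). Genes are then
kept if detected in at least `min_cells_per_gene` (10) of the surviving
cells. The two cell rules are applied on the raw matrix and the gene rule
once on the survivors — a single pass, no iteration to a fixpoint. The
order is safe because removing a cell can only decrease a gene's
detected-cell count, so a second pass could never resurrect anything; a
cell failing both rules is tallied under the detected-gene rule. The QC
report reconciles exactly: in − removed = out on both axes.

Normalization is `ln(1 + count · s / total)` with scale factor
`s = 10,000`; zeros map to zeros and the transform is strictly monotone
within a cell. Variable-gene selection works on the exponentiated
(count-scale) values: per gene the mean and the dispersion
`ln(variance/mean)`, z-scored within 20 equal-width mean bins; selected
genes have mean in `[0.0125, 3]` and z-dispersion ≥ 0.5 (all four numbers
are the conventional defaults of the upstream tool this emulates and are
configurable); ribosomal genes (symbol `^RP[LS]`) and MT genes are then
removed. A "detected" gene means count > 0; no higher detection threshold
is imposed.

## Fetal index and origin calls

For clusters of cells from pregnancies with a male fetus, the fetal index
is the ratio of summed Y-gene UMIs to summed autosomal UMIs (chromosomes
1–22 only; X and MT are excluded from the denominator — "autosomes" is
taken literally). The index is a ratio of sums, hence invariant to cell
duplication and to uniform depth scaling.

No published numeric threshold separates maternal from fetal clusters, so
the classifier is this package's own declared rule: clusters are split on
`log10(index + 1e-6)` at the threshold maximizing the between-class
variance (Otsu's criterion, brute-forced over midpoints of consecutive
distinct values); the higher-mean side is fetal. Clusters within
`origin_margin` (0.5 log10 units) of the threshold are left indeterminate,
as are all clusters when no split exists (a single cluster, or all indices
identical). The 1e-6 pseudocount exists only inside the classifier's log;
reported indices are raw ratios.

## Marker detection and signatures

Per cluster, genes pass to testing when detected in ≥25% of cells inside
or outside the cluster and |log fold change| ≥ 0.25, where log fold
change is the difference of mean log-normalized values (cluster minus
rest) on the natural-log scale — deliberately *not* the log of the ratio
of means. This convention changes gene ranking and therefore signature
membership, so it is fixed and documented here. The test is a two-sided
Wilcoxon rank-sum with tie-corrected normal approximation and continuity
correction, implemented vectorized over genes; exact enumeration is used
below 25 total observations when a gene has no ties. BH correction is
applied within each cluster's tested genes. Rank tests make the p-values
invariant under any strictly monotone transform of a gene's values.

A signature is a cluster's markers with q < 0.05 (a gate this package
declares; only "distinguishing" markers are eligible) and positive fold
change, sorted by decreasing fold change with ties broken
lexicographically by gene id, truncated to 20. A gene may appear in
several clusters' signatures; no exclusivity is imposed.

## Pseudobulk differential expression

Counts of cells sharing a cell type are summed per (subject, compartment,
cell type) for the compartment analysis, or pooled across compartments
per (subject, cell type) for the study-group analysis. A cell type enters
only with at least 100 cells in every compartment (resp. every study
group). Pairwise contrasts use only units at the two contrasted levels.

Per cell type and gene the model is NB(μ, α) with variance μ + αμ²,
log link, fixed effects per the analysis (subject and compartment for the
compartment contrast; group for the labor contrasts), and offset
log(size factor), with median-of-ratios size factors computed on
all-nonzero genes (total-count scaling when fewer than 50 such genes
exist). Coefficients are fitted by Fisher-scoring IRLS with
expected-information weights μ/(1+αμ); convergence is declared on
coefficient stability or on a likelihood plateau — the latter handles
separation (a gene absent from one stratum), where fitted means converge
while a coefficient diverges.

Dispersion is estimated per gene by maximizing the Cox-Reid-adjusted
profile log-likelihood (profile NB likelihood minus ½·logdet(X'WX)),
floored at 1e-8 and capped at 10, and then moderated across genes by an
empirical-Bayes normal prior on log α centered at the across-gene median,
with prior variance the observed spread of log estimates minus the
approximate sampling variance trigamma((m−p)/2), floored at 0.25. The
moderation is trendless (no mean–dispersion curve is fitted): with a
handful of pseudobulk units per gene, unmoderated per-gene dispersions
are variable enough to make the Wald test visibly anticonservative, while
referring the Wald statistic to a heavy-tailed small-sample distribution
instead destroys power at three subjects per arm; shrinkage resolves
both, which is why the established NB-GLM tools all moderate. A trend is
unnecessary here because the generator uses a single true dispersion; on
real data with a strong mean–dispersion relationship a trended prior
would be the natural extension.

Inference is a Wald test on the contrast coefficient (normal reference),
BH within (cell type, contrast); a gene is called at q < 0.1 **and**
fold change > 2 (|log₂FC| > 1). Non-convergent genes are flagged with
missing p; all-zero genes are skipped. No independent filtering and no
fold-change shrinkage are applied. For the shared/non-shared comparison
of term- and preterm-labor effects, a (gene, cell type) pair is "shared"
when both contrasts have q < 0.01 with the same sign; significant in one
only, "TIL-only"/"PTL-only"; otherwise (including the rare
both-significant-discordant case) "neither". Pearson correlations of the
two effect sizes are reported within major cell classes.

## Blood projection

Signature scores are the arithmetic mean of the member genes' log₂
values over the intersection with the measured panel (mean-log2 mode) or
the mean of per-gene Z-scores standardized by the control group's mean
and SD (mean-Z mode; zero-SD genes dropped with a warning). A score needs
at least 3 measured member genes — a 1–2 gene "signature average" is
indistinguishable from single-gene noise — and is missing otherwise;
absent genes are dropped, never imputed. Scores are invariant to gene
order, and control-group Z-scores average to zero per gene by
construction.

Gestational-age trajectories are modeled per signature on subjects with
exactly three longitudinal samples:
`score ~ B(GA) + (1 | subject)`, where `B` is a degree-2 B-spline basis
with one interior knot at the median GA (4 basis columns forming a
partition of unity, so no separate intercept). The model is fitted by
maximum likelihood — not REML — so the likelihood-ratio test against
`score ~ 1 + (1 | subject)` (χ², 3 df) is valid. Random intercepts only:
8 subjects per arm cannot support random slopes. On a singular or
non-convergent mixed fit the model falls back to fixed effects (OLS) with
a warning. Knot count and placement are config choices; one interior knot
is the most parsimonious basis that is genuinely "quadratic spline"
rather than a global quadratic.

Term labor (TIL vs TNL) is tested per signature by a two-tailed pooled-
variance t-test, preterm labor (PTL vs GA-matched controls) by a
two-sided Wilcoxon rank-sum (exact under 25 total observations without
ties). All three analyses are BH-corrected across signatures at q < 0.1.
The BH step-up implementation propagates missing p-values without
shrinking the family of tested hypotheses. In the longitudinal cohort the
labor effect exists at the delivery visit, so the analysis driver runs
the t-test on each subject's last sample; pooling all visits dilutes the
effect threefold and adds the GA trend to the within-group variance.

## Synthetic data

The single-cell generator emits NB counts (variance μ + αμ², matching the
GLM's parameterization; α = 0.1 by default) with a lognormal(0, 0.3)
per-cell size factor, for 6 cell types × 3 compartments × 3 study groups
at 40 cells per block (≈2,200 cells, 1,000 genes by default — the study's
structure at desk scale), three subjects per group of which one carries a
male fetus. Markers (25 per type, 4-fold enriched) are planted on
moderately expressed genes (baseline rate ≥ 0.25): a marker is by
definition detectably expressed in its own type, so planting one on a
near-silent gene would make "recovery" a property of the gene draw, not
of the test. Fetal cells of male-fetus pregnancies express 5 Y genes at
rate 2; maternal cells express none; XIST is high in any female cell.
Mitochondrial content is Beta(2, 38) (mean 5%) of each cell's expected
counts. Low-quality cells (5% by default) violate exactly one QC rule —
fewer than 200 detected genes, or mito fraction pushed to 15–50% — and
cells not flagged low-quality are guaranteed to pass QC: rare draws below
the detected-gene floor are topped up with single counts on ordinary
genes (never Y or MT) and mito overshoot is trimmed below the cutoff.
This makes the generator's QC contract exact rather than probabilistic.

Bulk cohorts are simulated directly on the log₂ scale (Gaussian; the
blood analyses operate on log₂-normalized values, so count-level realism
adds nothing): gene baselines N(5, 2), residual SD 0.3, subject random
intercept SD 0.3. The longitudinal design draws one sample per trimester
window (12–20, 21–30, 31–40 weeks) per subject; 5 of 10 twenty-gene
signatures carry a GA slope of 0.05 log₂-units/week, and 3 of those also
a 1.0 log₂ labor shift on the TIL arm's delivery visit. The
cross-sectional design draws both arms from the same uniform 24–34 week
GA distribution with a 0.3 log₂ (one residual SD) shift on 3 signatures.
The default panel is 3,000 genes (the real targeted panel's size is not
public; this is configurable), scaled to 600 in the replicated
simulation studies to keep them fast at single-CPU scale.

What the synthetic data do **not** contain: doublets, ambient RNA, batch
effects, mean–dispersion trends, zero inflation beyond NB sampling,
cluster-assignment errors (labels are ground truth, since clustering
itself is out of scope), or count-level noise in the blood panels.
Passing tests therefore establish the correctness and calibration of the
statistical machinery under the stated model, not robustness to those
artifacts.

## Numerical notes and limitations

- All randomness flows from explicit seeds through `numpy` Generators;
  every stage is bit-reproducible, and CLI run manifests contain no
  timestamps so reruns are byte-identical.
- Dispersion optimization is bounded on log α ∈ [ln 1e-8, ln 10] with a
  1e-3 tolerance; the floor is compared explicitly because the profile
  can be flat near zero.
- Result tables are plain TSV with deterministic row order and `NA` for
  missing values.
- The NB machinery is this package's own (size factors, CR dispersion,
  EB moderation, Wald): it is not a clone of any published tool and omits
  independent filtering, trended priors and fold-change shrinkage, so DE
  calls on real data would differ in detail from heavier frameworks.
- The origin classifier assumes at least two clusters with distinct
  indices and a real maternal/fetal mixture; a dataset of purely fetal
  clusters would be split anyway unless the margin rule catches it.
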