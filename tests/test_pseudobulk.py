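"""Pseudobulk aggregation (conservation, 100-cell rule) and the NB GLM
(Poisson limit, dispersion profiling, Wald calls, effect comparison)."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import statsmodels.api as sm

from scplacenta import (RunConfig, ScSimConfig, aggregate_pseudobulk,
                        compare_labor_effects, nb_glm_de, simulate_sc_dataset,
                        size_factors_median_ratio)
from scplacenta.pseudobulk import (DISPERSION_FLOOR, PseudobulkDataset,
                                   estimate_dispersion, irls_nb, nb_loglik)


@pytest.fixture(scope="module")
def sc_small(cfg):
    # 40 cells per (type, compartment, group) block -> 120 per compartment,
    # enough to clear the 100-cell rule
    adata, truth = simulate_sc_dataset(
        ScSimConfig(seed=61, n_cell_types=2, cells_per_type=40, n_genes=300))
    labels = truth.cells.set_index("barcode")["true_cluster"].reindex(adata.obs["barcode"])
    return adata, truth, labels


def brute_force_aggregate(adata, labels, grouping, min_cells):
    """Reference pass with explicit python loops."""
    X = np.asarray(sp.csr_matrix(adata.X).todense())
    obs = adata.obs.assign(cell_type=np.asarray(labels))
    stratum = "compartment" if grouping == "by_location" else "group"
    keep = []
    for ct in sorted(obs["cell_type"].unique()):
        ok = all(((obs["cell_type"] == ct) & (obs[stratum] == s)).sum() >= min_cells
                 for s in obs[stratum].unique())
        if ok:
            keep.append(ct)
    units = {}
    for i in range(len(obs)):
        r = obs.iloc[i]
        if r["cell_type"] not in keep:
            continue
        key = ((r["subject_id"], r["compartment"], r["cell_type"])
               if grouping == "by_location" else (r["subject_id"], r["cell_type"]))
        units.setdefault(key, np.zeros(X.shape[1]))
        units[key] += X[i]
    return units


class TestAggregate:
    @pytest.mark.parametrize("grouping", ["by_location", "by_group"])
    def test_matches_brute_force_and_conserves_counts(self, sc_small, cfg, grouping):
        adata, truth, labels = sc_small
        pb = aggregate_pseudobulk(adata, labels, grouping, cfg)
        ref = brute_force_aggregate(adata, labels, grouping, cfg.min_cells_per_pseudobulk)
        assert len(pb.units) == len(ref)
        for key, vec in ref.items():
            unit_id = "|".join(str(k) for k in key)
            assert np.array_equal(pb.counts[unit_id].to_numpy(), vec.astype(int))
        # total conservation over included cells
        included = pd.Series(np.asarray(labels)).isin(pb.units["cell_type"].unique())
        total_sc = sp.csr_matrix(adata.X)[included.to_numpy()].sum()
        assert pb.counts.to_numpy().sum() == total_sc

    def test_type_below_100_in_one_compartment_excluded(self, cfg):
        adata, truth = simulate_sc_dataset(
            ScSimConfig(seed=62, n_cell_types=2, cells_per_type=40, n_genes=300))
        labels = truth.cells.set_index("barcode")["true_cluster"].reindex(
            adata.obs["barcode"]).copy()
        # demote CT1 cells in BP until only 99 remain there
        in_bp = (adata.obs["compartment"] == "BP").to_numpy() & (labels == "CT1").to_numpy()
        assert in_bp.sum() >= 100
        drop = np.where(in_bp)[0][: in_bp.sum() - 99]
        labels.iloc[drop] = "CT0"
        pb = aggregate_pseudobulk(adata, labels, "by_location", cfg)
        assert "CT1" not in set(pb.units["cell_type"])
        assert "CT0" in set(pb.units["cell_type"])

    def test_no_surviving_type_is_error(self, sc_small):
        adata, truth, labels = sc_small
        strict = RunConfig(min_cells_per_pseudobulk=10_000)
        with pytest.raises(ValueError, match="minimum-cells"):
            aggregate_pseudobulk(adata, labels, "by_location", strict)

    def test_unknown_grouping_rejected(self, sc_small, cfg):
        adata, truth, labels = sc_small
        with pytest.raises(ValueError, match="grouping"):
            aggregate_pseudobulk(adata, labels, "by_donor", cfg)


def _toy_pb(seed=0, n_genes=60, n_per_arm=3, lfc=None, alpha=0.1,
            depth_spread=True, mean_log=4.0):
    """Direct pseudobulk-level NB simulation: one cell type, two groups."""
    rng = np.random.default_rng(seed)
    if lfc is None:
        lfc = np.zeros(n_genes)
    base = np.exp(rng.normal(mean_log, 1.0, n_genes))
    sf = np.exp(rng.uniform(-0.7, 0.7, 2 * n_per_arm)) if depth_spread else np.ones(2 * n_per_arm)
    mu = base[:, None] * sf[None, :]
    mu[:, :n_per_arm] *= 2.0 ** lfc[:, None]
    shape = 1.0 / alpha
    counts = rng.poisson(rng.gamma(shape, mu * alpha))
    units = pd.DataFrame({
        "unit_id": [f"u{i}" for i in range(2 * n_per_arm)],
        "subject_id": [f"s{i}" for i in range(2 * n_per_arm)],
        "compartment": pd.NA,
        "group": ["TIL"] * n_per_arm + ["TNL"] * n_per_arm,
        "cell_type": "CT0",
        "n_cells": 500,
    })
    pb = PseudobulkDataset(
        counts=pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                            columns=units["unit_id"]),
        units=units, grouping="by_group")
    return pb


class TestNBGLM:
    def test_poisson_limit_matches_irls_poisson_glm(self, cfg):
        pb = _toy_pb(seed=1, alpha=0.001)
        de = nb_glm_de(pb, ["group"], ("group", "TIL", "TNL"), cfg, dispersion=0.0)
        Y = pb.counts.to_numpy()
        sf = size_factors_median_ratio(Y)
        grp = (pb.units["group"] == "TIL").to_numpy(float)
        X = np.column_stack([np.ones_like(grp), grp])
        for i, g in enumerate(pb.counts.index):
            ref = sm.GLM(Y[i], X, family=sm.families.Poisson(),
                         offset=np.log(sf)).fit(tol=1e-12)
            got = de.set_index("gene_id").loc[g, "log2_fc"] * np.log(2.0)
            assert got == pytest.approx(ref.params[1], abs=1e-6)

    def test_dispersion_recovered_in_order_of_magnitude(self):
        # many units so the CR-adjusted profile has information to work with
        pb = _toy_pb(seed=2, n_per_arm=20, alpha=0.1)
        Y = pb.counts.to_numpy()
        sf = size_factors_median_ratio(Y)
        grp = (pb.units["group"] == "TIL").to_numpy(float)
        X = np.column_stack([np.ones_like(grp), grp])
        alphas = [estimate_dispersion(Y[i].astype(float), X, np.log(sf))
                  for i in range(30)]
        assert 0.03 < np.median(alphas) < 0.3

    def test_fc_below_2_not_significant_despite_low_q(self, cfg):
        # planted |log2FC| = 0.85 (fold change 1.8): q can be small but the
        # fold-change arm of the call rule must veto significance
        lfc = np.zeros(60)
        lfc[:10] = 0.85
        pb = _toy_pb(seed=3, n_per_arm=12, lfc=lfc, alpha=0.01)
        de = nb_glm_de(pb, ["group"], ("group", "TIL", "TNL"), cfg)
        hits = de.set_index("gene_id").loc[[f"g{i}" for i in range(10)]]
        assert (hits["bh_q"] < 0.1).any()          # detectable shift...
        assert not hits["significant"].any()       # ...but below the FC gate

    def test_null_simulation_centred_lfc(self, cfg):
        pb = _toy_pb(seed=4, n_genes=200)
        de = nb_glm_de(pb, ["group"], ("group", "TIL", "TNL"), cfg)
        assert abs(np.median(de["log2_fc"])) < 0.1
        assert not de["significant"].any() or de["significant"].mean() < 0.05

    def test_absent_contrast_level_names_available(self, cfg):
        pb = _toy_pb(seed=5)
        with pytest.raises(ValueError, match="PTL"):
            nb_glm_de(pb, ["group"], ("group", "PTL", "TNL"), cfg)

    def test_all_zero_gene_skipped(self, cfg):
        pb = _toy_pb(seed=6)
        pb.counts.iloc[0] = 0
        de = nb_glm_de(pb, ["group"], ("group", "TIL", "TNL"), cfg)
        assert "g0" not in set(de["gene_id"])

    def test_irls_matches_statsmodels_nb(self):
        pb = _toy_pb(seed=7)
        Y = pb.counts.to_numpy()
        sf = size_factors_median_ratio(Y)
        grp = (pb.units["group"] == "TIL").to_numpy(float)
        X = np.column_stack([np.ones_like(grp), grp])
        for i in range(10):
            beta, mu, cov = irls_nb(Y[i].astype(float), X, np.log(sf), 0.1)
            ref = sm.GLM(Y[i], X, family=sm.families.NegativeBinomial(alpha=0.1),
                         offset=np.log(sf)).fit(tol=1e-12)
            assert np.allclose(beta, ref.params, atol=1e-7)
            assert np.allclose(np.sqrt(np.diag(cov)), ref.bse, atol=1e-6)

    def test_size_factor_fallback_on_sparse_counts(self):
        counts = np.zeros((60, 4), dtype=int)
        counts[:5] = [[10, 20, 30, 40]] * 5  # only 5 all-nonzero genes
        sf = size_factors_median_ratio(counts)
        tot = counts.sum(axis=0)
        assert np.allclose(sf, tot / np.exp(np.mean(np.log(tot))))


class TestCompareLaborEffects:
    def _de(self, betas, qs):
        return pd.DataFrame({
            "cell_type": "CT0", "contrast": "x",
            "gene_id": [f"g{i}" for i in range(len(betas))],
            "log2_fc": betas, "bh_q": qs,
        })

    def test_identical_inputs_give_r_one_and_shared(self, cfg):
        rng = np.random.default_rng(0)
        betas = rng.normal(0, 2, 50)
        qs = np.full(50, 0.001)
        de = self._de(betas, qs)
        pairs, corr = compare_labor_effects(de, de, {"CT0": "immune"}, cfg)
        assert corr.loc[corr["cell_class"] == "immune", "pearson_r"].iloc[0] \
            == pytest.approx(1.0)
        assert (pairs["class"] == "shared").all()

    def test_til_only_classification(self, cfg):
        de_t = self._de([2.0, 1.0], [0.005, 0.5])
        de_p = self._de([1.5, 0.5], [0.5, 0.5])
        pairs, _ = compare_labor_effects(de_t, de_p, {"CT0": "immune"}, cfg)
        assert list(pairs["class"]) == ["TIL-only", "neither"]

    def test_independent_effects_near_zero_correlation(self, cfg):
        rng = np.random.default_rng(1)
        n = 1000
        de_t = self._de(rng.normal(0, 1, n), rng.random(n))
        de_p = self._de(rng.normal(0, 1, n), rng.random(n))
        _, corr = compare_labor_effects(de_t, de_p, {"CT0": "immune"}, cfg)
        assert abs(corr["pearson_r"].iloc[0]) < 0.1

    def test_discordant_sign_not_shared(self, cfg):
        de_t = self._de([2.0], [0.001])
        de_p = self._de([-2.0], [0.001])
        pairs, _ = compare_labor_effects(de_t, de_p, {"CT0": "immune"}, cfg)
        assert pairs["class"].iloc[0] == "neither"

    def test_disjoint_keys_rejected(self, cfg):
        de_t = self._de([1.0], [0.01])
        de_p = self._de([1.0], [0.01])
        de_p["gene_id"] = ["other"]
        with pytest.raises(ValueError, match="keys"):
            compare_labor_effects(de_t, de_p, {"CT0": "immune"}, cfg)
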