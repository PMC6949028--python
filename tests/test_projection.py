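"""Signature scoring arithmetic and the three blood-cohort tests."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from scplacenta import (BulkExpressionSet, BulkSimConfig, RunConfig,
                        compare_ptl_control, compare_til_tnl, fit_ga_trajectory,
                        score_signatures_mean, score_signatures_zscore,
                        simulate_bulk_longitudinal)
from scplacenta.projection import quadratic_spline_basis
from conftest import truth_signature_frames


def _toy_bulk(values, groups=None, ga=None, subjects=None):
    """genes x samples toy bulk set."""
    expr = pd.DataFrame(values)
    expr.index = [f"g{i}" for i in range(expr.shape[0])]
    expr.columns = [f"s{i}" for i in range(expr.shape[1])]
    n = expr.shape[1]
    samples = pd.DataFrame({
        "sample_id": expr.columns,
        "subject_id": subjects or [f"sub{i}" for i in range(n)],
        "gestational_age": ga if ga is not None else np.linspace(12, 40, n),
        "group": groups or ["TNL"] * n,
    })
    return BulkExpressionSet(expression=expr, samples=samples)


def _sig(genes):
    return {"S": pd.DataFrame({"gene_id": genes, "log_fc": np.nan})}


class TestMeanScoring:
    def test_single_gene_signature_equals_gene_value(self):
        bulk = _toy_bulk([[1.0, 2.0], [5.0, 6.0], [7.0, 8.0]])
        cfg = RunConfig(min_signature_genes_bulk=1)
        scores = score_signatures_mean(bulk, _sig(["g1"]), cfg)
        assert list(scores["S"]) == [5.0, 6.0]

    def test_constant_members_give_constant_score(self):
        bulk = _toy_bulk([[3.0, 3.0], [3.0, 3.0], [9.0, 9.0]])
        scores = score_signatures_mean(bulk, _sig(["g0", "g1", "g2"]))
        assert np.allclose(scores["S"], 5.0)

    def test_hand_computed_means_on_four_samples(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(5, 2, size=(20, 4))
        bulk = _toy_bulk(vals.tolist())
        genes = [f"g{i}" for i in range(20)]
        scores = score_signatures_mean(bulk, _sig(genes))
        assert np.allclose(scores["S"].to_numpy(), vals.mean(axis=0), atol=1e-12)

    def test_missing_genes_dropped_and_counted(self):
        bulk = _toy_bulk([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        cfg = RunConfig(min_signature_genes_bulk=2)
        scores = score_signatures_mean(bulk, _sig(["g0", "g2", "nope1", "nope2"]), cfg)
        assert scores.attrs["n_genes_used"]["S"] == 2
        assert list(scores["S"]) == [3.0, 4.0]

    def test_below_minimum_overlap_gives_missing_score(self):
        bulk = _toy_bulk([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        scores = score_signatures_mean(bulk, _sig(["g0", "g1", "nope"]))  # 2 < 3
        assert scores["S"].isna().all()

    def test_no_overlap_at_all_is_error(self):
        bulk = _toy_bulk([[1.0, 2.0]])
        with pytest.raises(ValueError, match="nope"):
            score_signatures_mean(bulk, _sig(["nope"]))

    def test_gene_order_irrelevant(self):
        rng = np.random.default_rng(1)
        bulk = _toy_bulk(rng.normal(size=(6, 3)).tolist())
        genes = [f"g{i}" for i in range(6)]
        s1 = score_signatures_mean(bulk, _sig(genes))
        s2 = score_signatures_mean(bulk, _sig(genes[::-1]))
        assert np.allclose(s1["S"], s2["S"])


class TestZScoring:
    def _bulk(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(5, 1, size=(10, 8))
        return _toy_bulk(vals.tolist(),
                         groups=["GA_control"] * 5 + ["PTL"] * 3)

    def test_control_mean_sample_scores_zero(self):
        bulk = self._bulk()
        ctrl = bulk.samples.loc[bulk.samples["group"] == "GA_control", "sample_id"]
        bulk.expression["s7"] = bulk.expression[ctrl].mean(axis=1)
        scores = score_signatures_zscore(bulk, _sig([f"g{i}" for i in range(10)]),
                                         "GA_control")
        assert scores.loc["s7", "S"] == pytest.approx(0.0, abs=1e-12)

    def test_one_sd_above_mean_single_gene(self):
        bulk = self._bulk()
        ctrl = bulk.samples.loc[bulk.samples["group"] == "GA_control", "sample_id"]
        mu = bulk.expression.loc["g0", ctrl].mean()
        sd = bulk.expression.loc["g0", ctrl].std(ddof=1)
        bulk.expression.loc["g0", "s7"] = mu + sd
        cfg = RunConfig(min_signature_genes_bulk=1)
        scores = score_signatures_zscore(bulk, _sig(["g0"]), "GA_control", cfg)
        assert scores.loc["s7", "S"] == pytest.approx(1.0, abs=1e-10)

    def test_brute_force_recomputation(self):
        bulk = self._bulk()
        genes = [f"g{i}" for i in range(10)]
        scores = score_signatures_zscore(bulk, _sig(genes), "GA_control")
        ctrl = bulk.samples.loc[bulk.samples["group"] == "GA_control", "sample_id"]
        for s in bulk.expression.columns:
            acc = [(bulk.expression.loc[g, s] - bulk.expression.loc[g, ctrl].mean())
                   / bulk.expression.loc[g, ctrl].std(ddof=1) for g in genes]
            assert scores.loc[s, "S"] == pytest.approx(np.mean(acc), abs=1e-12)

    def test_control_group_required(self):
        bulk = self._bulk()
        with pytest.raises(ValueError, match="absent"):
            score_signatures_zscore(bulk, _sig(["g0"]), "TNL")


class TestGroupTests:
    def test_t_test_matches_textbook_pooled_formula(self):
        bulk = _toy_bulk(np.tile([[1, 2, 3, 4, 5, 6]], (3, 1)).astype(float).tolist(),
                         groups=["TIL"] * 3 + ["TNL"] * 3)
        scores = score_signatures_mean(bulk, _sig(["g0", "g1", "g2"]))
        res = compare_til_tnl(scores, bulk)
        a, b = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        sp2 = ((a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p_hand = 2 * scipy.stats.t.sf(abs(t_hand), 4)
        assert res["statistic"].iloc[0] == pytest.approx(t_hand, abs=1e-12)
        assert res["p_value"].iloc[0] == pytest.approx(p_hand, abs=1e-12)
        assert res["direction"].iloc[0] == "down"

    def test_identical_groups_t_zero_p_one(self):
        bulk = _toy_bulk([[1.0, 2, 3, 1, 2, 3]], groups=["TIL"] * 3 + ["TNL"] * 3)
        scores = score_signatures_mean(bulk, _sig(["g0"]),
                                       RunConfig(min_signature_genes_bulk=1))
        res = compare_til_tnl(scores, bulk)
        assert res["statistic"].iloc[0] == pytest.approx(0.0)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_zero_pooled_variance_leaves_p_missing(self, caplog):
        bulk = _toy_bulk([[2.0, 2, 2, 2, 2]], groups=["TIL"] * 2 + ["TNL"] * 3)
        scores = score_signatures_mean(bulk, _sig(["g0"]),
                                       RunConfig(min_signature_genes_bulk=1))
        with caplog.at_level("WARNING"):
            res = compare_til_tnl(scores, bulk)
        assert np.isnan(res["p_value"].iloc[0])

    def test_wilcoxon_matches_exact_enumeration(self):
        bulk = _toy_bulk([[1.0, 2, 3, 10, 11, 12, 13]],
                         groups=["PTL"] * 3 + ["GA_control"] * 4)
        scores = score_signatures_mean(bulk, _sig(["g0"]),
                                       RunConfig(min_signature_genes_bulk=1))
        res = compare_ptl_control(scores, bulk)
        # most extreme of the C(7,3)=35 rank splits, two-sided
        assert res["p_value"].iloc[0] == pytest.approx(2 / 35, abs=1e-12)
        assert res["statistic"].iloc[0] == 0.0  # U of the PTL arm

    def test_wilcoxon_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(1, 30))
        groups = ["PTL"] * 14 + ["GA_control"] * 16
        cfg = RunConfig(min_signature_genes_bulk=1)
        b1 = _toy_bulk(vals.tolist(), groups=groups)
        b2 = _toy_bulk(np.exp(vals).tolist(), groups=groups)
        p1 = compare_ptl_control(score_signatures_mean(b1, _sig(["g0"]), cfg), b1)
        p2 = compare_ptl_control(score_signatures_mean(b2, _sig(["g0"]), cfg), b2)
        assert p1["p_value"].iloc[0] == pytest.approx(p2["p_value"].iloc[0], abs=1e-12)

    def test_permutation_null_uniform_p(self):
        # label permutations of null data: p below alpha at about alpha rate
        rng = np.random.default_rng(4)
        vals = rng.normal(size=30)
        cfg = RunConfig(min_signature_genes_bulk=1)
        ps = []
        for _ in range(200):
            perm = rng.permutation(30)
            groups = np.array(["TIL"] * 15 + ["TNL"] * 15)[perm]
            bulk = _toy_bulk([vals.tolist()], groups=list(groups))
            scores = score_signatures_mean(bulk, _sig(["g0"]), cfg)
            ps.append(compare_til_tnl(scores, bulk)["p_value"].iloc[0])
        ks = scipy.stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestTrajectory:
    def test_spline_basis_partitions_unity(self):
        ga = np.linspace(12, 40, 50)
        B = quadratic_spline_basis(ga, 26.0, 12.0, 40.0)
        assert B.shape == (50, 4)
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_subject_with_two_samples_excluded(self, cfg):
        bulk, truth = simulate_bulk_longitudinal(BulkSimConfig(seed=71, n_genes=300))
        # drop one sample from one subject
        drop = bulk.samples.iloc[0]["sample_id"]
        bulk2 = BulkExpressionSet(
            expression=bulk.expression.drop(columns=[drop]),
            samples=bulk.samples[bulk.samples["sample_id"] != drop].reset_index(drop=True))
        sigs = truth_signature_frames(truth)
        scores = score_signatures_mean(bulk2, sigs, cfg)
        fit = fit_ga_trajectory(scores, bulk2, cfg)
        assert (fit["n_subjects"] == 15).all()
        assert (fit["n_samples"] == 45).all()

    def test_planted_ga_signatures_detected_nulls_spared(self, cfg,
                                                         bulk_longitudinal):
        bulk, truth = bulk_longitudinal
        sigs = truth_signature_frames(truth)
        scores = score_signatures_mean(bulk, sigs, cfg)
        fit = fit_ga_trajectory(scores, bulk, cfg).set_index("signature_id")
        planted = truth.signatures.loc[truth.signatures["ga_slope"] != 0, "signature_id"]
        assert fit.loc[planted, "significant"].all()
        nulls = truth.signatures.loc[
            (truth.signatures["ga_slope"] == 0)
            & (truth.signatures["labor_effect"] == 0), "signature_id"]
        # nulls cannot all be flagged; allow the odd FDR-budget false positive
        assert fit.loc[nulls, "significant"].mean() <= 0.4

    def test_too_few_subjects_rejected(self, cfg):
        bulk, truth = simulate_bulk_longitudinal(
            BulkSimConfig(seed=72, n_genes=300, n_subjects_arm1=2, n_subjects_arm2=2))
        sigs = truth_signature_frames(truth)
        scores = score_signatures_mean(bulk, sigs, cfg)
        with pytest.raises(ValueError, match="6 subjects"):
            fit_ga_trajectory(scores, bulk, cfg)
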