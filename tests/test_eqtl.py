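"""eQTL stage: normalization, factors, kinship, imputation, the mixed
model, LD background, blocks, hotspots and master-regulator ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from svdomest import eqtl as eq


def _acc(n):
    return [f"a{i}" for i in range(n)]


class TestNormalization:
    def test_fpkm_formula(self):
        counts = pd.DataFrame({"s1": [10]}, index=["g1"])
        fpkm = eq.fpkm_from_counts(
            counts, pd.Series({"g1": 1_000}), pd.Series({"s1": 1_000_000})
        )
        assert fpkm.loc["g1", "s1"] == pytest.approx(10.0)

    def test_median_zero_genes_are_dropped(self):
        rng = np.random.default_rng(0)
        fpkm = pd.DataFrame(
            rng.uniform(1, 10, size=(5, 20)), index=[f"g{i}" for i in range(5)],
            columns=_acc(20),
        )
        fpkm.loc["g2", :] = 0.0
        fpkm.loc["g2", ["a0", "a1"]] = 5.0  # median still zero
        out = eq.normalize_expression(fpkm=fpkm)
        assert "g2" not in out.values.index

    def test_qq_transform_is_rank_preserving_and_centered(self):
        rng = np.random.default_rng(1)
        fpkm = pd.DataFrame(
            rng.lognormal(1, 1, size=(3, 50)), index=["g0", "g1", "g2"],
            columns=_acc(50),
        )
        out = eq.quantile_normal_transform(fpkm)
        for g in fpkm.index:
            assert (
                fpkm.loc[g].rank().values == out.loc[g].rank().values
            ).all()
            assert abs(out.loc[g].mean()) < 1e-6

    def test_pca_outlier_accession_is_removed(self):
        rng = np.random.default_rng(2)
        fpkm = pd.DataFrame(
            rng.uniform(1, 5, size=(40, 30)), columns=_acc(30),
            index=[f"g{i}" for i in range(40)],
        )
        fpkm["a7"] = fpkm["a7"] + 40.0  # gross outlier on PC1
        out = eq.normalize_expression(fpkm=fpkm)
        assert "a7" not in out.values.columns

    def test_too_few_accessions_raises(self):
        fpkm = pd.DataFrame(np.ones((5, 3)) + np.eye(5, 3), columns=_acc(3))
        with pytest.raises(ValueError, match="fewer than 4"):
            eq.normalize_expression(fpkm=fpkm)


class TestHiddenFactors:
    def _expr(self, values):
        return eq.ExpressionMatrix(
            values=values, genes=pd.DataFrame(index=values.index),
            stage="qq_normalized",
        )

    def test_rank_one_structure_dominates_factor_one(self):
        rng = np.random.default_rng(3)
        u = rng.normal(size=50)
        v = rng.normal(size=30)
        values = pd.DataFrame(
            np.outer(u, v) + 1e-3 * rng.normal(size=(50, 30)), columns=_acc(30)
        )
        fac = eq.derive_hidden_factors(self._expr(values), k=5)
        var = fac.var(axis=0)
        assert var.iloc[0] / var.sum() > 0.99

    def test_k_zero_gives_empty_table(self):
        values = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 10)), columns=_acc(10))
        fac = eq.derive_hidden_factors(self._expr(values), k=0)
        assert fac.shape == (10, 0)

    def test_factors_are_orthogonal(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(rng.normal(size=(40, 25)), columns=_acc(25))
        fac = eq.derive_hidden_factors(self._expr(values), k=6).values
        gram = fac.T @ fac
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_k_at_least_n_raises(self):
        values = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 10)), columns=_acc(10))
        with pytest.raises(ValueError):
            eq.derive_hidden_factors(self._expr(values), k=10)


class TestKinship:
    def test_identical_accessions_match_diagonal(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.4, size=(100, 10)).astype(float)
        g[:, 1] = g[:, 0]
        D = pd.DataFrame(g, columns=_acc(10))
        K = eq.compute_kinship(D)
        assert K.iloc[0, 1] == pytest.approx(K.iloc[0, 0])

    def test_symmetric(self):
        rng = np.random.default_rng(6)
        D = pd.DataFrame(rng.binomial(2, 0.3, size=(80, 15)).astype(float), columns=_acc(15))
        K = eq.compute_kinship(D).values
        assert np.abs(K - K.T).max() == 0.0

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(7)
        D = pd.DataFrame(rng.binomial(2, 0.3, size=(120, 20)).astype(float), columns=_acc(20))
        K = eq.compute_kinship(D).values
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_monomorphic_only_raises(self):
        D = pd.DataFrame(np.full((10, 5), 2.0), columns=_acc(5))
        with pytest.raises(ValueError):
            eq.compute_kinship(D)


class TestImputation:
    def test_params_validation(self):
        with pytest.raises(ValueError):
            eq.ImputationParams(w=2, k=5)
        with pytest.raises(ValueError):
            eq.ImputationParams(r=0.0)

    def test_unanimous_neighbours_fill_the_missing_dosage(self):
        rng = np.random.default_rng(8)
        base = rng.binomial(2, 0.5, size=(30, 1))
        D = pd.DataFrame(np.repeat(base, 8, axis=1).astype(float), columns=_acc(8))
        D.iloc[10, 0] = np.nan
        out = eq.knn_impute(D, eq.ImputationParams(w=10, k=3, p=-7, r=0.8))
        assert out.iloc[10, 0] == base[10, 0]

    def test_low_concordance_leaves_missing(self):
        # two equidistant neighbour clades voting 0 vs 2: no 80% majority
        D = pd.DataFrame(
            np.array([[0.0, 0.0, 2.0, 2.0, np.nan]] * 11).T.reshape(5, 11).T,
            columns=_acc(5),
        )
        out = eq.knn_impute(D, eq.ImputationParams(w=11, k=4, p=-1, r=0.8))
        assert np.isnan(out.iloc[5, 4])

    def test_non_missing_entries_are_untouched(self):
        rng = np.random.default_rng(9)
        D = pd.DataFrame(rng.binomial(2, 0.4, size=(40, 12)).astype(float), columns=_acc(12))
        mask = rng.random(D.shape) < 0.1
        Dm = D.mask(pd.DataFrame(mask, index=D.index, columns=D.columns))
        out = eq.knn_impute(Dm)
        called = ~Dm.isna().values
        assert (out.values[called] == Dm.values[called]).all()

    def test_masking_experiment_accuracy(self, small_population):
        _, _, m = small_population
        res = eq.imputation_masking_experiment(m.dosage(), 0.10, seed=0)
        assert res["accuracy"] >= 0.9
        assert res["filling_rate"] > 0.5


class TestBonferroni:
    def test_printed_thresholds_at_both_alphas(self):
        thr, lg = eq.bonferroni_threshold(0.05, 71_684)
        assert thr == pytest.approx(6.97e-7, rel=5e-3)
        assert lg == pytest.approx(6.15, abs=0.01)
        thr1, lg1 = eq.bonferroni_threshold(1.0, 71_684)
        assert thr1 == pytest.approx(1.40e-5, rel=5e-3)
        assert lg1 == pytest.approx(4.85, abs=0.01)

    def test_single_test_threshold_is_alpha(self):
        thr, _ = eq.bonferroni_threshold(0.05, 1)
        assert thr == 0.05

    def test_product_recovers_alpha_exactly(self):
        for m in (1, 7, 71_684):
            thr, _ = eq.bonferroni_threshold(0.05, m)
            assert thr * m == pytest.approx(0.05, rel=1e-12)

    def test_invalid_alpha_raises(self):
        with pytest.raises(ValueError):
            eq.bonferroni_threshold(0.0, 10)


class TestAssociation:
    def test_identity_kinship_matches_ols_to_three_sig_figs(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        n = 60
        acc = _acc(n)
        G = pd.DataFrame(rng.binomial(2, 0.4, size=(30, n)).astype(float),
                         index=[f"sv{i}" for i in range(30)], columns=acc)
        y = pd.Series(rng.normal(size=n) + 0.5 * G.iloc[0].values, index=acc)
        K = pd.DataFrame(np.eye(n), index=acc, columns=acc)
        res = eq.association_scan(y, G, None, K).set_index("sv")
        for sv in ["sv0", "sv5", "sv17"]:
            fit = sm.OLS(y.values, sm.add_constant(G.loc[sv].values)).fit()
            assert res.loc[sv, "p"] == pytest.approx(fit.pvalues[1], rel=1e-3)
            assert res.loc[sv, "beta"] == pytest.approx(fit.params[1], rel=1e-3)

    def test_planted_effect_is_detected(self):
        rng = np.random.default_rng(11)
        n = 150
        acc = _acc(n)
        G = pd.DataFrame(rng.binomial(2, 0.4, size=(50, n)).astype(float),
                         index=[f"sv{i}" for i in range(50)], columns=acc)
        y = pd.Series(1.5 * G.iloc[7].values + rng.normal(size=n), index=acc)
        K = eq.compute_kinship(G)
        res = eq.association_scan(y, G, None, K).set_index("sv")
        assert res["p"].idxmin() == "sv7"
        assert res.loc["sv7", "p"] < 6.97e-7

    def test_planted_cis_power_across_replicates(self):
        """beta = 1.5 at n = 150, noise SD 1: the causal SV's p stays below
        the genome-wide threshold 6.97e-7 in >= 90% of replicates."""
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(200 + rep)
            n = 150
            acc = _acc(n)
            G = pd.DataFrame(rng.binomial(2, 0.4, size=(40, n)).astype(float),
                             index=[f"sv{i}" for i in range(40)], columns=acc)
            y = pd.Series(1.5 * G.loc["sv3"].values + rng.normal(size=n), index=acc)
            K = eq.compute_kinship(G)
            res = eq.association_scan(y, G, None, K).set_index("sv")
            hits += int(res["p"].idxmin() == "sv3" and res.loc["sv3", "p"] < 6.97e-7)
        assert hits >= 9

    def test_zero_variance_sv_is_excluded(self):
        rng = np.random.default_rng(12)
        n = 40
        acc = _acc(n)
        G = pd.DataFrame(rng.binomial(2, 0.5, size=(5, n)).astype(float),
                         index=[f"sv{i}" for i in range(5)], columns=acc)
        G.loc["sv3"] = 2.0
        y = pd.Series(rng.normal(size=n), index=acc)
        K = pd.DataFrame(np.eye(n), index=acc, columns=acc)
        res = eq.association_scan(y, G, None, K)
        assert "sv3" not in set(res["sv"])

    def test_maf_and_missing_filters(self):
        rng = np.random.default_rng(13)
        n = 100
        G = pd.DataFrame(rng.binomial(2, 0.3, size=(4, n)).astype(float),
                         index=["ok", "rare", "gappy", "ok2"], columns=_acc(n))
        G.loc["rare"] = 0.0
        G.loc["rare", "a0"] = 1.0  # MAF 0.005
        G.loc["gappy", G.columns[: int(0.5 * n)]] = np.nan
        out = eq.filter_sv_dosages(G)
        assert set(out.index) == {"ok", "ok2"}


class TestLDBackground:
    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(14)
        x = rng.binomial(2, 0.5, size=200).astype(float)
        assert eq.pairwise_r2(x, x) == pytest.approx(1.0)

    def test_independent_sites_have_r2_near_1_over_n(self):
        rng = np.random.default_rng(15)
        n = 200
        r2s = [
            eq.pairwise_r2(
                rng.binomial(2, 0.5, size=n).astype(float),
                rng.binomial(2, 0.5, size=n).astype(float),
            )
            for _ in range(400)
        ]
        assert np.mean(r2s) == pytest.approx(1 / n, rel=0.5)

    def test_background_estimate_on_block_structured_data(self):
        rng = np.random.default_rng(16)
        n_acc, n_sites = 120, 150
        hap = rng.binomial(1, 0.5, size=(n_acc, n_sites // 10))
        G = np.repeat(hap, 10, axis=1) * 2.0  # 10-site blocks in perfect LD
        flip = rng.random(G.shape) < 0.1
        G = np.where(flip, 2 - G, G)
        D = pd.DataFrame(G.T, columns=_acc(n_acc),
                         index=[f"sv{i}" for i in range(n_sites)])
        pos = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(n_sites) * 50_000}, index=D.index
        )
        bg, dist = eq.ld_background(D, pos, max_dist=7e6, bin_width=100_000)
        assert bg < 0.2  # unlinked blocks ~ 1/n
        assert 200_000 <= dist <= 2_000_000  # blocks span 500 kb


class TestBlocks:
    def _inputs(self):
        rng = np.random.default_rng(17)
        n = 100
        acc = _acc(n)
        base = rng.binomial(2, 0.5, size=n).astype(float)
        G = pd.DataFrame(
            {f"sv{i}": np.where(rng.random(n) < 0.05, 2 - base, base) for i in range(6)}
        ).T
        G.columns = acc
        G.loc["far"] = rng.binomial(2, 0.5, size=n).astype(float)
        pos = pd.DataFrame(
            {"chrom": ["chr1"] * 6 + ["chr2"],
             "pos": [100_000 + 10_000 * i for i in range(6)] + [5_000_000]},
            index=list(G.index),
        )
        genes = pd.DataFrame(
            {"chrom": ["chr1", "chr2"], "tss": [100_000, 200_000], "tes": [105_000, 195_000]},
            index=["geneA", "geneB"],
        )
        return G, pos, genes

    def test_cis_block_contains_linked_significant_svs(self):
        G, pos, genes = self._inputs()
        res = pd.DataFrame(
            {"gene": "geneA", "sv": [f"sv{i}" for i in range(6)],
             "p": [1e-9, 1e-8, 1e-7, 1e-8, 1e-6, 1e-7], "beta": 1.0}
        )
        blocks = eq.build_eqtl_blocks(res, pos, genes, G, r2_bg=0.2,
                                      dist_bg=1_000_000, sig_threshold=1e-5)
        assert len(blocks) == 1
        b = blocks.iloc[0]
        assert b["class"] == "cis" and b["lead_sv"] == "sv0" and b["n_svs"] == 6

    def test_lead_on_other_chromosome_is_trans(self):
        G, pos, genes = self._inputs()
        res = pd.DataFrame(
            {"gene": "geneB", "sv": [f"sv{i}" for i in range(6)],
             "p": [1e-9] * 6, "beta": 1.0}
        )
        blocks = eq.build_eqtl_blocks(res, pos, genes, G, 0.2, 1_000_000, 1e-5)
        assert blocks.iloc[0]["class"] == "trans"

    def test_two_member_chain_is_not_a_block(self):
        G, pos, genes = self._inputs()
        res = pd.DataFrame(
            {"gene": "geneA", "sv": ["sv0", "sv1"], "p": [1e-9, 1e-9], "beta": 1.0}
        )
        blocks = eq.build_eqtl_blocks(res, pos, genes, G, 0.2, 1_000_000, 1e-5)
        assert len(blocks) == 0

    def test_cis_window_boundary_at_35kb(self):
        G, pos, genes = self._inputs()
        genes2 = genes.copy()
        genes2.loc["geneA", ["tss", "tes"]] = [100_000, 105_000]
        pos2 = pos.copy()
        pos2.loc[:, "pos"] = [140_000 + 10_000 * i for i in range(6)] + [5_000_000]
        res = pd.DataFrame(
            {"gene": "geneA", "sv": [f"sv{i}" for i in range(6)],
             "p": [1e-9, 1e-8, 1e-7, 1e-8, 1e-6, 1e-7], "beta": 1.0}
        )
        blocks = eq.build_eqtl_blocks(res, pos2, genes2, G, 0.2, 1_000_000, 1e-5)
        assert blocks.iloc[0]["class"] == "cis"  # lead at 140 kb, TES 105 kb

    def test_output_invariant_to_input_order(self):
        G, pos, genes = self._inputs()
        res = pd.DataFrame(
            {"gene": "geneA", "sv": [f"sv{i}" for i in range(6)],
             "p": [1e-9, 1e-8, 1e-7, 1e-8, 1e-6, 1e-7], "beta": 1.0}
        )
        b1 = eq.build_eqtl_blocks(res, pos, genes, G, 0.2, 1_000_000, 1e-5)
        b2 = eq.build_eqtl_blocks(res.iloc[::-1].reset_index(drop=True),
                                  pos, genes, G, 0.2, 1_000_000, 1e-5)
        pd.testing.assert_frame_equal(b1, b2)

    def test_cis_trans_partition_is_exhaustive(self):
        G, pos, genes = self._inputs()
        res = pd.DataFrame(
            {"gene": ["geneA"] * 6 + ["geneB"] * 6,
             "sv": [f"sv{i}" for i in range(6)] * 2,
             "p": [1e-9] * 12, "beta": 1.0}
        )
        blocks = eq.build_eqtl_blocks(res, pos, genes, G, 0.2, 1_000_000, 1e-5)
        assert (blocks["class"].isin(["cis", "trans"])).all()
        assert (blocks["class"] == "cis").sum() + (blocks["class"] == "trans").sum() == len(blocks)


class TestHotspots:
    def test_concentrated_targets_yield_significant_window(self):
        rng = np.random.default_rng(18)
        rows = []
        for i in range(30):
            rows.append(dict(gene=f"t{i}", chrom="chr1",
                             lead_pos=1_000_000 + int(rng.integers(0, 40_000))))
        for i in range(10):
            rows.append(dict(gene=f"u{i}", chrom="chr1",
                             lead_pos=int(rng.uniform(0, 100_000_000))))
        blocks = pd.DataFrame(rows)
        hs = eq.detect_hotspots(blocks, genome_span={"chr1": (0, 100_000_000)})
        assert len(hs) >= 1
        top = hs.sort_values("n_targets").iloc[-1]
        assert top["start"] <= 1_000_000 <= top["end"]
        assert top["adj_p"] < 0.05

    def test_uniform_targets_rarely_significant(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            blocks = pd.DataFrame(
                dict(gene=[f"g{i}" for i in range(40)], chrom="chr1",
                     lead_pos=rng.uniform(0, 100_000_000, size=40).astype(int))
            )
            hs = eq.detect_hotspots(blocks, genome_span={"chr1": (0, 100_000_000)})
            hits += len(hs)
        assert hits <= 1

    def test_empty_trans_set_gives_empty_output(self):
        assert len(eq.detect_hotspots(pd.DataFrame(columns=["gene", "chrom", "lead_pos"]))) == 0


class TestMasterRegulator:
    def test_minimal_hypergeometric_prefix_oracle(self):
        # prefix holding all t targets and nothing else: p = 1 / C(N, t)
        N, t = 12, 4
        flags = [True] * t + [False] * (N - t)
        assert eq.iga_enrichment_p(flags) == pytest.approx(1 / comb(N, t), rel=1e-9)

    def test_single_window_gene_is_returned(self):
        rng = np.random.default_rng(19)
        values = pd.DataFrame(rng.normal(size=(10, 30)), columns=_acc(30),
                              index=[f"g{i}" for i in range(10)])
        expr = eq.ExpressionMatrix(values=values, genes=pd.DataFrame(index=values.index),
                                   stage="qq_normalized")
        out = eq.rank_master_regulator(["g1", "g2"], expr, ["g5"])
        assert list(out["candidate"]) == ["g5"]

    def test_true_regulator_ranks_first(self):
        rng = np.random.default_rng(20)
        n = 100
        reg = rng.normal(size=n)
        rows = {"reg": reg, "decoy": rng.normal(size=n)}
        for i in range(10):
            rows[f"t{i}"] = reg + 0.7 * rng.normal(size=n)
        for i in range(30):
            rows[f"n{i}"] = rng.normal(size=n)
        values = pd.DataFrame(rows).T
        values.columns = _acc(n)
        expr = eq.ExpressionMatrix(values=values, genes=pd.DataFrame(index=values.index),
                                   stage="qq_normalized")
        out = eq.rank_master_regulator([f"t{i}" for i in range(10)], expr, ["reg", "decoy"])
        assert out.iloc[0]["candidate"] == "reg"

    def test_no_expressed_window_gene_raises(self):
        values = pd.DataFrame(np.ones((2, 5)), index=["g1", "g2"], columns=_acc(5))
        expr = eq.ExpressionMatrix(values=values, genes=pd.DataFrame(index=values.index),
                                   stage="qq_normalized")
        with pytest.raises(ValueError):
            eq.rank_master_regulator(["g1"], expr, ["absent"])
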