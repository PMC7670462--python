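"""Generator contracts: genome arithmetic, genotype marginals, read
evidence soundness and expression effects."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from svdomest import genotyping as gt
from svdomest.records import A_HOM, B_HOM, HET
from svdomest.simulate import (
    SimulationConfig,
    plan_eqtl_effects,
    plan_truth,
    simulate_expression,
    simulate_genome_pair,
    simulate_population_genotypes,
    simulate_read_evidence,
)


class TestGenomePair:
    def test_no_variants_gives_identical_genomes(self):
        cfg = SimulationConfig(
            seed=1, n_chromosomes=1, chrom_length=50_000,
            n_deletions=0, n_insertions=0, n_inversions=0, snp_rate=0.0,
        )
        a, b, truth = simulate_genome_pair(cfg)
        assert a == b
        assert len(truth.svs) == 0 and len(truth.snps) == 0

    def test_deletions_shrink_genome_b_by_their_total_size(self):
        cfg = SimulationConfig(
            seed=2, n_chromosomes=1, chrom_length=120_000,
            n_deletions=10, n_insertions=0, n_inversions=0, snp_rate=0.0,
        )
        a, b, truth = simulate_genome_pair(cfg)
        assert len(a["chr1"]) - len(b["chr1"]) == truth.svs["size"].sum()

    def test_inversions_preserve_genome_length(self):
        cfg = SimulationConfig(
            seed=3, n_chromosomes=1, chrom_length=100_000,
            n_deletions=0, n_insertions=0, n_inversions=1, snp_rate=0.0,
        )
        a, b, truth = simulate_genome_pair(cfg)
        assert len(a["chr1"]) == len(b["chr1"])
        sv = truth.sv_records()[0]
        # planted segment really is reverse-complemented on B
        seg_a = a["chr1"][sv.start_a : sv.end_a]
        seg_b = b["chr1"][sv.start_b : sv.end_b]
        comp = str.maketrans("ACGT", "TGCA")
        assert seg_b == seg_a.translate(comp)[::-1]

    def test_b_coordinates_track_insertions(self):
        cfg = SimulationConfig(
            seed=4, n_chromosomes=1, chrom_length=120_000,
            n_deletions=0, n_insertions=6, n_inversions=0, snp_rate=0.0,
        )
        a, b, truth = simulate_genome_pair(cfg)
        assert len(b["chr1"]) - len(a["chr1"]) == truth.svs["size"].sum()
        for sv in truth.sv_records():
            assert sv.end_b - sv.start_b == sv.size

    def test_overfull_plan_raises_naming_chromosome(self):
        cfg = SimulationConfig(
            seed=5, n_chromosomes=1, chrom_length=15_000,
            n_deletions=30, n_insertions=0, n_inversions=0,
            sv_size_range=(900, 1_000),
        )
        with pytest.raises(ValueError, match="chr1"):
            simulate_genome_pair(cfg)

    def test_same_seed_is_byte_identical(self):
        cfg = SimulationConfig(seed=6, n_chromosomes=1, chrom_length=60_000)
        a1, b1, t1 = simulate_genome_pair(cfg)
        a2, b2, t2 = simulate_genome_pair(cfg)
        assert a1 == a2 and b1 == b2
        pd.testing.assert_frame_equal(t1.svs, t2.svs)


class TestPopulationGenotypes:
    def test_fixed_locus_is_homozygous_everywhere(self):
        cfg = SimulationConfig(
            seed=8, n_chromosomes=1, chrom_length=2_000_000,
            n_deletions=30, n_insertions=0, n_inversions=0,
            group_sizes=(20, 20, 20, 20), missing_rate=0.0,
            selected_loci=[(0, (1.0, 1.0, 1.0, 1.0)), (1, (0.0, 0.0, 0.0, 0.0))],
        )
        truth = plan_truth(cfg)
        m = simulate_population_genotypes(truth, cfg)
        assert (m.calls.iloc[0] == A_HOM).all()
        assert (m.calls.iloc[1] == B_HOM).all()

    def test_sweep_target_frequency_within_binomial_error(self):
        cfg = SimulationConfig(
            seed=9, n_chromosomes=1, chrom_length=5_000_000,
            n_deletions=50, n_insertions=50, n_inversions=0,
            group_sizes=(100, 100, 100, 100), missing_rate=0.0, inbreeding=0.0,
            selected_loci=[(3, (0.6, 0.3, 0.05, 0.05))],
        )
        truth = plan_truth(cfg)
        m = simulate_population_genotypes(truth, cfg)
        sv = truth.svs["id"].iloc[3]
        modern = m.calls.loc[sv, m.groups == "modern"].astype(float)
        freq = modern.sum() / (2 * len(modern))
        se = np.sqrt(0.05 * 0.95 / (2 * len(modern)))
        assert abs(freq - 0.05) <= 3 * se

    def test_realized_frequency_matches_allele_counting(self, small_population):
        _, _, m = small_population
        row = m.calls.iloc[0].dropna().astype(int)
        f_dosage = row.sum() / (2 * len(row))
        f_counted = (2 * (row == 2).sum() + (row == 1).sum()) / (2 * len(row))
        assert f_dosage == f_counted

    def test_zero_group_with_nonzero_trajectory_raises(self):
        cfg = SimulationConfig(
            seed=10, n_chromosomes=1, chrom_length=1_000_000,
            n_deletions=10, n_insertions=0, n_inversions=0,
            group_sizes=(10, 0, 10, 10),
        )
        truth = plan_truth(cfg)
        with pytest.raises(ValueError, match="SLC"):
            simulate_population_genotypes(truth, cfg)

    def test_determinism(self, small_population):
        cfg, truth, m = small_population
        m2 = simulate_population_genotypes(plan_truth(cfg), cfg)
        assert m.calls.equals(m2.calls)

    def test_empty_truth_raises(self):
        cfg = SimulationConfig(
            seed=1, n_deletions=0, n_insertions=0, n_inversions=0
        )
        with pytest.raises(ValueError):
            simulate_population_genotypes(plan_truth(cfg), cfg)


class TestReadEvidence:
    @pytest.mark.parametrize("true_gt", [A_HOM, B_HOM, HET])
    def test_deletion_evidence_matches_genotype(self, toy_genomes, true_gt):
        cfg, ga, gb, truth = toy_genomes
        sv = next(s for s in truth.sv_records() if s.sv_type == "deletion")
        rng = np.random.default_rng(0)
        _, recs = simulate_read_evidence(ga, gb, sv, true_gt, cfg, rng=rng)
        to_a, to_b = gt.split_by_reference(recs)
        ev = gt.collect_evidence(to_a, to_b, sv)
        if true_gt == B_HOM:
            # segment absent: near-zero depth inside, >=3 junction reads
            assert ev.deleted_region_covered_frac_at_2x < 0.1
            assert max(ev.split_reads_bp1, ev.split_reads_bp2) >= 3
        elif true_gt == A_HOM:
            assert ev.deleted_region_covered_frac_at_2x > 0.9
            assert ev.split_reads_bp1 == 0
        else:
            assert max(ev.split_reads_bp1, ev.split_reads_bp2) >= 3
            assert max(ev.spanning_reads_bp1, ev.spanning_reads_bp2) >= 3

    def test_zero_depth_warns_and_emits_nothing(self, toy_genomes):
        cfg, ga, gb, truth = toy_genomes
        sv = truth.sv_records()[0]
        cfg0 = replace(cfg, read_depth=0.0)
        with pytest.warns(UserWarning, match="depth 0"):
            _, recs = simulate_read_evidence(ga, gb, sv, A_HOM, cfg0)
        assert recs == []

    def test_missing_genotype_emits_nothing(self, toy_genomes):
        cfg, ga, gb, truth = toy_genomes
        sv = truth.sv_records()[0]
        _, recs = simulate_read_evidence(ga, gb, sv, None, cfg)
        assert recs == []


class TestExpression:
    def _matrix(self, seed=12, n_acc=(30, 40, 40, 40)):
        cfg = SimulationConfig(
            seed=seed, n_chromosomes=1, chrom_length=10_000_000,
            n_deletions=100, n_insertions=100, n_inversions=0,
            group_sizes=n_acc, missing_rate=0.0, n_genes=50,
        )
        truth = plan_truth(cfg)
        return cfg, truth, simulate_population_genotypes(truth, cfg)

    def test_planted_cis_effect_shifts_class_means(self):
        cfg, truth, m = self._matrix()
        dose = m.dosage()
        common = dose.index[(dose.mean(axis=1) / 2).between(0.3, 0.7)]
        sv = list(dose.index).index(common[0])
        cfg = replace(cfg, cis_effects=[(0, sv, 2.0)], noise_sd=0.5, n_confounders=0)
        expr = simulate_expression(m, cfg)
        y = expr.values.iloc[0]
        d = dose.iloc[sv]
        means = [y[d == k].mean() for k in (0, 1, 2)]
        assert means[1] - means[0] == pytest.approx(2.0, abs=0.5)
        assert means[2] - means[1] == pytest.approx(2.0, abs=0.5)

    def test_null_gene_uncorrelated_with_genotype(self):
        cfg, truth, m = self._matrix(seed=13)
        cfg = replace(cfg, noise_sd=1.0, n_confounders=0)
        expr = simulate_expression(m, cfg)
        y = expr.values.iloc[5].values
        dose = m.dosage(impute_mean=True).values
        keep = dose.std(axis=1) > 0
        r = np.corrcoef(np.vstack([y, dose[keep]]))[0, 1:]
        assert np.abs(r).max() < 0.35  # ~n=150 null fluctuation

    def test_zero_noise_no_effects_gives_constant_genes(self):
        cfg, truth, m = self._matrix(seed=14)
        cfg = replace(cfg, noise_sd=0.0, cis_effects=[], hotspot=None)
        expr = simulate_expression(m, cfg)
        assert (expr.values.std(axis=1) < 1e-12).all()

    def test_unknown_effect_reference_raises(self):
        cfg, truth, m = self._matrix(seed=15)
        cfg = replace(cfg, cis_effects=[(999, 0, 1.0)])
        with pytest.raises(ValueError, match="unknown gene"):
            simulate_expression(m, cfg)

    def test_cis_genes_are_placed_within_cis_window(self):
        cfg, truth, m = self._matrix(seed=16)
        cfg = plan_eqtl_effects(m, cfg, n_cis=5, hotspot_targets=3)
        expr = simulate_expression(m, cfg, truth)
        eff = truth.eqtl_effects
        for _, e in eff[eff["kind"] == "cis"].iterrows():
            g = expr.genes.loc[e["gene"]]
            p = m.positions.loc[e["sv"]]
            assert g["chrom"] == p["chrom"]
            assert abs(int(g["tss"]) - int(p["pos"])) <= 50_000
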