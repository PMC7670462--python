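"""End-to-end evaluation batteries run against the synthetic truth.

Each function builds a scenario with the generator, runs the relevant
pipeline stage from scratch, and scores the result against the planted
truth.  They back both the acceptance test suite and the standalone
acceptance script, so every reported number is recomputed at call time.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, hypergeom

from . import eqtl as eq
from . import genotyping as gt
from . import popgen as pg
from . import validation as val
from .records import A_HOM, B_HOM, HET, GenotypeMatrix
from .simulate import (
    SimulationConfig,
    plan_eqtl_effects,
    plan_truth,
    simulate_expression,
    simulate_genome_pair,
    simulate_population_genotypes,
    simulate_read_evidence,
)

log = logging.getLogger(__name__)


def _seed(base: int, k: int) -> int:
    return int((base * 1_000_003 + k) % (2**31 - 1))


# ---------------------------------------------------------------------------
# Fisher oracle
# ---------------------------------------------------------------------------


def fisher_two_tailed_oracle(a: int, b: int, c: int, d: int) -> float:
    """Brute-force two-tailed Fisher p: enumerate all tables with the
    observed margins and sum hypergeometric probabilities not exceeding
    the observed table's."""
    r1, r2 = a + b, c + d
    n = r1 + r2
    c1 = a + c
    xs = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    probs = hypergeom.pmf(xs, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def fisher_oracle_check(max_margin: int = 30) -> dict:
    """Compare the scan's Fisher p against the enumeration oracle on every
    2x2 table with both row margins <= ``max_margin``."""
    worst = 0.0
    n_tables = 0
    for r1 in range(1, max_margin + 1):
        for r2 in range(1, max_margin + 1):
            for a in range(r1 + 1):
                for c in range(r2 + 1):
                    b, d = r1 - a, r2 - c
                    _, p = fisher_exact([[a, b], [c, d]])
                    p0 = fisher_two_tailed_oracle(a, b, c, d)
                    worst = max(worst, abs(p - p0))
                    n_tables += 1
    return dict(max_abs_diff=worst, n_tables=n_tables)


# ---------------------------------------------------------------------------
# genotyping recovery
# ---------------------------------------------------------------------------


def genotyping_battery_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        seed=_seed(seed, 1),
        n_chromosomes=1,
        chrom_length=200_000,
        n_deletions=12,
        n_insertions=12,
        n_inversions=2,
        sv_size_range=(100, 2_000),
        snp_rate=0.0,
    )


def genotyping_recovery(seed: int, n_cases: int = 200, depth: float = 15.0) -> dict:
    """Simulate read evidence for SV x accession cases and re-call them.

    Returns the fraction of correct calls at the requested depth and the
    missing-call fraction when depth is zero.
    """
    config = genotyping_battery_config(seed)
    genome_a, genome_b, truth = simulate_genome_pair(config)
    svs = truth.sv_records()
    rng = np.random.default_rng(_seed(seed, 2))
    ref_lengths = {
        f"A_{c}": len(s) for c, s in genome_a.items()
    } | {f"B_{c}": len(s) for c, s in genome_b.items()}

    cfg = replace(config, read_depth=depth)
    correct = 0
    for i in range(n_cases):
        sv = svs[i % len(svs)]
        true_gt = int(rng.integers(0, 3))
        _, recs = simulate_read_evidence(
            genome_a, genome_b, sv, true_gt, cfg, accession=f"acc{i}", rng=rng
        )
        to_a, to_b = gt.split_by_reference(recs)
        ev = gt.collect_evidence(to_a, to_b, sv, accession=f"acc{i}", ref_lengths=ref_lengths)
        call = gt.call_genotype(ev)
        if pd.notna(call) and int(call) == true_gt:
            correct += 1

    # depth -> 0 limit: everything becomes missing
    cfg0 = replace(config, read_depth=0.0)
    n_zero = 0
    missing_zero = 0
    import warnings as _w

    for sv in svs[:10]:
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            _, recs = simulate_read_evidence(genome_a, genome_b, sv, A_HOM, cfg0, rng=rng)
        to_a, to_b = gt.split_by_reference(recs)
        ev = gt.collect_evidence(to_a, to_b, sv)
        n_zero += 1
        missing_zero += int(pd.isna(gt.call_genotype(ev)))

    return dict(
        accuracy=correct / n_cases,
        n_cases=n_cases,
        missing_fraction_at_zero_depth=missing_zero / n_zero,
    )


def genotyping_concordance(seed: int, n_cases: int = 100, depth: float = 20.0) -> float:
    """Concordance between two independent read-evidence replicates of the
    same genotypes (the repeat-genotyping consistency check)."""
    config = genotyping_battery_config(seed)
    genome_a, genome_b, truth = simulate_genome_pair(config)
    svs = truth.sv_records()
    cfg = replace(config, read_depth=depth)
    groups = pd.Series("SP", index=[f"acc{i}" for i in range(10)], name="group")
    rngs = [np.random.default_rng(_seed(seed, 7)), np.random.default_rng(_seed(seed, 8))]
    mats = []
    for rng in rngs:
        evidence = []
        case = 0
        gt_rng = np.random.default_rng(_seed(seed, 9))
        for acc in groups.index:
            for sv in svs:
                true_gt = int(gt_rng.integers(0, 3))
                if case >= n_cases:
                    break
                case += 1
                _, recs = simulate_read_evidence(
                    genome_a, genome_b, sv, true_gt, cfg, accession=acc, rng=rng
                )
                to_a, to_b = gt.split_by_reference(recs)
                evidence.append(gt.collect_evidence(to_a, to_b, sv, accession=acc))
        m, _ = gt.build_genotype_matrix(evidence, groups, min_genotyped=0.0)
        mats.append(m)
    return gt.concordance(mats[0], mats[1])


# ---------------------------------------------------------------------------
# SV validation pipeline recovery
# ---------------------------------------------------------------------------


def simulate_caller_records(truth, rng, jitter: int = 5, n_false: int = 10, chrom_len: int = 0):
    """Candidate call sets derived from truth: a genome-comparison set with
    small breakpoint jitter plus decoy calls, and a read-mapping set."""
    from .records import SVRecord

    genome_cmp, read_map = [], []
    for k, sv in enumerate(truth.sv_records()):
        j = int(rng.integers(-jitter, jitter + 1))
        lo = max(0, sv.start_a + (0 if sv.sv_type == "insertion" else j))
        genome_cmp.append(
            replace(
                sv,
                id=f"cmp{k}",
                start_a=lo,
                end_a=lo + sv.len_a,
                sources=frozenset({"genome_alignment"}),
            )
        )
        read_map.append(
            replace(
                sv,
                id=f"map{k}",
                sources=frozenset({"read_mapping_caller1", "read_mapping_caller2"}),
            )
        )
    for k in range(n_false):
        s = int(rng.integers(10_000, chrom_len - 20_000))
        size = int(rng.integers(50, 500))
        genome_cmp.append(
            SVRecord(
                id=f"false{k}",
                sv_type="deletion",
                chrom_a=truth.svs["chrom_a"].iloc[0],
                start_a=s,
                end_a=s + size,
                chrom_b=truth.svs["chrom_a"].iloc[0],
                start_b=s,
                end_b=s,
                size=size,
                sources=frozenset({"genome_alignment"}),
            )
        )
    return genome_cmp, read_map


def validation_recovery(seed: int) -> dict:
    """Run the full validation pipeline on simulated caller records and
    score recovery of planted SVs and leakage of decoys."""
    from .records import GapTrack

    config = SimulationConfig(
        seed=_seed(seed, 3),
        n_chromosomes=1,
        chrom_length=300_000,
        n_deletions=15,
        n_insertions=15,
        n_inversions=2,
        sv_size_range=(50, 2_000),
        snp_rate=1e-4,
    )
    genome_a, genome_b, truth = simulate_genome_pair(config)
    rng = np.random.default_rng(_seed(seed, 4))
    genome_cmp, read_map = simulate_caller_records(
        truth, rng, chrom_len=config.chrom_length
    )

    flank_hits = {
        sv.id: val.anchor_flanks_exact(sv, genome_a, genome_b, flank_len=500)
        for sv in genome_cmp
        if sv.sv_type in ("deletion", "insertion")
    }
    inv_ev = {
        sv.id: [(20, 20), (20, 20)] for sv in genome_cmp if sv.sv_type == "inversion"
    }
    merged = val.build_reference_sv_set(
        genome_cmp,
        read_map,
        GapTrack(),
        GapTrack(),
        flank_hits=flank_hits,
        inversion_evidence=inv_ev,
    )
    # count validated records matching a planted SV (same type, near-same span)
    planted = truth.sv_records()
    hit = set()
    false_records = 0
    for m in merged:
        matched = False
        for i, t in enumerate(planted):
            if (
                m.sv_type == t.sv_type
                and m.chrom_a == t.chrom_a
                and abs(m.start_a - t.start_a) <= 10
                and abs(m.size - t.size) <= max(10, 0.1 * t.size)
            ):
                hit.add(i)
                matched = True
                break
        if not matched:
            false_records += 1
    return dict(
        recall=len(hit) / len(planted),
        false_records=false_records,
        n_output=len(merged),
    )


# ---------------------------------------------------------------------------
# selection scan power / size
# ---------------------------------------------------------------------------


def selection_scenario(seed: int, n_null: int = 980, n_sweeps: int = 20) -> tuple:
    config = SimulationConfig(
        seed=_seed(seed, 5),
        n_chromosomes=2,
        chrom_length=10_000_000,
        n_deletions=(n_null + n_sweeps) // 2,
        n_insertions=(n_null + n_sweeps) - (n_null + n_sweeps) // 2 - 10,
        n_inversions=10,
        group_sizes=(100, 100, 100, 100),
        stage_scale=(1.0, 1.0, 1.0, 1.0),
        wild_freq_range=(0.2, 0.8),
        drift_sd=0.01,
        missing_rate=0.05,
        selected_loci=[],
    )
    truth = plan_truth(config)
    n = len(truth.svs)
    rng = np.random.default_rng(_seed(seed, 6))
    sweep_idx = sorted(rng.choice(n, size=n_sweeps, replace=False))
    config = replace(
        config,
        selected_loci=[(int(i), (0.6, 0.05, 0.05, 0.05)) for i in sweep_idx],
    )
    matrix = simulate_population_genotypes(truth, config)
    return matrix, truth, sweep_idx


def selection_power_and_size(seed: int) -> dict:
    """Power on planted SP->SLC sweeps and false-positive rate on null loci."""
    matrix, truth, sweep_idx = selection_scenario(seed)
    freqs = pg.group_allele_frequencies(matrix)
    res = pg.fisher_selection_scan(freqs, ("SP", "SLC"))
    sweep_ids = set(truth.svs["id"].iloc[sweep_idx])
    is_sweep = res.index.isin(sweep_ids)
    power = float(res.loc[is_sweep, "selected"].mean())
    fpr = float(res.loc[~is_sweep, "selected"].mean())
    return dict(power=power, false_positive_rate=fpr, n_tested=len(res))


# ---------------------------------------------------------------------------
# introgression recovery
# ---------------------------------------------------------------------------


def introgression_scenario(seed: int) -> tuple[GenotypeMatrix, "pd.DataFrame"]:
    config = SimulationConfig(
        seed=_seed(seed, 10),
        n_chromosomes=2,
        chrom_length=10_000_000,
        n_deletions=300,
        n_insertions=290,
        n_inversions=10,
        group_sizes=(51, 100, 120, 52),
        ld_length=300_000.0,
        missing_rate=0.05,
        introgression_blocks=[
            ("modern", 0.10, "chr1", (2_000_000, 4_000_000)),
            ("modern", 0.12, "chr2", (5_000_000, 7_500_000)),
            ("heirloom", 0.05, "chr1", (6_000_000, 8_000_000)),
        ],
    )
    truth = plan_truth(config)
    matrix = simulate_population_genotypes(truth, config)
    return matrix, truth.introgressions


def introgression_recovery(seed: int) -> dict:
    """Window-level recall and precision of planted donor blocks."""
    matrix, blocks = introgression_scenario(seed)
    segs = pg.introgression_scan(matrix)

    # truth windows: sliding windows fully inside a planted block
    truth_windows = set()
    for _, b in blocks.iterrows():
        w0 = 0
        while w0 + pg.WINDOW_SIZE <= 10_000_000:
            if w0 >= b["start"] and w0 + pg.WINDOW_SIZE <= b["end"]:
                truth_windows.add((b["accession"], b["chrom"], w0))
            w0 += pg.WINDOW_STEP
    pred = set(zip(segs["accession"], segs["chrom"], segs["start"]))
    hits = truth_windows & pred
    recall = len(hits) / len(truth_windows) if truth_windows else float("nan")

    by_acc = {
        (b["accession"], b["chrom"]): (b["start"], b["end"]) for _, b in blocks.iterrows()
    }
    ok = 0
    for acc, chrom, w0 in pred:
        span = by_acc.get((acc, chrom))
        if span and w0 < span[1] and w0 + pg.WINDOW_SIZE > span[0]:
            ok += 1
    precision = ok / len(pred) if pred else float("nan")
    return dict(recall=recall, precision=precision, n_predicted=len(pred))


# ---------------------------------------------------------------------------
# eQTL scenario and recovery
# ---------------------------------------------------------------------------


def eqtl_scenario(seed: int, n_cis: int = 20, hotspot_targets: int = 8):
    """The default desk-scale eQTL study: 150 accessions, 2,000 SVs,
    300 genes, 20 planted cis effects and one regulator-driven hotspot."""
    config = SimulationConfig(
        seed=_seed(seed, 20),
        n_chromosomes=2,
        chrom_length=20_000_000,
        n_deletions=1_800,
        n_insertions=1_770,
        n_inversions=30,
        group_sizes=(20, 60, 50, 20),
        missing_rate=0.05,
        n_genes=300,
        noise_sd=1.0,
    )
    truth = plan_truth(config)
    matrix = simulate_population_genotypes(truth, config)
    config = plan_eqtl_effects(
        matrix, config, n_cis=n_cis, hotspot_targets=hotspot_targets
    )
    expr = simulate_expression(matrix, config, truth)
    return matrix, expr, truth, config


def run_eqtl_pipeline(matrix: GenotypeMatrix, expr, alpha: float = 0.05):
    """Normalization -> factors -> imputation -> kinship -> scan -> blocks."""
    values = eq.quantile_normal_transform(expr.values)
    norm_expr = eq.ExpressionMatrix(values=values, genes=expr.genes, stage="qq_normalized")
    factors = eq.derive_hidden_factors(norm_expr, k=20)

    # covariate-adjusted expression: hidden factors projected out; used
    # wherever gene-gene correlations matter (master-regulator ranking),
    # so confounder-borne correlation does not masquerade as regulation
    F = factors.values - factors.values.mean(axis=0)
    Q, _ = np.linalg.qr(F)
    V = values.values - values.values.mean(axis=1, keepdims=True)
    resid = V - (V @ Q) @ Q.T
    resid_expr = eq.ExpressionMatrix(
        values=pd.DataFrame(resid, index=values.index, columns=values.columns),
        genes=expr.genes,
        stage="qq_normalized",
    )

    dosages = matrix.dosage()
    imputed = eq.knn_impute(dosages)
    kinship = eq.compute_kinship(imputed)
    results = eq.eqtl_scan(norm_expr, imputed, factors, kinship)

    m = results["sv"].nunique()
    thr, _ = eq.bonferroni_threshold(alpha, m)
    suggestive, _ = eq.bonferroni_threshold(1.0, m)
    r2_bg, dist_bg = eq.ld_background(imputed, matrix.positions)
    blocks = eq.build_eqtl_blocks(
        results, matrix.positions, norm_expr.genes, imputed, r2_bg, dist_bg, thr,
        member_threshold=suggestive,
    )
    return dict(
        results=results,
        blocks=blocks,
        threshold=thr,
        m=m,
        r2_bg=r2_bg,
        dist_bg=dist_bg,
        expr=norm_expr,
        expr_resid=resid_expr,
        dosages=imputed,
    )


def cis_recovery(seed: int) -> dict:
    """Fraction of planted cis effects recovered as cis blocks containing
    the causal SV, plus hotspot detection with regulator ranking."""
    matrix, expr, truth, config = eqtl_scenario(seed)
    out = run_eqtl_pipeline(matrix, expr)
    blocks = out["blocks"]

    effects = truth.eqtl_effects
    cis_truth = effects[effects["kind"] == "cis"]
    reg_gene = config.hotspot[0]
    reg_gene_id = f"gene{reg_gene + 1:04d}"
    cis_truth = cis_truth[cis_truth["gene"] != reg_gene_id]

    recovered = 0
    for _, e in cis_truth.iterrows():
        sub = blocks[(blocks["gene"] == e["gene"]) & blocks["cis"]]
        if any(e["sv"] in b for b in sub["svs"]):
            recovered += 1

    hot = hotspot_outcome(out, expr, truth, config, matrix)
    return dict(
        cis_recovery=recovered / len(cis_truth),
        n_cis=len(cis_truth),
        n_blocks=len(blocks),
        **hot,
    )


def hotspot_outcome(out, expr, truth, config, matrix) -> dict:
    """Detect hotspots on the trans blocks and rank regulator candidates."""
    blocks = out["blocks"]
    trans = blocks[~blocks["cis"]]
    spans = {
        c: (0, int(matrix.positions.loc[matrix.positions["chrom"] == c, "pos"].max()))
        for c in matrix.positions["chrom"].unique()
    }
    hotspots = eq.detect_hotspots(trans, genome_span=spans)

    reg_gene, targets, _ = config.hotspot
    reg_gene_id = f"gene{reg_gene + 1:04d}"
    target_ids = {f"gene{t + 1:04d}" for t in targets}
    reg = expr.genes.loc[reg_gene_id]

    detected = False
    top_is_regulator = False
    for _, h in hotspots.iterrows():
        in_window = h["chrom"] == reg["chrom"] and (
            h["start"] - eq.CIS_WINDOW <= reg["tss"] <= h["end"] + eq.CIS_WINDOW
        )
        overlap = len(set(h["targets"]) & target_ids)
        if in_window and overlap >= max(2, len(target_ids) // 3):
            detected = True
            genes_near = [
                g
                for g, r in expr.genes.iterrows()
                if r["chrom"] == h["chrom"]
                and h["start"] - eq.CIS_WINDOW <= r["tss"] <= h["end"] + eq.CIS_WINDOW
            ]
            ranking = eq.rank_master_regulator(
                list(h["targets"]), out["expr_resid"], genes_near
            )
            top_is_regulator = ranking.iloc[0]["candidate"] == reg_gene_id
            break
    return dict(
        hotspot_detected=detected,
        regulator_top_ranked=bool(detected and top_is_regulator),
        n_hotspots=len(hotspots),
    )


def hotspot_battery(seed: int, n_seeds: int = 20) -> dict:
    """Repeat the full eQTL stage over seeds; fraction of runs where the
    planted hotspot is found with its regulator ranked first."""
    ok = 0
    detected = 0
    for k in range(n_seeds):
        matrix, expr, truth, config = eqtl_scenario(_seed(seed, 100 + k))
        out = run_eqtl_pipeline(matrix, expr)
        hot = hotspot_outcome(out, expr, truth, config, matrix)
        detected += int(hot["hotspot_detected"])
        ok += int(hot["regulator_top_ranked"])
    return dict(
        top_ranked_fraction=ok / n_seeds,
        detected_fraction=detected / n_seeds,
        n_seeds=n_seeds,
    )


# ---------------------------------------------------------------------------
# mixed-model sanity
# ---------------------------------------------------------------------------


def mixed_model_sanity(seed: int) -> dict:
    """Identity-kinship limit vs ordinary regression, and null type-I rate."""
    import statsmodels.api as sm

    rng = np.random.default_rng(_seed(seed, 30))
    n, m = 80, 50
    acc = [f"a{i}" for i in range(n)]
    G = pd.DataFrame(
        rng.binomial(2, 0.4, size=(m, n)).astype(float),
        index=[f"sv{i}" for i in range(m)],
        columns=acc,
    )
    y = pd.Series(rng.normal(size=n), index=acc)
    K = pd.DataFrame(np.eye(n), index=acc, columns=acc)
    res = eq.association_scan(y, G, None, K)

    max_rel = 0.0
    for _, r in res.iterrows():
        x = sm.add_constant(G.loc[r["sv"]].values)
        fit = sm.OLS(y.values, x).fit()
        p_ols = fit.pvalues[1]
        rel = abs(r["p"] - p_ols) / p_ols
        max_rel = max(max_rel, rel)

    # null type-I under population structure with the real kinship
    config = SimulationConfig(
        seed=_seed(seed, 31),
        n_chromosomes=2,
        chrom_length=20_000_000,
        n_deletions=500,
        n_insertions=490,
        n_inversions=10,
        group_sizes=(20, 60, 50, 20),
        missing_rate=0.0,
    )
    truth = plan_truth(config)
    matrix = simulate_population_genotypes(truth, config)
    D = eq.filter_sv_dosages(matrix.dosage())
    kin = eq.compute_kinship(D)
    rng2 = np.random.default_rng(_seed(seed, 32))
    ps = []
    for g in range(10):
        ynull = pd.Series(rng2.normal(size=D.shape[1]), index=D.columns)
        r = eq.association_scan(ynull, D, None, kin, prefiltered=True)
        ps.append(r["p"].values)
    ps = np.concatenate(ps)
    return dict(
        max_rel_p_diff_vs_ols=max_rel,
        null_type1_rate=float((ps < 0.05).mean()),
        n_null_tests=len(ps),
    )
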