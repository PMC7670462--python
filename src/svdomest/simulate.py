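"""Synthetic data generator: toy genome pair, population genotypes, read
evidence and expression, all with a machine-readable truth set.

The generator emulates the statistical structure of a wild-vs-cultivated
tomato SV study: two assemblies differing by planted indels/inversions/SNPs,
a four-stage population (wild progenitor SP -> early domesticate SLC ->
heirloom -> modern) whose A-allele (wild) frequencies decline through
domestication, introgressed wild blocks in cultivated accessions, and fruit
expression with planted cis effects plus one trans hotspot driven by a
master-regulator gene.

Every operation is deterministic given ``SimulationConfig.seed``: each stage
draws from ``numpy.random.default_rng([seed, stage_tag])`` so stages can be
re-run independently without perturbing one another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.stats import norm

from .records import (
    A_HOM,
    B_HOM,
    GT_CODES,
    GT_LABELS,
    HET,
    STAGE_GROUPS,
    EvidenceSummary,
    GenotypeMatrix,
    SVRecord,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: minimum aligned bases on each side of a junction for a split alignment
MIN_ANCHOR = 20

# rng stream tags, one per stage
_S_GENOME, _S_FREQ, _S_HAPLO, _S_READS, _S_EXPR = 11, 23, 37, 53, 71


@dataclass
class SimulationConfig:
    """All knobs of the generator.

    Population defaults mirror the study design the pipeline targets: group
    sizes (51, 228, 226, 52) for SP/SLC/heirloom/modern, and per-stage
    scaling of the wild-allele frequency chosen so that mean A-allele
    frequencies fall from ~0.58 in SP to ~0.16 / 0.05 / 0.06 in
    SLC / heirloom / modern.  ``stage_scale = (1, 1, 1, 1)`` gives a neutral
    (drift-only) population for null calibrations.
    """

    seed: int = 0
    # genome pair
    n_chromosomes: int = 2
    chrom_length: int = 500_000
    n_deletions: int = 20
    n_insertions: int = 20
    n_inversions: int = 2
    sv_size_range: tuple[int, int] = (50, 2_000)
    snp_rate: float = 2e-3
    # population
    group_sizes: tuple[int, int, int, int] = (51, 228, 226, 52)
    stage_scale: tuple[float, float, float, float] = (1.0, 0.27, 0.08, 0.11)
    wild_freq_range: tuple[float, float] = (0.2, 0.95)
    drift_sd: float = 0.03
    inbreeding: float = 0.8
    ld_length: float = 1_500_000.0
    missing_rate: float = 0.05
    selected_loci: list = field(default_factory=list)  # (sv_index, per-group freqs)
    introgression_blocks: list = field(default_factory=list)  # (group, frac, chrom, (s, e))
    # read evidence
    read_depth: float = 20.0
    read_length: int = 150
    # expression
    n_genes: int = 100
    cis_effects: list = field(default_factory=list)  # (gene index, sv index, beta)
    hotspot: Optional[tuple] = None  # (regulator gene idx, [target gene idx], beta)
    regulator_beta: float = 2.0
    noise_sd: float = 1.0
    expression_baseline_sd: float = 0.5
    # hidden global expression confounders (batch / physiology); these are
    # what the hidden-factor covariates in the eQTL stage are meant to
    # absorb.  Loadings shrink geometrically so the factor spectrum decays
    # smoothly as in real expression panels.  Disabled when noise_sd is 0.
    n_confounders: int = 30
    confounder_sd: float = 0.8
    confounder_decay: float = 0.95

    def __post_init__(self) -> None:
        counts = (
            self.n_chromosomes,
            self.chrom_length,
            self.n_deletions,
            self.n_insertions,
            self.n_inversions,
            self.n_genes,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.sv_size_range[0] < 10:
            raise ValueError("sv_size_range minimum must be >= 10 bp")
        if self.sv_size_range[0] > self.sv_size_range[1]:
            raise ValueError("sv_size_range must be (min, max)")
        for f, (sv, freqs) in enumerate(self.selected_loci):
            if any(not 0.0 <= p <= 1.0 for p in freqs):
                raise ValueError(f"selected locus {f}: frequencies outside [0, 1]")

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, tag])


@dataclass
class TruthSet:
    """Planted ground truth emitted alongside each simulated dataset."""

    svs: pd.DataFrame  # id, sv_type, chrom_a, start_a, end_a, chrom_b, start_b, end_b, size
    snps: pd.DataFrame  # chrom, pos_a, pos_b, ref, alt
    genotypes: Optional[pd.DataFrame] = None  # SV x accession dosage codes
    groups: Optional[pd.Series] = None
    selected_loci: list = field(default_factory=list)
    introgressions: Optional[pd.DataFrame] = None  # accession, group, chrom, start, end, donor
    eqtl_effects: Optional[pd.DataFrame] = None  # gene, sv, beta, kind

    def sv_records(self) -> list[SVRecord]:
        recs = []
        for _, r in self.svs.iterrows():
            recs.append(
                SVRecord(
                    id=r["id"],
                    sv_type=r["sv_type"],
                    chrom_a=r["chrom_a"],
                    start_a=int(r["start_a"]),
                    end_a=int(r["end_a"]),
                    chrom_b=r["chrom_b"],
                    start_b=int(r["start_b"]),
                    end_b=int(r["end_b"]),
                    size=int(r["size"]),
                )
            )
        return recs


# ---------------------------------------------------------------------------
# genome pair
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _revcomp(arr: np.ndarray) -> np.ndarray:
    comp = {b"A": b"T", b"T": b"A", b"C": b"G", b"G": b"C"}
    out = np.array([comp[bytes(x)] for x in arr[::-1]], dtype="S1")
    return out


def _plan_svs(config: SimulationConfig) -> pd.DataFrame:
    """Lay out non-overlapping SV intervals on genome A.

    Raises if a chromosome cannot host its share of the plan.
    """
    rng = config.rng(_S_GENOME)
    lo, hi = config.sv_size_range
    margin = 2 * MIN_ANCHOR + 200  # keep flanks of neighbouring SVs separable
    end_pad = 5_000 if config.chrom_length > 20_000 else 500

    types = (
        ["deletion"] * config.n_deletions
        + ["insertion"] * config.n_insertions
        + ["inversion"] * config.n_inversions
    )
    if not types:
        return pd.DataFrame(
            columns=[
                "id", "sv_type", "chrom_a", "start_a", "end_a",
                "chrom_b", "start_b", "end_b", "size",
            ]
        )
    types = list(rng.permutation(types))
    sizes = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=len(types))
    ).astype(np.int64)
    sizes = np.clip(sizes, lo, hi)

    chrom_of = rng.integers(0, config.n_chromosomes, size=len(types))
    rows = []
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        idx = np.where(chrom_of == c)[0]
        if len(idx) == 0:
            continue
        # footprint on A: deletions/inversions occupy their size, insertions a point
        footprints = np.array(
            [0 if types[i] == "insertion" else sizes[i] for i in idx]
        )
        usable = config.chrom_length - 2 * end_pad
        needed = footprints.sum() + margin * len(idx)
        if needed > usable:
            raise ValueError(
                f"SV plan exceeds capacity of {chrom}: needs {needed} bp, "
                f"has {usable} bp"
            )
        free = usable - footprints.sum() - margin * len(idx)
        cuts = np.sort(rng.uniform(0, free, size=len(idx)))
        gaps = np.diff(np.concatenate([[0.0], cuts])).astype(np.int64)
        pos = end_pad
        order = idx[np.argsort(rng.random(len(idx)))]
        for g, i in zip(gaps, order):
            pos += int(g) + margin // 2
            start = pos
            end = start + int(footprints[np.where(idx == i)[0][0]])
            rows.append(
                dict(
                    sv_type=types[i],
                    chrom_a=chrom,
                    start_a=start,
                    end_a=end,
                    size=int(sizes[i]),
                )
            )
            pos = end + margin // 2
    df = pd.DataFrame(rows).sort_values(["chrom_a", "start_a"]).reset_index(drop=True)
    df["id"] = [f"SV{i + 1:05d}" for i in range(len(df))]
    return df


def plan_truth(config: SimulationConfig) -> TruthSet:
    """SV layout only (no sequences): a TruthSet for population-scale runs
    where the base-level genomes are never touched."""
    plan = _plan_svs(config)
    return TruthSet(svs=plan, snps=pd.DataFrame(columns=["chrom", "pos_a", "ref", "alt"]))


def simulate_genome_pair(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str], TruthSet]:
    """Build genome A, derive genome B by applying planted SVs and SNPs.

    Returns the two genomes as chrom -> sequence dicts and a TruthSet whose
    SV table carries breakpoints on both coordinate systems.
    """
    rng = config.rng(_S_GENOME + 1)
    plan = _plan_svs(config)

    genome_a: dict[str, str] = {}
    genome_b: dict[str, str] = {}
    snp_rows = []
    b_coords = {"start_b": {}, "end_b": {}}

    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        a = _random_sequence(rng, config.chrom_length)
        sub = plan[plan["chrom_a"] == chrom]

        # SNP substitutions outside SV intervals
        in_sv = np.zeros(config.chrom_length, dtype=bool)
        for _, r in sub.iterrows():
            lo = max(0, r["start_a"] - MIN_ANCHOR)
            hi = min(config.chrom_length, r["end_a"] + MIN_ANCHOR)
            in_sv[lo:hi] = True
        snp_mask = (rng.random(config.chrom_length) < config.snp_rate) & ~in_sv
        b_template = a.copy()
        for p in np.where(snp_mask)[0]:
            ref = bytes(a[p]).decode()
            alt = rng.choice([x for x in "ACGT" if x != ref])
            b_template[p] = alt.encode()
            snp_rows.append(dict(chrom=chrom, pos_a=int(p), ref=ref, alt=alt))

        # apply SVs left to right, tracking the B-coordinate offset
        parts: list[np.ndarray] = []
        cursor = 0
        offset = 0
        for i, r in sub.iterrows():
            s, e = int(r["start_a"]), int(r["end_a"])
            parts.append(b_template[cursor:s])
            if r["sv_type"] == "deletion":
                b_coords["start_b"][i] = s + offset
                b_coords["end_b"][i] = s + offset
                offset -= e - s
            elif r["sv_type"] == "insertion":
                ins = _random_sequence(rng, int(r["size"]))
                parts.append(ins)
                b_coords["start_b"][i] = s + offset
                b_coords["end_b"][i] = s + offset + int(r["size"])
                offset += int(r["size"])
            else:  # inversion
                parts.append(_revcomp(b_template[s:e]))
                b_coords["start_b"][i] = s + offset
                b_coords["end_b"][i] = e + offset
            cursor = e
        parts.append(b_template[cursor:])
        genome_a[chrom] = a.tobytes().decode()
        genome_b[chrom] = np.concatenate(parts).tobytes().decode() if parts else ""

    plan = plan.copy()
    plan["chrom_b"] = plan["chrom_a"]
    plan["start_b"] = pd.Series(b_coords["start_b"], dtype="int64").reindex(plan.index)
    plan["end_b"] = pd.Series(b_coords["end_b"], dtype="int64").reindex(plan.index)
    if len(plan):
        plan[["start_b", "end_b"]] = plan[["start_b", "end_b"]].astype(np.int64)

    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos_a", "ref", "alt"])
    if len(snps):
        # B coordinate of each SNP: shift by cumulative indel offset
        pos_b = []
        for _, s in snps.iterrows():
            sub = plan[
                (plan["chrom_a"] == s["chrom"]) & (plan["end_a"] <= s["pos_a"])
            ]
            off = int(
                (sub["end_b"] - sub["start_b"]).sum() - (sub["end_a"] - sub["start_a"]).sum()
            )
            pos_b.append(s["pos_a"] + off)
        snps["pos_b"] = pos_b

    cols = [
        "id", "sv_type", "chrom_a", "start_a", "end_a",
        "chrom_b", "start_b", "end_b", "size",
    ]
    truth = TruthSet(svs=plan[cols] if len(plan) else plan, snps=snps)
    return genome_a, genome_b, truth


# ---------------------------------------------------------------------------
# population genotypes
# ---------------------------------------------------------------------------


def accession_names(group_sizes: Sequence[int]) -> tuple[list[str], pd.Series]:
    names, labels = [], []
    for grp, n in zip(STAGE_GROUPS, group_sizes):
        for i in range(n):
            names.append(f"{grp}{i + 1:03d}")
            labels.append(grp)
    return names, pd.Series(labels, index=names, name="group")


def group_frequency_trajectories(
    truth: TruthSet, config: SimulationConfig
) -> np.ndarray:
    """Per-locus A-allele frequency for each stage group (4 x n_svs).

    Base wild frequencies are uniform on ``wild_freq_range``; each later
    stage multiplies by the relative ``stage_scale`` and adds Gaussian drift.
    Selected loci are forced to their configured targets.
    """
    rng = config.rng(_S_FREQ)
    svs = truth.svs
    n = len(svs)
    lo, hi = config.wild_freq_range

    # base wild frequencies are spatially autocorrelated along each
    # chromosome (nearby variants share genealogy, hence similar
    # frequencies); marginally uniform on wild_freq_range
    u = np.empty(n)
    for chrom in svs["chrom_a"].unique():
        loci = np.where((svs["chrom_a"] == chrom).values)[0]
        pos = ((svs["start_a"].values[loci] + svs["end_a"].values[loci]) // 2).astype(float)
        order = np.argsort(pos)
        loci, pos = loci[order], pos[order]
        rho = np.exp(-np.diff(pos) / config.ld_length)
        z = rng.normal(size=len(loci))
        for j in range(1, len(loci)):
            z[j] = rho[j - 1] * z[j - 1] + np.sqrt(1 - rho[j - 1] ** 2) * z[j]
        u[loci] = norm.cdf(z)
    f = np.empty((4, n))
    f[0] = lo + (hi - lo) * u
    for g in range(1, 4):
        rel = config.stage_scale[g] / config.stage_scale[g - 1]
        f[g] = np.clip(f[g - 1] * rel + rng.normal(0, config.drift_sd, size=n), 0.0, 1.0)
    for sv_idx, freqs in config.selected_loci:
        f[:, sv_idx] = np.asarray(freqs, dtype=float)
    return f


def simulate_population_genotypes(
    truth: TruthSet, config: SimulationConfig
) -> GenotypeMatrix:
    """Sample SV genotypes for the four-stage population.

    Haplotypes are drawn through a Gaussian-copula AR(1) process along each
    chromosome so that nearby loci are in linkage disequilibrium (decay
    length ``ld_length``) while every locus keeps its configured marginal
    frequency.  ``inbreeding`` is the probability that an accession's two
    haplotypes are identical copies (partial selfing).  Introgression blocks
    replace the genotypes of chosen cultivated accessions with those of a
    random wild (SP) accession over the configured interval.
    """
    if len(truth.svs) == 0:
        raise ValueError("truth set contains no SVs")
    for grp, n, scale in zip(STAGE_GROUPS, config.group_sizes, config.stage_scale):
        if n == 0 and scale != 0:
            raise ValueError(f"group {grp} has size 0 but a nonzero trajectory")

    freqs = group_frequency_trajectories(truth, config)
    rng = config.rng(_S_HAPLO)
    names, groups = accession_names(config.group_sizes)
    n_acc = len(names)
    group_idx = np.repeat(np.arange(4), config.group_sizes)

    svs = truth.svs
    n_svs = len(svs)
    dosage = np.zeros((n_svs, n_acc), dtype=np.int8)

    inbred = rng.random(n_acc) < config.inbreeding

    for chrom in svs["chrom_a"].unique():
        loci = np.where((svs["chrom_a"] == chrom).values)[0]
        pos = ((svs["start_a"].values[loci] + svs["end_a"].values[loci]) // 2).astype(float)
        order = np.argsort(pos)
        loci, pos = loci[order], pos[order]
        rho = np.exp(-np.diff(pos) / config.ld_length)

        # latent AR(1) per haplotype; thresholds give exact marginals
        thr = norm.ppf(np.clip(freqs[:, loci], 1e-12, 1 - 1e-12))  # 4 x L
        z = rng.normal(size=(2, n_acc, len(loci)))
        for j in range(1, len(loci)):
            z[:, :, j] = rho[j - 1] * z[:, :, j - 1] + np.sqrt(1 - rho[j - 1] ** 2) * z[:, :, j]
        t = thr[group_idx, :]  # n_acc x L
        fmat = freqs[:, loci][group_idx, :]
        hap1 = (z[0] < t).astype(np.int8)
        hap2 = (z[1] < t).astype(np.int8)
        hap2[inbred] = hap1[inbred]
        # fixation targets are deterministic, not merely near-certain
        for h in (hap1, hap2):
            h[fmat >= 1.0] = 1
            h[fmat <= 0.0] = 0
        dosage[loci[:, None], np.arange(n_acc)[None, :]] = (hap1 + hap2).T

    calls = pd.DataFrame(dosage, index=svs["id"].values, columns=names).astype("Int8")

    # introgression blocks: copy SP genotypes into chosen focal accessions
    intro_rows = []
    sp_names = [a for a in names if groups[a] == "SP"]
    for grp, frac, chrom, (istart, iend) in config.introgression_blocks:
        grp_names = [a for a in names if groups[a] == grp]
        k = max(1, int(round(frac * len(grp_names))))
        chosen = list(rng.choice(grp_names, size=k, replace=False))
        mid = (svs["start_a"].values + svs["end_a"].values) // 2
        in_block = (svs["chrom_a"].values == chrom) & (mid >= istart) & (mid < iend)
        block_ids = svs["id"].values[in_block]
        # donor lineage: the SP accession richest in wild alleles over the
        # block -- introgressions retained through breeding carry the wild
        # haplotype, which is what made them worth introgressing
        donor_scores = calls.loc[block_ids, sp_names].astype("float64").sum()
        ranked = list(donor_scores.sort_values(ascending=False).index)
        for acc in chosen:
            donor = ranked[int(rng.integers(0, max(1, min(3, len(ranked)))))]
            calls.loc[block_ids, acc] = calls.loc[block_ids, donor]
            intro_rows.append(
                dict(accession=acc, group=grp, chrom=chrom, start=istart, end=iend, donor=donor)
            )

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls = calls.mask(pd.DataFrame(mask, index=calls.index, columns=calls.columns))

    positions = pd.DataFrame(
        {
            "chrom": svs["chrom_a"].values,
            "pos": ((svs["start_a"].values + svs["end_a"].values) // 2),
        },
        index=svs["id"].values,
    )
    truth.genotypes = calls
    truth.groups = groups
    truth.selected_loci = list(config.selected_loci)
    truth.introgressions = pd.DataFrame(
        intro_rows, columns=["accession", "group", "chrom", "start", "end", "donor"]
    )
    return GenotypeMatrix(calls, groups, positions)


# ---------------------------------------------------------------------------
# read evidence
# ---------------------------------------------------------------------------


def reference_name(genome: str, chrom: str) -> str:
    """SAM reference name for a chromosome of genome 'A' or 'B'."""
    return f"{genome}_{chrom}"


def make_sam_header(genome_a: dict[str, str], genome_b: dict[str, str]) -> pysam.AlignmentHeader:
    names, lengths = [], []
    for chrom, seq in genome_a.items():
        names.append(reference_name("A", chrom))
        lengths.append(len(seq))
    for chrom, seq in genome_b.items():
        names.append(reference_name("B", chrom))
        lengths.append(len(seq))
    return pysam.AlignmentHeader.from_references(names, lengths)


@dataclass
class _Block:
    hs: int
    he: int
    ref: str  # "A" or "B"
    chrom: str
    rs: int
    strand: str


def _allele_blocks(sv, genome_a, genome_b, allele: str, flank: int):
    """Haplotype sequence and block maps for one allele of one SV.

    Returns (sequence ndarray of single chars, [blocks]) where blocks map
    haplotype intervals onto reference coordinates of both genomes.
    """
    c = sv.chrom_a
    A = np.frombuffer(genome_a[c].encode(), dtype="S1")
    B = np.frombuffer(genome_b[sv.chrom_b].encode(), dtype="S1")

    if sv.sv_type == "deletion":
        s, e = sv.start_a, sv.end_a
        j = sv.start_b
        w0, w1 = max(0, s - flank), min(len(A), e + flank)
        if allele == "A":
            seq = A[w0:w1]
            blocks = [
                _Block(0, w1 - w0, "A", c, w0, "+"),
                _Block(0, s - w0, "B", c, j - (s - w0), "+"),
                _Block(e - w0, w1 - w0, "B", c, j, "+"),
            ]
        else:
            seq = np.concatenate([A[w0:s], A[e:w1]])
            blocks = [
                _Block(0, s - w0, "A", c, w0, "+"),
                _Block(s - w0, len(seq), "A", c, e, "+"),
                _Block(0, len(seq), "B", c, j - (s - w0), "+"),
            ]
    elif sv.sv_type == "insertion":
        p = sv.start_a
        bs, be = sv.start_b, sv.end_b
        v0, v1 = max(0, bs - flank), min(len(B), be + flank)
        if allele == "B":
            seq = B[v0:v1]
            blocks = [
                _Block(0, v1 - v0, "B", c, v0, "+"),
                _Block(0, bs - v0, "A", c, p - (bs - v0), "+"),
                _Block(be - v0, v1 - v0, "A", c, p, "+"),
            ]
        else:
            seq = np.concatenate([B[v0:bs], B[be:v1]])
            blocks = [
                _Block(0, bs - v0, "B", c, v0, "+"),
                _Block(bs - v0, len(seq), "B", c, be, "+"),
                _Block(0, len(seq), "A", c, p - (bs - v0), "+"),
            ]
    elif sv.sv_type == "inversion":
        s, e = sv.start_a, sv.end_a
        bs, be = sv.start_b, sv.end_b
        w0, w1 = max(0, s - flank), min(len(A), e + flank)
        v0 = bs - (s - w0)
        if allele == "A":
            seq = A[w0:w1]
            blocks = [
                _Block(0, w1 - w0, "A", c, w0, "+"),
                _Block(0, s - w0, "B", c, v0, "+"),
                _Block(s - w0, e - w0, "B", c, bs, "-"),
                _Block(e - w0, w1 - w0, "B", c, be, "+"),
            ]
        else:
            seq = np.concatenate([A[w0:s], _revcomp(A[s:e]), A[e:w1]])
            blocks = [
                _Block(0, s - w0, "A", c, w0, "+"),
                _Block(s - w0, e - w0, "A", c, s, "-"),
                _Block(e - w0, len(seq), "A", c, e, "+"),
                _Block(0, len(seq), "B", c, v0, "+"),
            ]
    else:
        raise ValueError(f"cannot simulate reads for sv_type {sv.sv_type!r}")
    return seq, blocks


def _read_alignments(read_start, read_len, blocks, ref):
    """Map read [read_start, read_start+read_len) through ref's blocks.

    Returns list of segments (read_off, seg_len, chrom, ref_start, strand).
    """
    a, b = read_start, read_start + read_len
    segs = []
    for blk in blocks:
        if blk.ref != ref:
            continue
        lo, hi = max(a, blk.hs), min(b, blk.he)
        if hi - lo < MIN_ANCHOR:
            continue
        if blk.strand == "+":
            rs = blk.rs + (lo - blk.hs)
        else:
            # reversed block: haplotype [lo, hi) maps to ref ending at
            # rs + (blk.he - lo), starting at rs + (blk.he - hi)
            rs = blk.rs + (blk.he - hi)
        segs.append((lo - a, hi - lo, blk.chrom, rs, blk.strand))
    return segs


def _cigar(read_len, off, seg_len, strand):
    if strand == "+":
        lead, trail = off, read_len - off - seg_len
    else:
        lead, trail = read_len - off - seg_len, off
    parts = []
    if lead:
        parts.append(f"{lead}S")
    parts.append(f"{seg_len}M")
    if trail:
        parts.append(f"{trail}S")
    return "".join(parts)


def simulate_read_evidence(
    genome_a: dict[str, str],
    genome_b: dict[str, str],
    sv: SVRecord,
    genotype,
    config: SimulationConfig,
    accession: str = "sample",
    rng: Optional[np.random.Generator] = None,
) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    """Emit pre-aligned synthetic reads around one SV for one accession.

    Reads are sampled from the accession's two haplotype copies at total
    depth ``config.read_depth`` and are aligned *by construction* to both
    reference genomes: reads crossing a junction present in the haplotype
    but absent from a reference become split alignments (primary +
    supplementary with an SA tag); reads inside a segment missing from a
    reference are soft-clipped or unmapped there.  Reference names carry an
    ``A_``/``B_`` prefix so one SAM holds both coordinate systems.
    """
    if isinstance(genotype, str):
        genotype = GT_CODES[genotype]
    if genotype is None or (isinstance(genotype, float) and np.isnan(genotype)):
        return make_sam_header(genome_a, genome_b), []
    alleles = {A_HOM: ("A", "A"), B_HOM: ("B", "B"), HET: ("A", "B")}[int(genotype)]

    header = make_sam_header(genome_a, genome_b)
    if config.read_depth <= 0:
        warnings.warn(f"read depth 0 requested for {sv.id}/{accession}; no reads emitted")
        return header, []
    if rng is None:
        rng = config.rng(_S_READS)

    flank = max(
        1_000,
        4 * config.read_length,
        sv.end_a - sv.start_a,
        sv.end_b - sv.start_b,
    )
    records: list[pysam.AlignedSegment] = []
    rid = 0
    for copy_i, allele in enumerate(alleles):
        seq, blocks = _allele_blocks(sv, genome_a, genome_b, allele, flank)
        hap_len = len(seq)
        if hap_len < config.read_length:
            continue
        depth = config.read_depth / 2.0
        n_reads = rng.poisson(depth * hap_len / config.read_length)
        starts = rng.integers(0, hap_len - config.read_length + 1, size=n_reads)
        for st in starts:
            rid += 1
            name = f"{accession}:{sv.id}:{copy_i}:{rid}"
            read_seq = seq[st : st + config.read_length].tobytes().decode()
            for ref in ("A", "B"):
                segs = _read_alignments(st, config.read_length, blocks, ref)
                if not segs:
                    continue
                segs.sort(key=lambda s: -s[1])
                sa_parts = [
                    (
                        reference_name(ref, s[2]),
                        s[3],
                        s[4],
                        _cigar(config.read_length, s[0], s[1], s[4]),
                    )
                    for s in segs
                ]
                for k, (off, seg_len, chrom, rs, strand) in enumerate(segs):
                    rec = pysam.AlignedSegment(header)
                    rec.query_name = name
                    rec.reference_id = header.get_tid(reference_name(ref, chrom))
                    rec.reference_start = int(rs)
                    rec.mapping_quality = 60
                    rec.cigarstring = _cigar(config.read_length, off, seg_len, strand)
                    rec.flag = (16 if strand == "-" else 0) | (0x800 if k > 0 else 0)
                    rec.query_sequence = (
                        read_seq
                        if strand == "+"
                        else _revcomp(np.frombuffer(read_seq.encode(), "S1")).tobytes().decode()
                    )
                    if len(segs) > 1:
                        others = [p for j, p in enumerate(sa_parts) if j != k]
                        rec.set_tag(
                            "SA",
                            "".join(f"{r},{p + 1},{s},{c},60,0;" for r, p, s, c in others),
                        )
                    rec.set_tag("NM", 0)
                    records.append(rec)
    return header, records


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def plan_eqtl_effects(
    matrix: GenotypeMatrix,
    config: SimulationConfig,
    n_cis: int,
    hotspot_targets: int,
    rng: Optional[np.random.Generator] = None,
    cis_beta: float = 1.5,
    hotspot_beta: float = 1.5,
) -> SimulationConfig:
    """Pick cis-effect SVs, a regulator locus and hotspot targets.

    Effect SVs are drawn from loci with pooled minor-allele frequency
    >= 0.1 that are also polymorphic *within* at least two population
    groups (within-group MAF >= 0.1): in a structured panel these are the
    loci whose dosage variation is not collinear with kinship, i.e. the
    loci at which an association design actually has power.  Returns a
    copy of ``config`` with concrete ``cis_effects`` and ``hotspot`` lists.
    """
    from dataclasses import replace as _replace

    if rng is None:
        rng = config.rng(_S_EXPR + 1)
    d = matrix.dosage(impute_mean=True).values
    f = d.mean(axis=1) / 2.0
    maf = np.minimum(f, 1 - f)
    groups = matrix.groups
    within_ok = np.zeros(len(maf), dtype=int)
    for grp in groups.unique():
        members = [i for i, a in enumerate(matrix.accessions) if groups[a] == grp]
        if len(members) < 10:
            continue
        fg = d[:, members].mean(axis=1) / 2.0
        within_ok += (np.minimum(fg, 1 - fg) >= 0.1).astype(int)
    eligible = np.where((maf >= 0.1) & (within_ok >= 2))[0]
    if len(eligible) < n_cis + 1:
        raise ValueError("not enough common SVs to plant the requested effects")
    chosen = rng.choice(eligible, size=n_cis + 1, replace=False)
    reg_sv = int(chosen[0])
    cis_svs = chosen[1:]

    n_genes = config.n_genes
    gene_pool = list(rng.permutation(n_genes))
    reg_gene = gene_pool.pop()
    cis_genes = [gene_pool.pop() for _ in range(n_cis)]
    targets = [gene_pool.pop() for _ in range(hotspot_targets)]

    cis_effects = [(g, int(sv), cis_beta) for g, sv in zip(cis_genes, cis_svs)]
    cis_effects.append((reg_gene, reg_sv, config.regulator_beta))
    hotspot = (reg_gene, targets, hotspot_beta)
    return _replace(config, cis_effects=cis_effects, hotspot=hotspot)


def simulate_expression(
    matrix: GenotypeMatrix,
    config: SimulationConfig,
    truth: Optional[TruthSet] = None,
):
    """Simulate per-gene expression scores with planted cis/trans effects.

    Expression of gene g in accession j is
    ``baseline_g + sum(beta * dosage) + trans + N(0, noise_sd)``; hotspot
    target genes add ``beta_hot * standardized(regulator expression)``.
    Gene coordinates are assigned so that each planted cis SV lies within
    50 kb of its gene's TSS while all other genes are placed away from
    their associated SVs.  Returns an :class:`~svdomest.eqtl.ExpressionMatrix`.
    """
    from .eqtl import ExpressionMatrix  # local import to avoid a cycle

    if matrix.calls.shape[1] < 20:
        raise ValueError("need at least 20 accessions for expression simulation")
    rng = config.rng(_S_EXPR)
    n_genes = config.n_genes
    acc = list(matrix.accessions)
    dos = matrix.dosage(impute_mean=True)

    sv_ids = list(matrix.sv_ids)
    for g, sv, _ in config.cis_effects:
        if g >= n_genes:
            raise ValueError(f"cis effect references unknown gene index {g}")
        if isinstance(sv, str) and sv not in sv_ids:
            raise ValueError(f"cis effect references unknown SV {sv}")
        if isinstance(sv, (int, np.integer)) and sv >= len(sv_ids):
            raise ValueError(f"cis effect references unknown SV index {sv}")

    # gene coordinates: spread genes over the chromosomes, then pin each
    # cis gene's TSS within the cis window of its causal SV
    pos = matrix.positions
    chroms = list(pos["chrom"].unique()) if pos is not None else ["chr1"]
    span = (
        {c: int(pos.loc[pos["chrom"] == c, "pos"].max() + 100_000) for c in chroms}
        if pos is not None
        else {"chr1": 1_000_000}
    )
    gene_chrom = [chroms[i % len(chroms)] for i in range(n_genes)]
    gene_tss = np.array(
        [rng.integers(0, span[gene_chrom[i]]) for i in range(n_genes)], dtype=np.int64
    )
    strand = rng.choice(["+", "-"], size=n_genes)
    glen = rng.integers(1_000, 5_000, size=n_genes)

    def _sv_index(sv) -> int:
        return sv_ids.index(sv) if isinstance(sv, str) else int(sv)

    effect_rows = []
    base = rng.normal(0.0, config.expression_baseline_sd, size=(n_genes, 1))
    values = np.repeat(base, len(acc), axis=1)
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=(n_genes, len(acc)))

    for g, sv, beta in config.cis_effects:
        si = _sv_index(sv)
        sv_id = sv_ids[si]
        values[g] += beta * dos.iloc[si].values
        if pos is not None:
            gene_chrom[g] = pos.iloc[si]["chrom"]
            gene_tss[g] = max(0, int(pos.iloc[si]["pos"]) + int(rng.integers(-30_000, 30_000)))
        effect_rows.append(dict(gene=f"gene{g + 1:04d}", sv=sv_id, beta=beta, kind="cis"))

    if config.hotspot is not None:
        reg, targets, beta_h = config.hotspot
        reg_expr = values[reg]
        z = (reg_expr - reg_expr.mean()) / max(reg_expr.std(), 1e-12)
        for t in targets:
            values[t] += beta_h * z
            effect_rows.append(
                dict(gene=f"gene{t + 1:04d}", sv=f"gene{reg + 1:04d}", beta=beta_h, kind="trans")
            )
        # keep trans targets away from the regulator locus
        reg_chrom = gene_chrom[reg]
        for t in targets:
            if gene_chrom[t] == reg_chrom and abs(int(gene_tss[t]) - int(gene_tss[reg])) < 500_000:
                gene_tss[t] = (int(gene_tss[t]) + span[reg_chrom] // 2) % span[reg_chrom]

    # technical / physiological confounders act on the measurement, after
    # the regulatory biology: every gene picks up shared hidden factors
    if config.noise_sd > 0 and config.n_confounders > 0:
        sds = config.confounder_sd * config.confounder_decay ** np.arange(
            config.n_confounders
        )
        load = rng.normal(0.0, 1.0, size=(n_genes, config.n_confounders)) * sds
        fac = rng.normal(0.0, 1.0, size=(config.n_confounders, len(acc)))
        values += load @ fac

    gene_ids = [f"gene{i + 1:04d}" for i in range(n_genes)]
    tes = np.where(strand == "+", gene_tss + glen, gene_tss - glen).clip(min=0)
    genes = pd.DataFrame(
        {"chrom": gene_chrom, "tss": gene_tss, "tes": tes, "strand": strand},
        index=gene_ids,
    )
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=acc),
        genes=genes,
        stage="simulated",
    )
    if truth is not None:
        truth.eqtl_effects = pd.DataFrame(
            effect_rows, columns=["gene", "sv", "beta", "kind"]
        )
    return expr
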