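"""Population SV genotyping from read alignments to both reference genomes.

Each SV is called per accession from split-read and read-depth evidence
gathered around its breakpoints on the two coordinate systems.  An allele
is supported either by >= 3 junction (split) reads at a breakpoint, or --
for the allele lacking the segment -- by the depth rule: less than 50% of
the variable region covered at 2x while more than 50% of a flanking region
of the same length is covered.  Support for both alleles yields a
heterozygous call, for one allele the corresponding homozygote, for
neither an undetermined (missing) call.  Inversions are called from split
reads alone, requiring every breakpoint to reach the split threshold.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .records import (
    A_HOM,
    B_HOM,
    HET,
    EvidenceSummary,
    GenotypeMatrix,
    SVRecord,
)
from .simulate import reference_name

log = logging.getLogger(__name__)

#: split reads required at a breakpoint to support an allele
MIN_SPLIT_READS = 3
#: spanning reads required to support the segment-carrying allele
MIN_SPANNING_READS = 3
#: junction position tolerance around a breakpoint (bp)
JUNCTION_TOL = 10
#: depth-rule coverage threshold
COVER_FRAC = 0.5
#: accessions with fewer than this fraction of SVs genotyped are excluded
MIN_GENOTYPED_FRAC = 0.40
#: alignment mismatch cap (NM / read length)
MAX_MISMATCH_FRAC = 0.03


def dedup_read_pairs(pairs: Sequence[tuple[str, str]], read_length: int) -> list[tuple[str, str]]:
    """Collapse duplicated read pairs by prefix identity.

    Pairs identical over the first 90 bp (100-bp reads) or 100 bp (150-bp
    reads) of BOTH mates are one equivalence class; the first member is
    kept.  Other read lengths fall back to ``min(read_length, 100)`` with a
    warning.
    """
    if read_length == 100:
        k = 90
    elif read_length == 150:
        k = 100
    else:
        k = min(read_length, 100)
        warnings.warn(
            f"unsupported read length {read_length}; deduplicating on {k}-bp prefixes"
        )
    seen: set[tuple[str, str]] = set()
    out = []
    for left, right in pairs:
        key = (left[:k], right[:k])
        if key in seen:
            continue
        seen.add(key)
        out.append((left, right))
    return out


def _passes_mismatch_filter(rec: pysam.AlignedSegment) -> bool:
    if not rec.has_tag("NM") or rec.query_length in (None, 0):
        return True
    return rec.get_tag("NM") <= MAX_MISMATCH_FRAC * rec.query_length


def _junctions(rec: pysam.AlignedSegment) -> list[int]:
    """Reference positions of clip junctions of an SA-tagged alignment."""
    out = []
    ct = rec.cigartuples or []
    if ct and ct[0][0] in (4, 5):  # leading clip
        out.append(rec.reference_start)
    if ct and ct[-1][0] in (4, 5):  # trailing clip
        out.append(rec.reference_end)
    return out


def _carrier(sv: SVRecord) -> tuple[str, str, tuple[int, ...], str, tuple[int, ...], tuple[int, int]]:
    """Carrier genome, its breakpoints, other genome and its breakpoints,
    plus the variable region on the carrier."""
    if sv.sv_type == "deletion":
        return ("A", sv.chrom_a, (sv.start_a, sv.end_a), "B", (sv.start_b,), (sv.start_a, sv.end_a))
    if sv.sv_type == "insertion":
        return ("B", sv.chrom_b, (sv.start_b, sv.end_b), "A", (sv.start_a,), (sv.start_b, sv.end_b))
    if sv.sv_type == "inversion":
        return ("A", sv.chrom_a, (sv.start_a, sv.end_a), "B", (sv.start_b, sv.end_b), (sv.start_a, sv.end_a))
    raise ValueError(f"cannot genotype sv_type {sv.sv_type!r}")


def collect_evidence(
    alignments_to_a: Iterable[pysam.AlignedSegment],
    alignments_to_b: Iterable[pysam.AlignedSegment],
    sv: SVRecord,
    accession: str = "sample",
    junction_tol: int = JUNCTION_TOL,
    ref_lengths: Optional[dict[str, int]] = None,
) -> EvidenceSummary:
    """Summarise split, spanning and depth evidence for one SV.

    Split reads are SA-tagged alignments whose clip junction lies within
    ``junction_tol`` of a breakpoint (unique read names counted).  Spanning
    reads are contiguous primary alignments covering a carrier breakpoint
    with at least ``junction_tol`` bp on each side.  Depth fractions are
    computed over the variable region and two equal-length flanks on the
    carrier genome from contiguous alignments only.
    """
    carrier, chrom, bps, other, other_bps, region = _carrier(sv)
    carrier_ref = reference_name(carrier, chrom)
    other_chrom = sv.chrom_b if other == "B" else sv.chrom_a
    other_ref = reference_name(other, other_chrom)

    if ref_lengths is not None:
        L = ref_lengths.get(carrier_ref)
        if L is not None and (region[0] < 0 or region[1] > L):
            raise ValueError(f"SV {sv.id}: coordinates outside reference {carrier_ref}")

    rlen = region[1] - region[0]
    flank_l = (max(0, region[0] - rlen), region[0])
    flank_r = (region[1], region[1] + rlen)
    lo = flank_l[0]
    hi = flank_r[1]
    depth = np.zeros(max(hi - lo, 1), dtype=np.int32)

    split_names: dict[int, set[str]] = {i: set() for i in range(len(bps))}
    alt_names: dict[int, set[str]] = {i: set() for i in range(len(other_bps))}
    spanning: dict[int, set[str]] = {i: set() for i in range(len(bps))}

    def carrier_pass(rec: pysam.AlignedSegment) -> None:
        if rec.is_unmapped or rec.reference_name != carrier_ref:
            return
        if not _passes_mismatch_filter(rec):
            return
        is_split = rec.has_tag("SA")
        if is_split:
            for j in _junctions(rec):
                for i, bp in enumerate(bps):
                    if abs(j - bp) <= junction_tol:
                        split_names[i].add(rec.query_name)
        else:
            if not rec.is_supplementary and not rec.is_secondary:
                s, e = rec.reference_start, rec.reference_end
                for i, bp in enumerate(bps):
                    if s <= bp - junction_tol and e >= bp + junction_tol:
                        spanning[i].add(rec.query_name)
        if not rec.is_secondary:
            for s, e in rec.get_blocks():
                s2, e2 = max(s, lo), min(e, hi)
                if s2 < e2:
                    depth[s2 - lo : e2 - lo] += 1

    def other_pass(rec: pysam.AlignedSegment) -> None:
        if rec.is_unmapped or rec.reference_name != other_ref:
            return
        if not _passes_mismatch_filter(rec) or not rec.has_tag("SA"):
            return
        for j in _junctions(rec):
            for i, bp in enumerate(other_bps):
                if abs(j - bp) <= junction_tol:
                    alt_names[i].add(rec.query_name)

    src_a, src_b = alignments_to_a, alignments_to_b
    for rec in src_a:
        (carrier_pass if carrier == "A" else other_pass)(rec)
    for rec in src_b:
        (carrier_pass if carrier == "B" else other_pass)(rec)

    def frac(iv: tuple[int, int]) -> float:
        s, e = iv[0] - lo, iv[1] - lo
        if e <= s:
            return 0.0
        return float((depth[s:e] >= 2).mean())

    return EvidenceSummary(
        sv_id=sv.id,
        accession=accession,
        sv_type=sv.sv_type,
        split_reads_bp1=len(split_names.get(0, ())),
        split_reads_bp2=len(split_names.get(1, ())),
        alt_split_bp1=len(alt_names.get(0, ())),
        alt_split_bp2=len(alt_names.get(1, ())),
        spanning_reads_bp1=len(spanning.get(0, ())),
        spanning_reads_bp2=len(spanning.get(1, ())),
        deleted_region_covered_frac_at_2x=frac(region),
        left_flank_covered_frac=frac(flank_l),
        right_flank_covered_frac=frac(flank_r),
    )


def split_by_reference(
    records: Iterable[pysam.AlignedSegment],
) -> tuple[list[pysam.AlignedSegment], list[pysam.AlignedSegment]]:
    """Partition mixed-reference alignments into (to genome A, to genome B)."""
    to_a, to_b = [], []
    for rec in records:
        name = rec.reference_name or ""
        (to_a if name.startswith("A_") else to_b).append(rec)
    return to_a, to_b


def call_genotype(
    ev: EvidenceSummary,
    sv_type: Optional[str] = None,
    min_split: int = MIN_SPLIT_READS,
):
    """Decide A_HOM / B_HOM / HET / missing from one evidence summary.

    Pure function of the summary: inversions require the split threshold at
    *every* breakpoint for an orientation to count as supported; indels
    accept either the split-read criterion at a breakpoint or, for the
    segment-absent allele, the depth rule, and for the segment-present
    allele spanning coverage of the region.
    """
    sv_type = sv_type or ev.sv_type
    cov = ev.deleted_region_covered_frac_at_2x
    flank = max(ev.left_flank_covered_frac, ev.right_flank_covered_frac)
    span = max(ev.spanning_reads_bp1, ev.spanning_reads_bp2)
    split = max(ev.split_reads_bp1, ev.split_reads_bp2)
    alt = max(ev.alt_split_bp1, ev.alt_split_bp2)

    if sv_type == "inversion":
        b_sup = min(ev.split_reads_bp1, ev.split_reads_bp2) >= min_split
        a_sup = min(ev.alt_split_bp1, ev.alt_split_bp2) >= min_split
    elif sv_type in ("deletion", "insertion"):
        absent_sup = split >= min_split or (cov < COVER_FRAC and flank > COVER_FRAC)
        present_sup = alt >= min_split or (
            cov > COVER_FRAC and span >= MIN_SPANNING_READS
        )
        if sv_type == "deletion":
            a_sup, b_sup = present_sup, absent_sup
        else:
            a_sup, b_sup = absent_sup, present_sup
    else:
        raise ValueError(f"cannot genotype sv_type {sv_type!r}")

    if a_sup and b_sup:
        return HET
    if a_sup:
        return A_HOM
    if b_sup:
        return B_HOM
    return pd.NA


def build_genotype_matrix(
    evidence: Iterable[EvidenceSummary],
    groups: pd.Series,
    min_genotyped: float = MIN_GENOTYPED_FRAC,
    positions: Optional[pd.DataFrame] = None,
) -> tuple[GenotypeMatrix, list[str]]:
    """Call all evidence summaries and assemble the SV x accession matrix.

    Accessions whose called (non-missing) fraction is strictly below
    ``min_genotyped`` are dropped; the dropped list is returned alongside.
    Individual calls are never altered by the assembly step.
    """
    evidence = list(evidence)
    if not evidence:
        raise ValueError("no evidence supplied")
    seen = set()
    for ev in evidence:
        key = (ev.sv_id, ev.accession)
        if key in seen:
            raise ValueError(f"duplicate evidence for {key}")
        seen.add(key)

    rows: dict[str, dict[str, object]] = {}
    for ev in evidence:
        rows.setdefault(ev.sv_id, {})[ev.accession] = call_genotype(ev)
    calls = pd.DataFrame.from_dict(rows, orient="index").astype("Int8")
    calls = calls.sort_index()

    called_frac = calls.notna().mean(axis=0)
    dropped = [a for a in calls.columns if called_frac[a] < min_genotyped]
    if dropped:
        log.info("excluding %d accessions below %.0f%% genotyped", len(dropped), 100 * min_genotyped)
    kept = [a for a in calls.columns if a not in dropped]
    matrix = GenotypeMatrix(
        calls[kept],
        groups,
        positions.loc[calls.index] if positions is not None else None,
    )
    return matrix, dropped


def concordance(calls1: GenotypeMatrix, calls2: GenotypeMatrix) -> float:
    """Fraction of shared, doubly-called cells with identical genotype."""
    svs = calls1.sv_ids.intersection(calls2.sv_ids)
    acc = calls1.accessions.intersection(calls2.accessions)
    if len(svs) == 0 or len(acc) == 0:
        raise ValueError("matrices share no cells")
    a = calls1.calls.loc[svs, acc]
    b = calls2.calls.loc[svs, acc]
    both = a.notna() & b.notna()
    n = int(both.values.sum())
    if n == 0:
        raise ValueError("no shared non-missing calls")
    eq = (a == b) & both
    return float(eq.values.sum()) / n
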