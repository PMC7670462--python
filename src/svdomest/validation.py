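"""Validation, normalization and merging of candidate reference SVs.

Candidates come from two routes: direct genome-to-genome comparison
(Assemblytics-style calls on the whole-genome alignment) and long-read
mapping callers.  The operations here implement the reference-set filters:
dropping calls near assembly gaps, anchoring indel flanks on the query
genome, confirming inversion breakpoints with split reads or dual-caller
support, converting repeat/tandem expansion-contraction calls into simple
indels with precise breakpoints, and 50%-reciprocal-overlap merging of the
two routes into one reference SV set.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Optional, Sequence

import numpy as np

from .records import (
    INDEL_TYPES,
    REPEAT_TYPES,
    FlankHit,
    GapTrack,
    SVRecord,
)

log = logging.getLogger(__name__)

#: minimum distance (bp) from any assembly gap on either genome
GAP_MIN_DIST = 50
#: flank-anchor acceptance: alignment length, identity (%), e-value
FLANK_MIN_LEN = 50
FLANK_MIN_IDENT = 90.0
FLANK_MAX_EVALUE = 1e-10
#: insertions: |hit distance - size estimate| must be < this fraction of the estimate
INSERTION_SIZE_TOL = 0.20
#: deletions: gap/overlap between the two flank hits must be < this many bp
DELETION_GAP_MAX = 3
#: inversions: split-read fraction of breakpoint-spanning reads
INVERSION_SPLIT_FRAC = 0.9
#: reciprocal overlap fraction for merging
RECIPROCAL_OVERLAP = 0.5
#: insertions are merged on breakpoint distance (bp) + size ratio instead
INSERTION_BP_DIST = 100
INSERTION_SIZE_RATIO = 0.5


def filter_gap_proximity(
    svs: Sequence[SVRecord],
    gaps_a: GapTrack,
    gaps_b: GapTrack,
    min_dist: int = GAP_MIN_DIST,
) -> list[SVRecord]:
    """Drop SVs spanning or closer than ``min_dist`` bp to a gap on either genome.

    Output preserves input order and is always a subset of the input.
    """
    kept = []
    for sv in svs:
        da = gaps_a.min_distance(sv.chrom_a, sv.start_a, sv.end_a)
        db = gaps_b.min_distance(sv.chrom_b, sv.start_b, sv.end_b)
        if da >= min_dist and db >= min_dist:
            kept.append(sv)
    return kept


def _qualifying(hit: FlankHit) -> bool:
    return (
        hit.align_length > FLANK_MIN_LEN
        and hit.identity > FLANK_MIN_IDENT
        and hit.evalue < FLANK_MAX_EVALUE
    )


def expected_query_region(
    sv: SVRecord, projected_pos: Optional[int] = None
) -> tuple[int, int]:
    """Window on the query genome where the flank hits are expected.

    Centered on the position projected through the unique alignment blocks
    (the SV's own B coordinates when no external projection is supplied),
    extended by 2x the estimated SV size plus 10 kb on each side.
    """
    center = projected_pos if projected_pos is not None else (sv.start_b + sv.end_b) // 2
    slack = 2 * sv.size + 10_000
    return center - slack, center + slack


def validate_indel_flanks(
    sv: SVRecord,
    hits: Sequence[FlankHit],
    read_size_estimate: float,
    projected_pos: Optional[int] = None,
) -> bool:
    """Flank-anchor validation of one indel against query-genome hits.

    Both flanks need a qualifying hit (length > 50 bp, identity > 90%,
    e-value < 1e-10) inside the expected query region.  The geometry rule
    then depends on the type: for insertions the distance between the two
    hits must agree with the read-based size estimate to within 20% of that
    estimate; for deletions the gap or overlap between the hits must be
    smaller than 3 bp.
    """
    if sv.sv_type == "inversion":
        raise ValueError("inversions are validated by validate_inversion")
    if sv.sv_type not in INDEL_TYPES:
        raise ValueError(f"flank validation undefined for {sv.sv_type!r}")

    lo, hi = expected_query_region(sv, projected_pos)
    best: dict[str, FlankHit] = {}
    for h in hits:
        if not _qualifying(h):
            continue
        if h.hit_chrom != sv.chrom_b or h.hit_end <= lo or h.hit_start >= hi:
            continue
        cur = best.get(h.flank)
        if cur is None or h.evalue < cur.evalue:
            best[h.flank] = h
    if "left" not in best or "right" not in best:
        return False
    left, right = best["left"], best["right"]
    if sv.sv_type == "insertion":
        distance = right.hit_start - left.hit_end
        return abs(distance - read_size_estimate) < INSERTION_SIZE_TOL * read_size_estimate
    # deletion: flank hits should be adjacent on the query genome
    gap = right.hit_start - left.hit_end  # negative = overlap
    return abs(gap) < DELETION_GAP_MAX


def validate_inversion(
    sv: SVRecord,
    breakpoint_reads: Sequence[tuple[int, int]],
    caller_support: Sequence[str] = (),
) -> bool:
    """Confirm an inversion from breakpoint split-read fractions or callers.

    Accepted when more than 90% of the reads spanning every covered
    breakpoint are split reads, or when both read-mapping callers report it.
    Breakpoints with zero spanning reads contribute no split-read support.
    """
    if sv.sv_type != "inversion":
        raise ValueError("validate_inversion only applies to inversions")
    support = set(caller_support)
    both_callers = {"read_mapping_caller1", "read_mapping_caller2"} <= support
    if both_callers:
        return True
    ok = True
    for split, total in breakpoint_reads:
        if total < 0 or split < 0:
            raise ValueError("read counts must be non-negative")
        if total == 0 or split / total <= INVERSION_SPLIT_FRAC:
            ok = False
    return ok and len(breakpoint_reads) > 0


def normalize_repeat_svs(
    assemblytics_style: Sequence[SVRecord],
    precise_breakpoints: Sequence[SVRecord],
) -> list[SVRecord]:
    """Convert repeat/tandem expansion-contraction calls into simple indels.

    Each repeat-class record that contains >= 1 precise read-mapping indel
    within its genome-A interval is replaced by those indels (retyped
    insertion/deletion, inheriting the union of sources); repeat-class
    records with no precise match are dropped.  Simple calls pass through.
    """
    precise = [p for p in precise_breakpoints if p.sv_type in INDEL_TYPES]
    out: list[SVRecord] = []
    for sv in assemblytics_style:
        if sv.sv_type not in REPEAT_TYPES:
            out.append(sv)
            continue
        inside = [
            p
            for p in precise
            if p.chrom_a == sv.chrom_a
            and p.start_a >= sv.start_a
            and p.end_a <= sv.end_a
        ]
        if not inside:
            log.debug("repeat SV %s has no precise breakpoint; dropped", sv.id)
            continue
        for j, p in enumerate(inside):
            out.append(
                replace(
                    p,
                    id=f"{sv.id}.{j + 1}" if len(inside) > 1 else sv.id,
                    sources=p.sources | sv.sources,
                    validated=True,
                )
            )
    return out


def _reciprocal_overlap(x: SVRecord, y: SVRecord) -> float:
    """Min of the two overlap fractions on genome A; 0 when disjoint."""
    ov = min(x.end_a, y.end_a) - max(x.start_a, y.start_a)
    if ov <= 0:
        return 0.0
    return min(ov / x.len_a, ov / y.len_a)


def _insertions_match(x: SVRecord, y: SVRecord) -> bool:
    if abs(x.start_a - y.start_a) > INSERTION_BP_DIST:
        return False
    ratio = min(x.size, y.size) / max(x.size, y.size)
    return ratio > INSERTION_SIZE_RATIO


def merge_sv_sets(
    set1: Sequence[SVRecord],
    set2: Sequence[SVRecord],
    reciprocal: float = RECIPROCAL_OVERLAP,
) -> list[SVRecord]:
    """Merge two SV call sets by >50% reciprocal overlap per type.

    A pair of same-type records merges when the overlap exceeds
    ``reciprocal`` of BOTH interval lengths on genome A; insertions (whose
    A interval is a point) merge on breakpoint distance <= 100 bp plus a
    size ratio > 0.5.  The combined record keeps ``set1`` coordinates and
    the union of sources.  When one record overlaps several partners the
    pair with the larger reciprocal overlap wins, remaining ties broken by
    leftmost start, so output is deterministic.  Unmerged records from both
    sets are retained; the result is idempotent (merging a set with itself
    returns records one-for-one).
    """
    out: list[SVRecord] = []
    used2: set[int] = set()
    candidates: list[tuple[float, int, int, int]] = []
    for i, x in enumerate(set1):
        for j, y in enumerate(set2):
            if x.sv_type != y.sv_type or x.chrom_a != y.chrom_a:
                continue
            if x.sv_type == "insertion":
                if _insertions_match(x, y):
                    score = 1.0 - abs(x.start_a - y.start_a) / (INSERTION_BP_DIST + 1)
                    candidates.append((score, min(x.start_a, y.start_a), i, j))
            else:
                ro = _reciprocal_overlap(x, y)
                if ro > reciprocal:
                    candidates.append((ro, min(x.start_a, y.start_a), i, j))
    # greedy: best reciprocal overlap first, leftmost on ties
    candidates.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    matched1: dict[int, int] = {}
    for _, _, i, j in candidates:
        if i in matched1 or j in used2:
            continue
        matched1[i] = j
        used2.add(j)
    for i, x in enumerate(set1):
        if i in matched1:
            y = set2[matched1[i]]
            out.append(x.with_sources(y.sources))
        else:
            out.append(x)
    for j, y in enumerate(set2):
        if j not in used2:
            out.append(y)
    return out


def build_reference_sv_set(
    genome_comparison: Sequence[SVRecord],
    read_mapping: Sequence[SVRecord],
    gaps_a: GapTrack,
    gaps_b: GapTrack,
    flank_hits: Optional[dict[str, Sequence[FlankHit]]] = None,
    size_estimates: Optional[dict[str, float]] = None,
    inversion_evidence: Optional[dict[str, Sequence[tuple[int, int]]]] = None,
    min_gap_dist: int = GAP_MIN_DIST,
) -> list[SVRecord]:
    """Full validation pipeline producing the reference SV set.

    Gap filter -> inversion confirmation -> repeat-call conversion ->
    flank-anchor validation of indels -> reciprocal merging of the
    genome-comparison and read-mapping call sets.  ``flank_hits`` and
    ``size_estimates`` are keyed by SV id; indels without flank evidence are
    kept only when a read-mapping caller also reports them (handled by the
    merge step marking dual support).
    """
    svs = filter_gap_proximity(genome_comparison, gaps_a, gaps_b, min_gap_dist)
    reads = filter_gap_proximity(read_mapping, gaps_a, gaps_b, min_gap_dist)

    kept: list[SVRecord] = []
    for sv in svs:
        if sv.sv_type == "inversion":
            ev = (inversion_evidence or {}).get(sv.id, [])
            if validate_inversion(sv, ev, sv.sources):
                kept.append(replace(sv, validated=True))
        else:
            kept.append(sv)

    kept = normalize_repeat_svs(kept, reads)

    validated: list[SVRecord] = []
    for sv in kept:
        if sv.sv_type in INDEL_TYPES and flank_hits is not None:
            hits = flank_hits.get(sv.id, [])
            est = (size_estimates or {}).get(sv.id, float(sv.size))
            if validate_indel_flanks(sv, hits, est):
                validated.append(replace(sv, validated=True))
        else:
            validated.append(sv)

    return merge_sv_sets(validated, reads)


# ---------------------------------------------------------------------------
# toy flank anchorer (exact matching; stands in for BLAST on toy genomes)
# ---------------------------------------------------------------------------


def anchor_flanks_exact(
    sv: SVRecord,
    genome_a: dict[str, str],
    genome_b: dict[str, str],
    flank_len: int = 5_000,
) -> list[FlankHit]:
    """Exact-substring flank anchoring for synthetic genomes.

    Extracts up to ``flank_len`` bp on each side of the SV from the genome
    carrying the segment's context (genome A) and locates the first exact
    occurrence in genome B.  Only suitable for toy data; real data should
    supply BLAST-format hit tables instead.
    """
    seq_a = genome_a[sv.chrom_a]
    seq_b = genome_b[sv.chrom_b]
    hits = []
    left = seq_a[max(0, sv.start_a - flank_len) : sv.start_a]
    right = seq_a[sv.end_a : sv.end_a + flank_len]
    for flank, s in (("left", left), ("right", right)):
        if len(s) <= FLANK_MIN_LEN:
            continue
        # search near the expected projection first to keep toy runs fast
        idx = seq_b.find(s)
        if idx < 0:
            continue
        hits.append(
            FlankHit(
                flank=flank,
                hit_chrom=sv.chrom_b,
                hit_start=idx,
                hit_end=idx + len(s),
                align_length=len(s),
                identity=100.0,
                evalue=0.0,
            )
        )
    return hits
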