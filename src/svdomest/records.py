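"""Core record types shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; standard
formats (SAM/VCF/GFF3) are converted at the I/O boundary.  The two reference
genomes are called "A" (the wild-reference, LA2093-like assembly) and "B"
(the cultivar-reference, Heinz-like assembly); the A/B *alleles* of an SV
locus are the corresponding states in a sampled accession.

Genotype calls are coded as small integers matching the flat-matrix export
convention: 0 = homozygous B, 1 = heterozygous, 2 = homozygous A, and a
missing value (pandas NA) for undetermined calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

# Genotype codes (dosage of the A allele).
B_HOM = 0
HET = 1
A_HOM = 2
MISSING = None  # represented as pd.NA inside matrices

GT_LABELS = {B_HOM: "B_HOM", HET: "HET", A_HOM: "A_HOM"}
GT_CODES = {v: k for k, v in GT_LABELS.items()}

SV_TYPES = (
    "insertion",
    "deletion",
    "inversion",
    "repeat_contraction",
    "repeat_expansion",
    "tandem_contraction",
    "tandem_expansion",
)
INDEL_TYPES = ("insertion", "deletion")
REPEAT_TYPES = (
    "repeat_contraction",
    "repeat_expansion",
    "tandem_contraction",
    "tandem_expansion",
)

SOURCES = ("genome_alignment", "read_mapping_caller1", "read_mapping_caller2")

#: minimum SV size considered by the pipeline (bp)
MIN_SV_SIZE = 10

GROUPS = ("SP", "SCG", "SLC", "heirloom", "modern", "other")
#: groups simulated and used by the domestication-stage analyses, in
#: chronological order wild -> early domesticate -> heirloom -> modern
STAGE_GROUPS = ("SP", "SLC", "heirloom", "modern")


@dataclass
class SVRecord:
    """One structural variant with coordinates on both reference genomes.

    ``start_a``/``end_a`` delimit the affected interval on genome A; for an
    insertion (sequence present only in B) the A interval is the zero-length
    breakpoint and the B interval holds the inserted segment, and vice versa
    for deletions.
    """

    id: str
    sv_type: str
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    size: int
    sources: frozenset = field(default_factory=frozenset)
    validated: bool = False

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.start_a > self.end_a or self.start_b > self.end_b:
            raise ValueError(f"{self.id}: start > end")
        if self.size < MIN_SV_SIZE:
            raise ValueError(f"{self.id}: size {self.size} below {MIN_SV_SIZE} bp floor")
        if self.sv_type == "inversion" and (
            self.end_a - self.start_a != self.end_b - self.start_b
        ):
            raise ValueError(f"{self.id}: inversion intervals differ in length")
        self.sources = frozenset(self.sources)

    @property
    def len_a(self) -> int:
        return self.end_a - self.start_a

    @property
    def len_b(self) -> int:
        return self.end_b - self.start_b

    def with_sources(self, extra: Iterable[str]) -> "SVRecord":
        return replace(self, sources=self.sources | frozenset(extra))


@dataclass
class FlankHit:
    """A BLAST-like hit of one 5-kb SV flank against the query genome."""

    flank: str  # "left" or "right"
    hit_chrom: str
    hit_start: int
    hit_end: int
    align_length: int
    identity: float  # percent
    evalue: float

    def __post_init__(self) -> None:
        if self.flank not in ("left", "right"):
            raise ValueError("flank must be 'left' or 'right'")
        if self.align_length <= 0:
            raise ValueError("align_length must be positive")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be a percentage")


class GapTrack:
    """Sorted, non-overlapping assembly-gap intervals per chromosome."""

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None):
        self._ivs: dict[str, np.ndarray] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                arr = np.asarray(sorted(ivs), dtype=np.int64).reshape(-1, 2)
                if len(arr) > 1 and np.any(arr[1:, 0] < arr[:-1, 1]):
                    raise ValueError(f"overlapping gap intervals on {chrom}")
                self._ivs[chrom] = arr

    def intervals(self, chrom: str) -> np.ndarray:
        return self._ivs.get(chrom, np.empty((0, 2), dtype=np.int64))

    def min_distance(self, chrom: str, start: int, end: int) -> float:
        """Distance (bp) from [start, end) to the nearest gap; 0 if overlapping.

        Returns ``inf`` when the chromosome carries no gaps.
        """
        ivs = self.intervals(chrom)
        if len(ivs) == 0:
            return float("inf")
        # gap strictly left of the interval: distance start - gap_end
        d = np.where(
            ivs[:, 1] <= start,
            start - ivs[:, 1],
            np.where(ivs[:, 0] >= end, ivs[:, 0] - end, 0),
        )
        return float(d.min())


@dataclass
class EvidenceSummary:
    """Per-SV, per-accession read evidence used by the genotype rules.

    Split and spanning counts refer to the *carrier* genome -- the reference
    that contains the variable segment (genome A for deletions and
    inversions, genome B for insertions).  ``split_reads_bp*`` count junction
    (SA-tagged) reads at the carrier breakpoints; these support the allele
    *lacking* the segment (or, for inversions, the opposite orientation).
    ``alt_split_bp*`` count junction reads on the other reference and support
    the segment-carrying allele / carrier orientation.  Depth fractions are
    measured on the carrier genome over the variable interval and two
    equal-length flanks.
    """

    sv_id: str
    accession: str
    sv_type: str
    split_reads_bp1: int = 0
    split_reads_bp2: int = 0
    alt_split_bp1: int = 0
    alt_split_bp2: int = 0
    spanning_reads_bp1: int = 0
    spanning_reads_bp2: int = 0
    deleted_region_covered_frac_at_2x: float = 0.0
    left_flank_covered_frac: float = 0.0
    right_flank_covered_frac: float = 0.0

    def __post_init__(self) -> None:
        for f in (
            self.split_reads_bp1,
            self.split_reads_bp2,
            self.alt_split_bp1,
            self.alt_split_bp2,
            self.spanning_reads_bp1,
            self.spanning_reads_bp2,
        ):
            if f < 0:
                raise ValueError("read counts must be non-negative")
        for f in (
            self.deleted_region_covered_frac_at_2x,
            self.left_flank_covered_frac,
            self.right_flank_covered_frac,
        ):
            if not 0.0 <= f <= 1.0:
                raise ValueError("coverage fractions must lie in [0, 1]")


class GenotypeMatrix:
    """SV x accession genotype calls plus group labels and SV positions.

    ``calls`` is an Int8 DataFrame (rows: SV ids, columns: accession ids)
    holding dosages of the A allele {0, 1, 2} with pandas NA for missing.
    ``groups`` maps each accession to one of the recognised group labels.
    ``positions`` (optional) carries per-SV genome-A coordinates used by the
    windowed analyses.
    """

    def __init__(
        self,
        calls: pd.DataFrame,
        groups: pd.Series,
        positions: Optional[pd.DataFrame] = None,
    ):
        calls = calls.astype("Int8")
        bad = set(groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        missing_groups = [a for a in calls.columns if a not in groups.index]
        if missing_groups:
            raise ValueError(f"accessions without group label: {missing_groups[:5]}")
        self.calls = calls
        self.groups = groups.loc[calls.columns]
        if positions is not None:
            positions = positions.loc[calls.index]
        self.positions = positions

    @property
    def sv_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def accessions(self) -> pd.Index:
        return self.calls.columns

    def accessions_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def dosage(self, impute_mean: bool = False) -> pd.DataFrame:
        """A-allele dosage as float, NaN (or per-SV mean) for missing."""
        d = self.calls.astype("float64")
        if impute_mean:
            d = d.apply(lambda row: row.fillna(row.mean()), axis=1)
        return d

    def subset(self, sv_ids=None, accessions=None) -> "GenotypeMatrix":
        calls = self.calls
        if sv_ids is not None:
            calls = calls.loc[sv_ids]
        if accessions is not None:
            calls = calls[accessions]
        pos = self.positions.loc[calls.index] if self.positions is not None else None
        return GenotypeMatrix(calls, self.groups.loc[calls.columns], pos)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<GenotypeMatrix {self.calls.shape[0]} SVs x "
            f"{self.calls.shape[1]} accessions>"
        )
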