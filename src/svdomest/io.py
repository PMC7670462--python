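"""Readers and writers for the standard formats plus pipeline configuration.

External files use the community conventions (1-based FASTA/SAM/VCF/GFF3,
0-based half-open BED); everything is converted to internal 0-based
half-open coordinates on the way in.  The flat genotype matrix codes calls
0/1/2/NA for homozygous-B / heterozygous / homozygous-A / missing; genotype
VCF output uses REF = B allele, so 0/0 is the cultivar-reference homozygote.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import GapTrack, GenotypeMatrix, SVRecord

_SVTYPE_TO_ALT = {"deletion": "<DEL>", "insertion": "<INS>", "inversion": "<INV>"}
_ALT_TO_SVTYPE = {"DEL": "deletion", "INS": "insertion", "INV": "inversion"}


class FormatError(ValueError):
    """Malformed record in an input file (carries file and line)."""

    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    genome = {str(r.id): str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise FormatError(path, 0, "empty FASTA")
    return genome


def write_fasta(genome: dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def write_sam(header: pysam.AlignmentHeader, records, path) -> None:
    with pysam.AlignmentFile(str(path), "w", header=header) as f:
        for rec in sorted(records, key=lambda r: (r.reference_id, r.reference_start)):
            f.write(rec)


def read_sam(path) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    with pysam.AlignmentFile(str(path), "r") as f:
        header = f.header
        records = [r for r in f]
    return header, records


# ---------------------------------------------------------------------------
# SV VCF (symbolic ALT dialect)
# ---------------------------------------------------------------------------

_SV_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=svdomest
##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive) on genome A">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length (negative for deletions)">
##INFO=<ID=AEND,Number=1,Type=Integer,Description="0-based half-open end on genome A">
##INFO=<ID=CHR2,Number=1,Type=String,Description="Chromosome on genome B">
##INFO=<ID=BSTART,Number=1,Type=Integer,Description="0-based start on genome B">
##INFO=<ID=BEND,Number=1,Type=Integer,Description="0-based half-open end on genome B">
##INFO=<ID=SOURCES,Number=.,Type=String,Description="Calling routes supporting the SV">
##ALT=<ID=DEL,Description="Deletion relative to genome A">
##ALT=<ID=INS,Description="Insertion relative to genome A">
##ALT=<ID=INV,Description="Inversion">
"""


def write_sv_vcf(svs: Sequence[SVRecord], path, contigs: Optional[dict[str, int]] = None) -> None:
    """Validated reference SV set as a symbolic-ALT VCF on genome-A coordinates."""
    lines = [_SV_VCF_HEADER]
    for chrom, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={chrom},length={length}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
    for sv in svs:
        if sv.sv_type not in _SVTYPE_TO_ALT:
            continue
        alt = _SVTYPE_TO_ALT[sv.sv_type]
        svlen = -sv.size if sv.sv_type == "deletion" else sv.size
        end = max(sv.end_a, sv.start_a + 1)  # VCF END stays >= POS
        info = (
            f"END={end};SVTYPE={alt[1:-1]};SVLEN={svlen};AEND={sv.end_a};"
            f"CHR2={sv.chrom_b};BSTART={sv.start_b};BEND={sv.end_b}"
        )
        if sv.sources:
            info += f";SOURCES={','.join(sorted(sv.sources))}"
        lines.append(
            f"{sv.chrom_a}\t{sv.start_a + 1}\t{sv.id}\tN\t{alt}\t.\tPASS\t{info}\n"
        )
    Path(path).write_text("".join(lines))


def _info(rec, key, default):
    """INFO lookup tolerant of keys absent from the header."""
    try:
        return rec.info.get(key, default)
    except (KeyError, ValueError):
        return default


def read_sv_vcf(path) -> list[SVRecord]:
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf):
            alt = (rec.alts or ("",))[0].strip("<>")
            svtype = _info(rec, "SVTYPE", alt)
            if svtype not in _ALT_TO_SVTYPE:
                raise FormatError(path, i + 1, f"unsupported ALT {alt!r}")
            sv_type = _ALT_TO_SVTYPE[svtype]
            start_a = rec.pos - 1
            svlen = abs(int(_info(rec, "SVLEN", rec.stop - start_a)))
            # AEND is exact when we wrote the file; otherwise fall back to
            # the VCF convention (htslib's stop for deletions, start+SVLEN
            # for inversions, whose symbolic records carry no padding base)
            aend = _info(rec, "AEND", None)
            if sv_type == "insertion":
                end_a = start_a
            elif aend is not None:
                end_a = int(aend)
            elif sv_type == "inversion":
                end_a = start_a + svlen
            else:
                end_a = rec.stop
            chrom_b = _info(rec, "CHR2", rec.chrom)
            start_b = int(_info(rec, "BSTART", start_a))
            end_b = int(_info(rec, "BEND", start_b if sv_type == "deletion" else start_b + svlen))
            sources = _info(rec, "SOURCES", ())
            if isinstance(sources, str):
                sources = (sources,)
            out.append(
                SVRecord(
                    id=rec.id or f"SV{i + 1:05d}",
                    sv_type=sv_type,
                    chrom_a=rec.chrom,
                    start_a=start_a,
                    end_a=end_a,
                    chrom_b=chrom_b,
                    start_b=start_b,
                    end_b=end_b,
                    size=svlen,
                    sources=frozenset(sources),
                )
            )
    return out


# ---------------------------------------------------------------------------
# genotype matrix: flat TSV and VCF
# ---------------------------------------------------------------------------


def write_genotype_tsv(matrix: GenotypeMatrix, path) -> None:
    """One row per SV, one column per accession; 0/1/2/NA coding.

    The first header line documents the coding; a second block appends the
    group label of every accession.
    """
    with open(path, "w") as f:
        f.write("# genotype coding: 0=B_HOM 1=HET 2=A_HOM NA=missing\n")
        df = matrix.calls.astype("object").where(matrix.calls.notna(), "NA")
        if matrix.positions is not None:
            df = pd.concat([matrix.positions[["chrom", "pos"]], df], axis=1)
        df.index.name = "sv"
        df.to_csv(f, sep="\t")
    Path(str(path) + ".groups").write_text(
        "accession\tgroup\n"
        + "".join(f"{a}\t{g}\n" for a, g in matrix.groups.items())
    )


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, na_values=["NA"])
    pos = None
    if "chrom" in df.columns and "pos" in df.columns:
        pos = df[["chrom", "pos"]]
        df = df.drop(columns=["chrom", "pos"])
    groups = pd.read_csv(str(path) + ".groups", sep="\t", index_col=0)["group"]
    return GenotypeMatrix(df.astype("Int8"), groups, pos)


def write_genotype_vcf(matrix: GenotypeMatrix, path, svs: Optional[Sequence[SVRecord]] = None) -> None:
    """Population genotypes as VCF; REF is the B (cultivar-reference) allele."""
    by_id = {sv.id: sv for sv in svs} if svs else {}
    acc = list(matrix.accessions)
    lines = [
        "##fileformat=VCFv4.2\n",
        "##source=svdomest\n",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype; REF is the B allele">\n',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(acc) + "\n",
    ]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    for sv_id in matrix.sv_ids:
        if sv_id in by_id:
            sv = by_id[sv_id]
            chrom, pos1 = sv.chrom_a, sv.start_a + 1
            svtype = _SVTYPE_TO_ALT.get(sv.sv_type, "<SV>")[1:-1]
        elif matrix.positions is not None:
            chrom = matrix.positions.loc[sv_id, "chrom"]
            pos1 = int(matrix.positions.loc[sv_id, "pos"]) + 1
            svtype = "SV"
        else:
            chrom, pos1, svtype = "chr1", 1, "SV"
        row = matrix.calls.loc[sv_id]
        gts = "\t".join(gt_map.get(int(v), "./.") if pd.notna(v) else "./." for v in row)
        lines.append(
            f"{chrom}\t{pos1}\t{sv_id}\tN\t<{svtype}>\t.\tPASS\tSVTYPE={svtype}\tGT\t{gts}\n"
        )
    Path(path).write_text("".join(lines))


def read_genotype_vcf(path, groups: pd.Series) -> GenotypeMatrix:
    calls: dict[str, dict[str, object]] = {}
    pos_rows = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            row = {}
            for s in samples:
                gt = rec.samples[s]["GT"]
                if gt is None or None in gt:
                    row[s] = pd.NA
                else:
                    row[s] = int(sum(gt))
            calls[rec.id] = row
            pos_rows[rec.id] = dict(chrom=rec.chrom, pos=rec.pos - 1)
    df = pd.DataFrame.from_dict(calls, orient="index").astype("Int8")
    return GenotypeMatrix(df, groups, pd.DataFrame.from_dict(pos_rows, orient="index"))


# ---------------------------------------------------------------------------
# group labels, GFF3, BED, gaps
# ---------------------------------------------------------------------------


def read_groups_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"accession", "group"} <= set(df.columns):
        raise FormatError(path, 1, "expected columns 'accession' and 'group'")
    return df.set_index("accession")["group"]


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene coordinates from GFF3: index gene id; chrom, tss, tes, strand.

    TSS/TES are internal 0-based positions; on the minus strand the TSS is
    the feature end and the TES the feature start.
    """
    rows = {}
    with open(path) as f:
        for ln, line in enumerate(f, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(path, ln, f"expected 9 GFF3 columns, got {len(parts)}")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            try:
                s1, e1 = int(start), int(end)
            except ValueError:
                raise FormatError(path, ln, "non-integer coordinates")
            gid = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gid = kv[3:]
            if gid is None:
                raise FormatError(path, ln, "gene without ID attribute")
            if strand == "-":
                tss, tes = e1 - 1, s1 - 1
            else:
                tss, tes = s1 - 1, e1 - 1
            rows[gid] = dict(chrom=chrom, tss=tss, tes=tes, strand=strand)
    return pd.DataFrame.from_dict(rows, orient="index")


def write_gff3_genes(genes: pd.DataFrame, path) -> None:
    lines = ["##gff-version 3\n"]
    for gid, g in genes.iterrows():
        strand = g.get("strand", "+")
        lo = int(min(g["tss"], g["tes"]))
        hi = int(max(g["tss"], g["tes"]))
        lines.append(
            f"{g['chrom']}\tsvdomest\tgene\t{lo + 1}\t{hi + 1}\t.\t{strand}\t.\tID={gid}\n"
        )
    Path(path).write_text("".join(lines))


def write_bed(df: pd.DataFrame, path, extra_cols: Sequence[str] = ()) -> None:
    """BED-like TSV (0-based half-open) with deterministic column order."""
    cols = ["chrom", "start", "end", *extra_cols]
    df[cols].to_csv(path, sep="\t", header=True, index=False)


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gap_bed(path) -> GapTrack:
    df = pd.read_csv(path, sep="\t")
    ivs: dict[str, list[tuple[int, int]]] = {}
    for _, r in df.iterrows():
        ivs.setdefault(r["chrom"], []).append((int(r["start"]), int(r["end"])))
    return GapTrack(ivs)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with the study defaults."""

    seed: int = 0
    gap_min_dist: int = 50
    inversion_split_frac: float = 0.9
    insertion_size_tol: float = 0.20
    deletion_gap_max: int = 3
    min_split_reads: int = 3
    min_genotyped_frac: float = 0.40
    selection_alpha: float = 1e-3
    window_size: int = 1_000_000
    window_step: int = 250_000
    introgression_ratio_max: float = 0.9
    introgression_min_svs: int = 2
    maf_min: float = 0.01
    missing_max: float = 0.40
    assoc_alphas: tuple = (0.05, 1.0)
    n_hidden_factors: int = 20
    cis_window: int = 50_000
    hotspot_window: int = 50_000
    hotspot_adj_p: float = 0.05
    block_min_svs: int = 3
    imputation: dict = field(
        default_factory=lambda: dict(w=80, k=3, p=-7.0, r=0.8)
    )

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["assoc_alphas"] = list(self.assoc_alphas)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "assoc_alphas" in d:
            d["assoc_alphas"] = tuple(d["assoc_alphas"])
        return cls(**d)


def write_truth_tsv(truth, prefix) -> None:
    prefix = Path(prefix)
    truth.svs.to_csv(f"{prefix}.svs.tsv", sep="\t", index=False)
    truth.snps.to_csv(f"{prefix}.snps.tsv", sep="\t", index=False)
    if truth.introgressions is not None:
        truth.introgressions.to_csv(f"{prefix}.introgressions.tsv", sep="\t", index=False)
    if truth.eqtl_effects is not None:
        truth.eqtl_effects.to_csv(f"{prefix}.eqtl_effects.tsv", sep="\t", index=False)


def write_expression_tsv(expr, path) -> None:
    expr.values.to_csv(path, sep="\t")


def read_expression_tsv(path, genes: Optional[pd.DataFrame] = None, stage: str = "raw_fpkm"):
    from .eqtl import ExpressionMatrix

    values = pd.read_csv(path, sep="\t", index_col=0)
    g = genes if genes is not None else pd.DataFrame(index=values.index)
    return ExpressionMatrix(values=values, genes=g, stage=stage)
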