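# svdomest

Structural-variant (SV) population analysis for a two-reference crop
domestication design, modelled on wild tomato (*Solanum pimpinellifolium*,
the "A" reference) versus cultivated tomato (the "B" reference).  The
package takes a pair of assembled genomes, candidate SV calls, short-read
alignment evidence, accession group labels and fruit expression data, and
produces:

- a validated, merged **reference SV set** (gap filtering, flank-anchor
  validation, split-read confirmation of inversions, repeat-call
  conversion, 50% reciprocal-overlap merging of genome-comparison and
  read-mapping calls);
- **population SV genotypes** called per accession from split-read counts
  and read-depth fractions around breakpoints on both reference genomes
  (≥3 split reads per supported allele; depth rule: <50% of the variable
  region covered at 2× with >50% of a flank covered; accessions with <40%
  of SVs genotyped excluded);
- **selection scans** across domestication stages (wild SP → SLC →
  heirloom → modern) using two-tailed Fisher's exact tests on allele
  counts with Bonferroni control (corrected *P* < 0.001), windowed
  nucleotide diversity π and Weir–Cockerham *F*<sub>ST</sub> (1000-kb
  windows, 250-kb step), and an **introgression scan** based on
  genotype-sharing ratios (windows with mean ratio ≤ 0.9 and ≥ 2 SVs);
- **eQTL mapping**: FPKM normalization, quantile-normal transform, hidden
  expression factors, Balding–Nichols kinship, KNN genotype imputation
  (*w* = 80, *k* = 3, *p* = −7, *r* = 0.8), an EMMAX-style mixed-model
  scan, LD-guided eQTL blocks (r² above background, ≥3 SVs), 50-kb
  cis/trans classification, trans-eQTL hotspot detection (50-kb windows,
  adjusted *P* < 0.05) and iGA-style master-regulator ranking.

A first-class **synthetic-data module** generates every input with a
machine-readable truth set — toy genome pairs with planted SVs and SNPs,
four-stage populations with drift, sweeps and introgressed wild blocks,
pre-aligned read evidence (SAM with SA-tagged split reads), and expression
matrices with planted cis effects and a regulator-driven trans hotspot —
so the whole pipeline runs and is tested without any download.

## The model in brief

For an SV locus with alleles A (wild reference) and B (cultivar
reference), the A-allele count in a group of accessions is
2·n(A/A) + n(A/B).  Selection between stages is tested on the 2×2 allele
count table by Fisher's exact test; Bonferroni correction uses the number
of SVs tested in that stage pair.  For expression trait *y* the
association model is the two-step mixed model

y = Xβ + Cγ + u + ε,  u ~ N(0, σ²_g K),  ε ~ N(0, σ²_e I)

with *K* the frequency-standardized (Balding–Nichols) kinship, *C* the
intercept plus 20 hidden expression factors, variance components fit once
per gene by REML and every SV *X* then tested by generalized least
squares.  Blocks chain adjacent associated SVs with r² above the
genome-wide LD background and distance below the background decay length.

## Worked example

```bash
svdomest all --out demo --seed 3
```

writes a synthetic dataset (genomes as FASTA, SVs as symbolic-ALT VCF,
genotypes as a 0/1/2/NA matrix, expression TSV plus GFF3 gene models,
truth tables) and runs every analysis stage on it. On the small default
configuration this prints, among other lines:

```
wrote synthetic dataset to demo
population statistics -> demo/popgen
20 introgression windows -> demo/introgressions.bed
0 eQTL blocks (0 cis) -> demo/eqtl
```

`demo/popgen/selection_SP_SLC.tsv` holds one row per SV with the raw and
Bonferroni-corrected Fisher *P* and the `selected` flag; the generator's
default wild→cultivated frequency collapse makes most loci significant,
e.g. `SV00001  p_raw 3.6e-10  p_corrected 1.5e-08  direction A_down
selected True` — the wild allele fell between SP and SLC.  The 20
introgression windows are chance wild-like stretches in this tiny panel
(42 SVs); no eQTL block forms because blocks need ≥3 associated SVs in
local LD, which this demo is too small to produce.  The full-scale
behaviour (150 accessions, 3,600 SVs, 300 genes) is exercised by the
acceptance script below.  The eQTL stage writes blocks with their lead
SV, lead *P* and cis/trans class to `demo/eqtl/blocks.tsv`.

The Python API mirrors the stages (`svdomest.simulate`,
`svdomest.validation`, `svdomest.genotyping`, `svdomest.popgen`,
`svdomest.eqtl`, `svdomest.io`); see the module docstrings.

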