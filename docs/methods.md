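# Methods

This note documents the statistical methods implemented in `svdomest`,
the assumptions of the synthetic-data generator, the numerical choices,
and the design decisions taken where the underlying procedures left room.

## Coordinates, alleles, genotype coding

All internal coordinates are 0-based half-open; SAM/VCF/GFF3 are converted
at the I/O boundary (VCF POS = start + 1; a deletion record with
`END=1501;SVLEN=-500` at POS 1001 becomes the internal interval
[1000, 1501)).  "A" denotes the wild-reference allele and "B" the
cultivar-reference allele.  Genotypes are coded as A-allele dosages
0/1/2 with NA for undetermined; genotype VCF output uses REF = B, so 0/0
is the cultivar homozygote.

## Reference SV validation

Candidates from genome comparison and from long-read mapping pass, in
order: a gap filter (drop SVs spanning or within 50 bp of an assembly gap
on either genome); inversion confirmation (split reads >90% of
breakpoint-spanning reads at every covered breakpoint, or detection by
both read-mapping callers); conversion of repeat/tandem
expansion–contraction calls into the precise read-mapping indels they
contain (calls without a precise match are dropped); flank-anchor
validation of indels (both 5-kb flanks hit the query genome with
alignment length >50 bp, identity >90%, e-value <1e−10 inside the
expected region; insertions require |hit distance − size estimate| <20%
of the estimate, deletions a flank gap/overlap <3 bp); and merging of the
two routes by >50% reciprocal overlap.

Decisions where the procedure is under-specified:

- *Expected query region* for flank hits: within 2 × estimated SV size
  + 10 kb of the position projected onto the query genome.
- *Insertions* have a degenerate interval on genome A, so reciprocal
  overlap is undefined; they merge on breakpoint distance ≤ 100 bp plus
  size ratio > 0.5.
- *Ties* (one record overlapping two partners) resolve to the larger
  reciprocal overlap, then the leftmost start, making the merge
  deterministic and idempotent.
- The built-in exact-substring flank anchorer is for toy genomes only;
  real data should supply BLAST-style hit tables.

## SV genotyping

Evidence per SV per accession is summarised on the *carrier* genome (the
reference containing the variable segment: A for deletions and
inversions, B for insertions): junction (SA-tagged) reads within ±10 bp
of a breakpoint, contiguous spanning reads, and the fraction of the
variable region covered at ≥2× together with two equal-length flanks.
Split reads on the carrier genome support the segment-absent allele;
split reads on the other genome, and spanning/depth evidence on the
carrier, support the segment-present allele.  An allele is supported by
≥3 split reads at a breakpoint or — for the absent allele — by the depth
rule (<50% of the region covered at 2× and >50% of a flank covered); the
present allele alternatively by >50% coverage with ≥3 spanning reads.
Both alleles supported → heterozygous; one → that homozygote; none →
missing.  Inversions use split-read evidence only and require the
threshold at *every* breakpoint.  Alignments with more than 3% mismatches
(NM tag) are ignored.  The ±10 bp junction tolerance absorbs alignment
jitter; the HET rule (split criterion for one allele plus spanning/depth
for the other) makes the heterozygous outcome explicit.  Matrix assembly
never alters calls; it only drops accessions genotyped at fewer than 40%
of SVs (strictly less — 40% exactly is retained).

## Population analyses

Allele counts per group are 2·hom + het over non-missing calls.  The
selection scan applies the two-tailed Fisher exact test (sum of
probabilities of all tables with the observed margins not exceeding the
observed table's probability — verified exactly against a brute-force
hypergeometric enumeration) per stage pair, Bonferroni-corrected by the
number of SVs tested in that pair (overridable), with corrected
*P* < 0.001 defining selection.  π uses per-site 2p(1−p)·n/(n−1) summed
over a window and divided by the window length; *F*<sub>ST</sub> is the
Weir–Cockerham two-population estimator aggregated per window as a ratio
of averages, reported unclipped (negative values possible).  Windows are
1000 kb with a 250-kb step.

The introgression scan computes, per focal accession and SV, the ratio of
the genotype-sharing percentage in the accession's own group (excluding
the accession itself) to that in the wild donor group; sharing is an
exact state match (HET matches only HET) and missing calls enter neither
side.  Sites with zero donor sharing are skipped.  Windows with mean
ratio ≤ 0.9 containing ≥ 2 SVs are reported.

## eQTL stage

Expression processing: FPKM = count·10⁹/(gene length · library
fragments); genes with median FPKM 0 dropped; accessions beyond 2.5 SD on
any of the first three principal components dropped; per-gene
quantile-normal transform (mid-rank ties, ranks mapped through
Φ⁻¹(r/(n+1))).  Hidden expression factors are the leading principal
components of the transformed matrix (default 20), standing in for PEER
factors: they play the same covariate role at desk scale, while PEER's
variational inference is out of scope.  Kinship is the
frequency-standardized dosage similarity Z Zᵀ/m with
z = (g − 2p)/√(2p(1−p)) (the Balding–Nichols construction), mean-imputing
missing dosages per site; it is symmetric and PSD by construction.

KNN imputation fills a missing dosage from the k = 3 nearest accessions,
with distances computed as mean squared dosage differences over a window
of w = 80 consecutive sites, weights distance^p with p = −7, and the fill
applied only when the top vote's weight share reaches r = 0.8; the
masking experiment (mask 10–30% of called cells, impute, compare)
measures filling rate and accuracy.  Sites left missing after KNN are
mean-imputed for the scan.

The association model is the EMMAX-style two-step mixed model: per gene,
REML on the covariate-only model profiles δ = σ²_e/σ²_g on the kinship
eigenbasis (grid over log₁₀δ ∈ [−5, 5] then bounded refinement); each SV
is then tested by GLS, implemented with a shared rotated dosage matrix
and Frisch–Waugh–Lovell projection so the per-gene cost is a few
matrix-vector products.  With identity kinship the procedure reduces
exactly to OLS.  SVs enter the scan with minor allele frequency ≥ 1% and
missing rate ≤ 40%.

LD background: pairwise r² within 10 Mb binned by distance; the
background level is the mean r² over the plateau (bins where the smoothed
decay slope falls below 1% of its initial magnitude) and the background
distance is where the smoothed curve first comes within 5% of its total
drop of that level; when no plateau exists the last bin is used with a
warning.

Blocks chain position-adjacent associated SVs when r² exceeds the LD
background and distance is below the background decay length; chains need
≥ 3 members.  Membership uses the suggestive threshold (Bonferroni at
α = 1) while the block's lead SV must pass the significant threshold
(α = 0.05) — the two-tier convention of reporting suggestive support
around a significant lead.  The lead SV is the smallest-p member
(leftmost on ties); a block is cis when the lead lies within 50 kb of the
gene's TSS or TES on the same chromosome, else trans; the partition is
exhaustive.  Chaining is adjacent-only, and cis distance is measured from
the lead SV (both parameterizable).

Hotspots: sliding 50-kb windows (10-kb step) are scored by the number of
distinct genes whose trans lead SV falls inside; one-sided Poisson tail
p-values against the genome-wide mean density are Benjamini–Hochberg
adjusted across windows; significant overlapping windows merge.  This
Poisson clustering test is a documented stand-in for the hot_scan tool,
whose internals are not published.  The master regulator of a hotspot is
ranked by an iterative-group (iGA) criterion: for each expressed gene in
(or within 50 kb of) the hotspot window, all other genes are ranked by
absolute Pearson correlation with the candidate and the minimal
hypergeometric prefix p of the hotspot's target genes near the top of
that ranking is taken; candidates are ordered by that p.  The pipeline
computes these correlations on the covariate-adjusted expression (hidden
factors projected out, the same adjustment the association scan uses):
shared hidden factors otherwise lend every gene a baseline correlation
with every other, letting an unrelated window gene occasionally outscore
the true regulator.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume,
with defaults fixed to the study design it targets:

- **Genome pair**: random chromosomes; non-overlapping planted deletions,
  insertions and inversions with log-uniform sizes (≥ 10 bp floor); SNP
  substitutions outside SV intervals; genome B derived from A with both
  coordinate systems recorded in the truth set.
- **Population**: four stage groups (SP, SLC, heirloom, modern) with
  default sizes (51, 228, 226, 52).  Per-locus wild A-allele frequencies
  are marginally uniform on (0.2, 0.95) but spatially autocorrelated
  along the chromosome (nearby variants share genealogy and hence similar
  frequencies); stage scaling (1, 0.27, 0.08, 0.11) plus Gaussian drift
  (SD 0.03) reproduces the wild→cultivated collapse of wild-allele
  frequency; a drift-only population uses unit scaling.  Haplotypes are
  drawn through a Gaussian-copula AR(1) process along each chromosome
  (decay length 1.5 Mb) so nearby loci are in LD while marginal
  frequencies are exact; partial selfing is modelled as a 0.8 probability
  that an accession's two haplotypes are identical.  Selected loci are
  forced to their target frequencies; fixation targets are deterministic.
  Introgression blocks copy the genotypes of a wild accession into chosen
  cultivated accessions over an interval; the donor is drawn from the SP
  accessions richest in wild alleles over the block, since introgressions
  retained through breeding carry the wild haplotype that made them worth
  introgressing.
- **Read evidence**: reads are sampled from the accession's two haplotype
  copies at the configured depth and aligned *by construction* to both
  references; reads crossing a junction absent from a reference become
  SA-tagged split alignments (≥ 20 bp anchors), reads inside a segment
  missing from a reference are soft-clipped or unmapped there.  One SAM
  holds both coordinate systems via `A_`/`B_` reference-name prefixes.
  No sequencing-error model is included.
- **Expression**: gene scores are baseline + Σβ·dosage + trans effects +
  Gaussian noise, on the scale of quantile-normalized data.  The
  regulator's *biological* expression (genetic + intrinsic noise) drives
  its targets; 30 global hidden confounders with geometrically decaying
  loadings are then added to every gene's *measurement* — they are what
  the hidden-factor covariates exist to absorb, and without them a small
  panel's only shared covariance would be the regulatory module itself,
  which the factor correction would then remove.  Cis genes are placed
  within 50 kb of their causal SV; trans targets away from the regulator
  locus.  Effect SVs are drawn from loci polymorphic *within* at least
  two groups (within-group MAF ≥ 0.1): in a structured panel these are
  the loci at which an association design has power, because their
  dosage variation is not collinear with kinship.

What the generator does **not** emulate: sequencing errors and mapping
ambiguity, multi-allelic or nested SVs, pedigree structure beyond the
copula (no recombination maps or explicit coalescent), realistic FPKM
count noise (expression is generated directly on the transformed scale),
and tissue-specific expression.  Passing recovery batteries therefore
demonstrates the correctness and calibration of the decision rules and
models under the assumed evidence structure, not robustness to real-data
artefacts.

## Evaluation batteries and problem sizes

The batteries in `svdomest.evaluation` rerun a full stage against planted
truth; the suite and the acceptance script call the same code.

- *Fisher oracle*: every 2×2 table with row margins ≤ 30 (246,016
  tables), exact agreement to 1e−12.
- *Genotyping*: one 200-kb chromosome with 26 SVs (100–2000 bp); 200
  SV×accession cases at 15× depth; accuracy ≥ 0.95 and the depth→0 limit
  all-missing.  Concordance between two independent evidence replicates
  of 100 cases at 20×.
- *Validation*: 32 planted SVs plus 10 decoy calls with ±5 bp jitter;
  recall and false-record count after the full pipeline.
- *Selection*: 1,000 loci, 100 accessions per group, drift-only
  background, 20 sweeps planted at (0.6, 0.05, 0.05, 0.05); power on the
  SP→SLC pair and the null false-positive rate.
- *Introgression*: 600 loci on 2 × 10 Mb, three planted donor blocks
  (2–2.5 Mb) in heirloom/modern accessions; background LD length 300 kb
  so the planted blocks are the only megabase-scale wild segments;
  window-level recall (windows fully inside a block) and precision
  (overlap with the accession's block).
- *eQTL*: 150 accessions, 3,600 SVs on 2 × 20 Mb (≈ 90 SVs/Mb), 300
  genes, 20 cis effects (β = 1.5, noise SD 1) plus one hotspot (regulator
  cis β = 2, 8 targets at β = 1.5); cis recovery = fraction of planted
  effects returned as cis blocks containing the causal SV; the hotspot
  battery repeats the full stage over 20 seeds and scores detection with
  the regulator ranked first.
- *Mixed model*: identity-kinship equivalence with OLS on 50 SVs, and the
  pooled type-I fraction of 10 null traits × ~1,000 structured SVs.

## Known limitations

Fisher tests loop per locus (exact tests dominate; fine to ~10⁵ loci).
KNN imputation is windowed but per-site; very large matrices should batch
it.  The hotspot test assumes a homogeneous Poisson null; strongly
varying SV density would need a locally-adjusted rate.  The LD plateau
detector falls back (with a warning) to the last distance bin on panels
whose LD never levels off within the scan range.
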