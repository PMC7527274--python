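# Methods

## Study design being emulated

The pipeline targets the situation of a highly heterozygous, clonally
propagated diploid whose assembly must be phased without trios: the
individual is selfed, a few hundred S1 (≡ F2) progeny are sequenced at ~1×,
and scaffolds are assigned to haplotypes from the co-segregation of their
read counts.  The synthetic-data generator reproduces that design at desk
scale; every analysis stage is then validated as a parameter-recovery
experiment against the generator's truth.

## The simulator

**Genome.** Each of `n_chromosomes` (default 2) chromosome pairs starts as
a random ACGT sequence of `chrom_length` (default 2 Mb).  Single-exon genes
(ATG + 98–398 random sense codons + TAA, so open reading frames are valid)
are planted at near-regular spacing (default 100 per chromosome).
Haplotype 2 is derived by an explicit edit script: SNPs at `snp_rate`
(default 0.015/bp, anywhere including CDS), indels at `indel_rate` (default
0.0017/bp, geometric lengths capped at 50 bp), `sv_count` SVs per
chromosome (51–2000 bp, default 3) and PAV events for
`pav_gene_fraction` of genes (default 2.5%; half deleted from haplotype 2,
half inserted as haplotype-2-only genes).  Indels and SVs avoid gene bodies
so that allelic CDSs differ by SNPs only; CDS indels are exercised directly
in the effect-classifier tests.  With these defaults the planted divergence
(SNPs + indel/SV bases over aligned bases) is ~2.1%, the regime the method
is meant for.  A coordinate map built from the edit script provides exact
haplotype-1 ↔ haplotype-2 position translation for all truth bookkeeping.

**Population.** Each progeny is the fusion of two independent parental
gametes.  Crossovers per gamete per chromosome are Poisson with mean
`map_length_morgans` (default 1; the true genetic map length is unknown and
this is an explicit free parameter), placed uniformly — no interference.
Lethal loci discard and redraw any progeny homozygous for the carrier
haplotype; vigor loci let such progeny survive with probability
`viability`.  A rejection-rate guard raises if the configuration makes the
population unattainable.

**Scaffolds and counts.** Cut points with log-normal spacing (length-biased
median = `scaffold_n50`) are placed jointly on both haplotypes (haplotype-2
positions via the coordinate map), partitioning each haplotype exactly, so
scaffold lengths always sum to the genome length.  With probability
`chimera_rate` an eligible homologous interval pair is cross-joined into
two chimeric scaffolds that switch haplotype at a shared junction; the
junction sits on the scaffold's `window_size` grid because the detector —
which scans fixed windows, following the windowed strategy the pipeline
implements — can only resolve breakpoints at window boundaries.  Counts are
Poisson: `c ~ Poisson(T_p · Σ_parts len·d/(2G))`, with per-progeny library
sizes log-normal around `coverage · G / read_length` (CV 0.1).  Scaffolds
at least two windows long also carry per-window counts whose sum is the
scaffold count, the substrate for chimera detection.

**Expression.** Per allelic pair, a log-normal gene mean (around
`expr_mean` = 200 fragments) with log-normal tissue effects; negative
binomial counts per replicate with size `expr_dispersion` = 5000, i.e.
near-Poisson.  That default matters: the allelic test is an exact binomial
on summed counts, which is calibrated when count noise is at the sampling
level.  Strong extra-Poisson biological noise (size ~20) would make any
binomial allelic test anticonservative — a caveat that applies to real data
too and is why passing type-I control here demonstrates calibration of the
statistic, not robustness to arbitrary overdispersion.  A `del_fraction`
(default 0.166) of pairs get one allele's mean multiplied by
`del_fold_change` (default 4).  TPM is computed from counts and transcript
lengths per (tissue, replicate) library.

**Methylation.** Sites are a random sample of cytosines per chromosome
(default 2000) plus *every* cytosine inside planted DMRs — site-level
truth where it matters without simulating 25% of the genome.  Baseline
methylation by context (CG 0.85, CHG 0.55, CHH 0.10, plant-like) with small
shared site-level jitter; inside each of `dmr_count` gene-centred DMRs the
two haplotypes are pushed to 0.9/0.1 (CG, CHG) or 0.5/0.05 (CHH), well past
the calling thresholds.  Depth is Poisson(30) per replicate; methylated
counts are binomial.  What the generator does **not** model: bisulfite
conversion failure, mapping bias between haplotypes, copy-number effects on
depth — so passing tests show the caller's statistics work, not that those
artefacts are handled.

## Analysis choices

**Dosage calling.** The count→genotype transformation is a Poisson ML
choice over d ∈ {0,1,2} with λ_d = (d/2)·L·T/G.  A call requires the
best-vs-second log-likelihood ratio ≥ ln 3 and λ₂ ≥ 1; anything else is
explicitly missing (never dosage 0).  The continuous normalised matrix is
retained alongside the discrete calls.

**Phasing.** Pairwise-complete Pearson correlation of dosage vectors
(pairs with < 30 shared progeny, or zero variance, are undefined — NaN by
contract, never propagated).  Linkage groups are connected components of
the |r| ≥ 0.7 graph; both haplotypes of a chromosome co-cluster through
anti-correlation edges.  Ward clustering at k = 2 on d = (1 − r)/2 splits
each group; correlation-derived distance is robust to missing-data scaling
where raw Euclidean is not.  Haplotype labels are arbitrary per group — an
F2 of one parent carries no cross-chromosome phase information — and all
accuracy metrics apply per-group optimal label matching.  Rescue assigns a
leftover scaffold only when its top two correlations with phased scaffolds
both exceed 0.7 and agree on (group, haplotype); rescued scaffolds never
displace clustered ones.  "Contrary read distribution" between adjacent
windows is quantified as window-dosage correlation < −0.5 (the threshold is
configurable; the source strategy names no number), and scaffolds are
broken at the shared boundary.  Ordering/orientation of scaffolds within a
haplotype is out of scope; output is unordered group membership.

**SD scan.** Windows (default 300 kb) are genotyped as markers by
length-weighted majority over member scaffolds (haplotype-2 members
flipped, ties missing), then tested χ² against 1:2:1 (df 2, untestable
below n = 20, distorted at P < 0.001; the statistic is invariant to the
n0 ↔ n2 label swap).  Recessive exclusion flags distorted windows whose
minor homozygote count is ≤ ε·n.  ε is 0.01 (genotyping error) plus a
recombination allowance (2/3)·r(w/2), with r the Haldane recombination
fraction and w the window's genetic width in Morgans, when that width is
known: a lethal locus can sit anywhere in its window, so the window
consensus is up to w/2 away, and at desk scale — a 300-kb window spanning
15 cM — surviving heterozygotes recombine into apparent carrier homozygotes
at a few percent.  On a realistic dense map the allowance vanishes, and it
always stays far below the ~25% minor-homozygote share of a neutral window,
so it cannot create false flags.

**Synteny and variants.** Homologs are screened by pairwise CDS alignment
(affine scoring 1/−2/−4/−1, end gaps free; an edit-distance prefilter skips
hopeless pairs) at coverage > 0.75 and identity > 0.75.  Anchors are
chained by dynamic programming (strictly collinear per orientation, ≤ 25
intervening genes, ≥ 5 anchors — common collinearity practice; the screening
criteria themselves are fixed), then blocks are screened: homologous
chromosomes, ≤ 3× length ratio, and anchor span > 50% of the block's
territory, where territory extends halfway toward neighbouring blocks (one
typical anchor spacing at chromosome edges) — the denominator had to be
defined, since a block trivially covers its own anchor span.  Variant
calling splits each block at anchor-gene midpoints (homologous positions on
both haplotypes, unlike midpoints *between* anchors, which drift across
indels), aligns segment pairs with edlib (unit-cost edit path; an O(nm)
affine DP is impractical at 10–100 kb), coalesces difference runs separated
by < 10 matched bases — a unit-cost path smears long novel indels into
co-optimal 1-bp fragments, and a 10-bp chance match inside random sequence
has probability 4⁻¹⁰ — and re-aligns each small region core with the affine
aligner to place the net gap correctly.  Indels are left-aligned;
insertions and deletions swap roles exactly under haplotype exchange.
Classes: SNP, indel 1–50 bp, SV > 50 bp.  Inverted blocks are chained and
reported but not base-aligned (known limitation).  Diversity =
(SNP count + indel/SV bases)/alignment columns × 100; whether indels count
as events or bases was an open reading, and bases were chosen so the
statistic measures divergent sequence content.

**Effects.** Both CDSs are translated (standard code); precedence
frameshift (net indel ≢ 0 mod 3) > premature stop > in-frame indel
(residues = length/3) > missense (residues = differing positions) >
synonymous > identical.  An internal stop in the reference allele flags the
pair pseudogene-like without suppressing the call.

**DEL.** "< 30% variance across replicates" is interpreted as coefficient
of variation < 0.30 — raw variance in TPM² units is scale-dependent and
cannot be a percentage.  The binomial test runs on rounded summed estimated
counts, never TPM (TPM has no sampling model).  Per-tissue BH at FDR 0.05
(configurable, including "none" for raw p < 0.05); a pair is DEL if
significant in ≥ 1 tissue.  Whether testing is per tissue or pooled was
open; per-tissue with ≥ 1-tissue aggregation is implemented and both levels
are reported.

**Methylation.** Sites are paired across haplotypes through the block
coordinate map — exact (per-base, from the indel offsets in the variant
calls) when variants are available, anchor-interpolated otherwise; sites
inside indel gaps are unpaired.  The DMP thresholds are printed in the
source method as "difference of < 0.4/0.2/0.1", which would select
*near-identical* sites; they are implemented as |difference| ≥ threshold,
the direction that screens differential sites.  This interpretation is
flagged, not asserted as the original intent.  A DMP must pass depth ≥ 5,
threshold and Fisher P < 0.01 in **every** replicate with consistent
direction.  The Fisher p-value is computed by direct hypergeometric
enumeration (scipy's independent implementation is the test oracle).  DMPs
of the same context and hypermethylated haplotype with gaps < 100 bp are
collapsed; ≥ 2 DMPs make a DMR (a single position is not a region;
configurable).  Gene association uses body ± 2 kb, the standard
promoter-proximal flank, since the original assignment rule is unstated.

## Problem sizes

Default experiment scales, chosen to exercise the study design with
comfortable statistical margins: phasing on 2 chromosomes × 2 Mb with 200
progeny (~850 scaffolds); chimera detection on 12 × 4 Mb with N50 400 kb at
a 5% chimera rate (a handful of planted junctions per run, re-rolled
deterministically if a seed yields fewer than 3); SD calibration over 10
neutral + 10 lethal-locus simulations (≥ 200 neutral windows); divergence,
DEL and DMR recovery on the default genome.  The full suite and the
reproduction script each run in a few minutes on one CPU.

## Known limitations

* Base-level variant calling covers collinear (forward) blocks only.
* The chimera model joins exactly two homologous segments with a junction
  on the window grid; off-grid junctions would be located only to ±1
  window, which is also the detector's stated resolution.
* No sequencing-error or mapping-bias model; mapping-quality filtering is
  abstracted into the count rate.
* Scaffold ordering within haplotypes, Hi-C scaffolding, read-level
  simulation, deleterious-substitution (conservation-based) prediction and
  QTL interval mapping are out of scope.
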