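# Methods

This note documents the models, conventions and numerical choices behind
`teiscope`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or the acceptance script
does not itself compute.

## The translatome enrichment index

For gene *g* in tissue *t*, TEI(g,t) = FPKM_TRAP(g,t) / FPKM_mRNA(g,t).
Both FPKMs are taken as given (the package does not estimate abundances
from alignments). Conventions:

- A gene is **transcribed** when FPKM_mRNA ≥ 1 and **translated** when
  FPKM_TRAP ≥ 1, both boundaries inclusive. The threshold (default 1) is a
  `PipelineConfig` field and appears in the run manifest.
- TEI is **undefined (NA)** when FPKM_mRNA < 1: a ratio over a
  sub-threshold denominator is dominated by sampling noise. A gene with
  TRAP ≥ 1 but mRNA < 1 still counts as translated in summary tables but
  contributes no TEI.
- TEI is held at full precision internally and rounded to two decimals
  only in written reports.
- Gene-level analyses use the representative (first) isoform of each gene;
  isoform-resolved tables are required by, and only by, the SI/RI module —
  gene-level FPKMs are never apportioned to isoforms, because any
  apportioning rule would be invented biology.

Translatome summary tables report, per gene set and tissue, the counts and
percentages of transcribed and translated genes (percentage of the set
size) and their overlap (percentage of the transcribed count); the union
column counts genes meeting each criterion in at least one tissue.
Percentages are 100·count/denominator rounded to two decimals, 0.00 on
empty denominators.

## Transposon validation by mask coverage

Candidate transposon cDNAs are masked against a repeat library with exact,
ungapped matching: every maximal common substring of length ≥ `min_match`
(default 50 bp) between the cDNA and a library sequence or its reverse
complement contributes a masked interval; intervals are merged before the
covered fraction is computed, and a cDNA with ≥ 50% of its length masked
(boundary inclusive) is validated as a transposon gene.

The matcher is k-mer anchoring with k = `min_match`. Because every length-k
window inside a maximal common run is itself a seed hit, grouping seed hits
by alignment diagonal and merging consecutive positions recovers maximal
matches *exactly* — no heuristic extension, and provable equivalence with
the brute-force all-diagonal scan, which the tests assert on random
fixtures. Exact matching (rather than alignment-based repeat masking) is a
deliberate simplification: the pipeline's scientific content is the
coverage-fraction filter, and the ≥50% rule is agnostic to how intervals
were found. Consequences: diverged repeat copies with no exact 50-mer are
missed, so measured fractions are a lower bound on alignment-based masking.

## Stratified TEI comparisons

Genes are partitioned by one feature per scheme; bins are left-closed,
right-open, terminal bin unbounded above:

- CDS length: edges 500/800/1100/1400/1700 bp (configurable);
- CDS GC: edges 50/60/70%;
- 5′UTR length: edges 100/200/400 bp; 3′UTR length: 200/400/600 bp;
- expression breadth: 1–7, 8–14, 15 of 15 samples;
- expression abundance: six per-dataset sextile cuts within FPKM ≥ 1
  (edges depend on the input and are recorded on the result object).

All bin pairs are compared with the two-sample Kolmogorov–Smirnov test
(asymptotic p-values by default; exact small-sample computation behind a
flag) and BH-adjusted within the scheme — one scheme is one multiplicity
family. Empty bins are retained in summaries with n = 0 but excluded from
testing. Top-1% TEI trimming exists for reports only and is never applied
before a test. The UTR analysis first drops genes with a 5′UTR < 20 bp or a
3′UTR < 110 bp (these minima mark where UTR annotations become unreliable),
then summarises TEI across UTR-length bins within each CDS-length group,
flagging the 200-bp and 400-bp 5′UTR thresholds. Quadratic trends
(TEI vs abundance group, TEI vs 3′UTR length) are ordinary least squares of
y = a + bx + cx² with the t-test p-value on c; an exactly-fit design
(zero residual) returns p = 1 for c ≈ 0 and p = 0 otherwise rather than a
0/0 t-statistic.

## SI/RI isoform analysis

Two isoforms of a gene form an SI/RI pair when the RI isoform's exonic
region equals the SI isoform's plus exactly one of the SI isoform's
introns; combinations differing by two or more introns are logged and not
paired. The retained intron is classified by projecting it onto the SI
isoform's three contiguous genomic regions (transcript span cut at the
genomic CDS boundaries, strand-aware); the region with the largest base
overlap wins, ties break toward CDS. Intron GC is computed on the genomic
intron sequence. Per region, SI and RI medians of mRNA FPKM, TRAP FPKM and
TEI are reported with KS tests on TRAP FPKM and TEI, BH-adjusted across the
three regions per metric. GO enrichment of pair genes against a background
uses a 2×2 Pearson chi-square per term (no continuity correction); tables
with an expected cell below 5 are computed anyway and flagged.

## Codon usage of TEI extremes

The low class is TEI < 0.2 (exclusive) and the high class TEI ≥ 3.0
(inclusive). Codon counts accumulate over in-frame CDS (frame violations
excluded with a log; N-containing codons skipped and tallied; RNA input
normalised to DNA). Within-family frequencies normalise each amino acid's
synonymous codons to 1. Comparison: per multi-codon family (18 families;
stop codons tabulated but never tested), a chi-square on the low-vs-high
count contingency with codons unobserved in both classes dropped; BH
across the 18 families. Designated codon-pair ratios default to the four
synonymous pairs differing only at the first position (CTA/TTA, CTG/TTG,
CGA/AGA, CGG/AGG) and a configurable third-position set (CCG/CCC, CTG/CTC,
GCG/GCC, ACG/ACC). GC3 is the G+C fraction at third codon positions,
N-sites excluded from numerator and denominator.

## Lineage and GO aggregation

Lineages are assigned from ortholog-cluster species content down a nested
ladder: *all-angiosperm* clusters span ≥1 monocot, ≥1 dicot and the basal
angiosperm; *monocot+dicot* lacks the basal angiosperm;
*monocot-restricted* clusters are monocot-only with at least one
non-Poaceae monocot; *Poaceae-restricted* clusters are Poaceae-only;
*species-specific* genes are focal-only or unclustered. "Conserved in all
angiosperms" is read as clade span (basal + both major clades), not
presence in every proteome — requiring all 13 species would leave the class
nearly empty under any realistic clustering. Transposon-validated genes are
never assigned a lineage. Per-lineage TEI gets a Gaussian KDE on a fixed
grid (Scott's rule bandwidth by default; the source data name none).

Per-GO-term summaries average TEI (and companion features) over terms with
≥ 40 genes, sorted by mean TEI descending, ties by gene count then term
id. Cross-dataset comparison reports, per shared term, the difference of
means and %variation = 100·|mean_a − mean_b| / min(mean_a, mean_b)
(undefined when the smaller mean is ≤ 0), plus top-10/bottom-10 term-set
overlaps. Restricting both gene universes to matched ortholog sets is the
caller's responsibility.

## Recombination binning

Marker maps (chrom, bp, cM; cM clipped to monotone with a warning if
violated) are cut into nominal 1-Mb bins from the first to the last marker
of each chromosome; a bin enclosing no marker is merged forward until it
encloses one, so marker deserts produce bins longer than 1 Mb. cM at bin
edges comes from linear interpolation between flanking markers, which makes
rate·span exactly additive: the bins conserve each chromosome's total map
length to floating-point precision (asserted at 1e-9 cM). Genes are paired
with the rate of the bin containing their midpoint (half-open; final bin
closed above), and gene-level Pearson correlations of rate vs CDS GC and
rate vs TEI are reported; a per-bin pairing is available by aggregating
beforehand. Chromosomes with fewer than two markers are skipped.

## The synthetic-data generator

The generator emulates the statistical structure of the real study — three
tissues, paired assays, and feature-dependent translatome enrichment — with
fully known ground truth.

**Gene models.** Default n = 2000 genes on 4 chromosomes, random strand,
random intergenic spacers. CDS length is log-normal (median 1095 bp, ln-σ
0.49, matching the reported median and mean/median ratio), rounded to a
codon multiple, regenerated below 9 bp; 5′UTR log-normal (median 147 bp,
ln-σ 0.87); 3′UTR (median 354 bp, ln-σ 0.63). CDS GC is a two-mode normal
mixture (means 0.45/0.66, low-mode weight 0.55, per-mode sd 0.11, clipped
to [0.33, 0.86]) emulating the bimodal 40–75% GC of grass coding
sequences. The per-mode sd realises the package's recovery requirement
that the four GC classes remain distinguishable in TEI at n = 2000: with a
much narrower spread, the two upper GC bins both fall inside the high mode
and adjacent-bin contrasts lose power. CDS sequences start ATG, end in a
stop, avoid internal stops, and place the GC deviation from 0.5
preferentially at third codon positions (third-position deviation = 2× the
first/second-position deviation by default), creating realistic GC3–GC
coupling. A configurable fraction of genes (default 0.15) carries a second
isoform retaining one intron, placed uniformly among the feasible regions;
intron sequences are GT…AG with GC one offset (default 0.10) below the host
region.

**Expression.** Per tissue, mRNA FPKM is i.i.d. log-normal (median 10,
ln-σ 1.5); a configurable fraction of genes (default 0.20) instead draws
mRNA FPKM uniformly below 1 so expressed/translated calling exercises both
outcomes. Then

log2 TEI = β₀ + β_gc·GC + β_cds·log2(CDS bp) + β_utr5·log2(5′UTR bp)
  + β_ri·[RI in 5′UTR] + N(0, σ)

and TRAP FPKM = mRNA FPKM · 2^{log2 TEI}. Default coefficients are
(3.3, +2, −0.3, −0.2, −1) with σ = 0.5; the intercept is calibrated so
that, at the median gene (GC ≈ 0.55, CDS 1095 bp, 5′UTR 147 bp), the
median simulated TEI sits near 1, in line with genome-wide rice estimates
(≈0.9 for nontransposon genes). The log-normal noise linking the two
assays is a modelling choice of this package.

**What the generator does not emulate.** Real TEI dispersion is wider
(log2-σ ≈ 1) than the default synthetic spread (≈0.66 including feature
effects), so the fixed TEI < 0.2 and ≥ 3.0 extreme classes contain only a
handful of genes at n = 2000 where the real data have thousands; analyses
treat the cutoffs as fixed constants regardless. There is no read-level
noise, no library-size or length bias (FPKMs are drawn directly), no
splice-graph complexity beyond one retained intron per RI isoform, no
correlation between mRNA abundance and gene features (so abundance-scheme
trends are flat by construction), and recombination rates are independent
of gene features (so those correlations are null by construction — which is
what the tests assert). Passing tests therefore demonstrate correctness of
the computations and recoverability of planted effects, not robustness to
real-data artefacts.

**Companion fixtures.** Transposon cDNAs are built by embedding a
contiguous library substring (with forced mismatches at its boundaries) in
random sequence, so each cDNA's true masked fraction is exact by
construction. GO labels assign 1–3 random terms per gene plus one term
preferentially attached to high-GC genes; ortholog clusters realise each
lineage class from fixed probabilities; the marker map places markers every
~200 kb with locally varying cM/Mb around 4, leaving a central marker
desert on one chromosome to exercise gap extension.

**Determinism.** All draws flow from one `numpy.random.default_rng(seed)`;
identical parameters give byte-identical GFF3/FASTA/TSV outputs (asserted
in tests). Every stochastic stage logs its seed, and the pipeline manifest
records seed, thresholds and per-stage row counts.

## Problem sizes used by the test suite

The suite runs the full generator at n = 2000 (the study-scale default)
for recovery and stratification checks, n = 5000 feature-only draws for
the median-length check, 100 replicates of 200 isoform pairs for the
retained-intron sign check, and 20 null replicates for the GO-enrichment
false-positive check; brute-force oracle equivalences (KS, chi-square,
masking) run on samples ≤ 50 points and cDNAs ≤ 600 bp, where exhaustive
computation is exact and fast. The complete suite finishes in well under a
minute on one CPU.

## Known limitations

- Exact-match masking understates coverage for diverged repeats.
- The KS test's asymptotic p-values are approximate below ~25 points per
  sample; the exact mode exists but is not the default.
- Chi-square enrichment on terms with very small expected counts is
  flagged, not replaced by an exact test.
- The abundance scheme's quantile edges depend on the input; two datasets
  are comparable only after harmonising edges manually.
- Lineage assignment trusts the provided cluster species content; it does
  not detect contamination or paralogy artefacts.
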