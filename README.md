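# teiscope

Analysis of paired mRNA-seq / TRAP-seq abundance data: how much of each
gene's transcript pool is actually on ribosomes, and which gene features
explain the difference.

## The problem

mRNA-seq measures steady-state transcript abundance; TRAP-seq (translating
ribosome affinity purification followed by sequencing) measures the subset
of transcripts co-purified with epitope-tagged ribosomes — the
*translatome*. The ratio of the two, per gene and tissue,

```
TEI = FPKM_TRAP / FPKM_mRNA
```

is the **translatome enrichment index**: a proxy for the proportion of a
gene's transcripts engaged by ribosomes. A gene is *transcribed* when its
mRNA-seq FPKM ≥ 1 and *translated* when its TRAP-seq FPKM ≥ 1; TEI is
reported only for transcribed genes (NA otherwise).

In rice — whose coding sequences have a distinctive bimodal GC distribution
spanning roughly 40–75% — TEI varies strongly and systematically with gene
architecture: it rises with CDS GC content, falls with CDS length and with
5′UTR length, and collapses for splice isoforms that retain an intron in
the 5′UTR. `teiscope` implements that analysis end to end for anyone with
gene-level (or isoform-level) FPKM tables, an annotation, and sequences:

- **expression**: expressed/translated calls, TEI tables, translatome
  summary tables (counts and percentages per tissue and their union);
- **repeats**: validation of transposon annotations by repeat-library mask
  coverage (exact k-mer matching, ≥50% rule);
- **stratify**: TEI distributions binned by CDS length, CDS GC, UTR
  lengths, expression breadth or abundance, compared bin-against-bin with
  KS tests under Benjamini–Hochberg adjustment, plus quadratic trend fits
  and the UTR-minimum (5′ ≥ 20 bp, 3′ ≥ 110 bp) conditional analysis;
- **isoforms**: pairing of spliced (SI) vs retained-intron (RI) isoforms,
  classification of the retained intron by transcript region, per-region
  SI/RI contrasts and GO chi-square enrichment;
- **codons**: 64-codon usage tables for the TEI-extreme classes
  (TEI < 0.2 vs ≥ 3.0), per-family chi-square comparisons, first/third
  codon-position dissection, GC3;
- **lineage**: evolutionary-lineage assignment from ortholog-cluster
  species content, TEI aggregated per lineage and per GO term (≥40-gene
  rule), two-dataset comparison with %variation of group means;
- **recomb**: recombination rates (cM/Mb) in 1-Mb bins with gap extension
  across marker deserts, correlated with gene GC and TEI;
- **sim**: a synthetic-data generator that emulates the statistical
  structure of the real data (bimodal GC, log-normal lengths, a log-linear
  TEI model with known coefficients) so every stage is testable with known
  ground truth, no downloads required.

## A worked example

```
$ python examples/01_tei_basics.py
element   tissue        mRNA    TRAP    TEI  status
Tos17     callus       15.03    0.58   0.04  transcribed only
Lullaby   callus       13.01   15.61   1.20  translated
Osr10     panicle       0.01    0.00     NA  not expressed
Osr37     callus       10.12    4.83   0.48  translated
Ping      panicle      16.50    9.41   0.57  translated
Pong      callus        6.40    6.36   0.99  translated
```

These are transposable elements with documented activity in the Nipponbare
rice genome, scored from their published per-tissue FPKM pairs. Tos17 is
abundantly transcribed in callus but almost absent from ribosomes
(TEI 0.04); Lullaby's transcripts are fully engaged (TEI 1.20); Osr10 is
not expressed at all, so its TEI is undefined.

Recovering the generative TEI model from a synthetic dataset
(`examples/02_simulate_and_recover.py`, n = 2000 genes, 3 tissues):

```
n = 1498 transcribed genes (shoot)
term                true  estimate      se
intercept           0.00     0.277   0.202
beta_gc             2.00     2.033   0.094
beta_log2_cds      -0.30    -0.323   0.018
beta_log2_utr5     -0.20    -0.209   0.010
beta_ri_utr5       -1.00    -1.006   0.056
```

Each coefficient of the log2-TEI model (GC effect, CDS-length effect,
5′UTR-length effect, retained-intron-in-5′UTR penalty) is recovered within
three standard errors. The other scripts in `examples/` walk through the
transposon filter, GC stratification, retained-intron contrasts, codon
usage and the lineage/GO/recombination views, each printing the numbers it
computes and a line on what they mean.

There is also a thin CLI mirroring the pipeline stages:

```
teiscope simulate --outdir out/sim --seed 1
teiscope tei --mrna out/sim/mrna_shoot.tsv --trap out/sim/trap_shoot.tsv --out out/tei.tsv
teiscope filter-te --cdna out/sim/te_cdnas.fa --library out/sim/repeat_library.fa --out out/te.tsv
teiscope run-all --outdir out/full --seed 1
```

All file formats are plain text: GFF3 (1-based inclusive), FASTA (60-column
wrap), TSV with `NA` as the single missing-value literal.

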