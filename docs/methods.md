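# Methods

## Scope and model

The package analyses collapsed small-RNA libraries (18–30 nt, adapter
trimming assumed upstream) from Argonaute immunoprecipitations against a
genome, gene models and annotation tracks. Its four analytical cores are
read classification, enriched-locus calling, mRNA target calling, and
library-level comparative statistics; a synthetic-data generator provides
the study conditions under which all of them are validated.

Coordinates are 0-based half-open (BED) internally; GFF3 is converted at
the boundary. Read sequences are stored as DNA; first nucleotides are
reported in the RNA alphabet (T→U). Reads containing N are dropped at load
(exact-match placement cannot use them) and counted.

## Read placement

Placement is exact and full-length: a hit exists iff the read or its
reverse complement is a substring of a contig or of a mature (spliced)
transcript. The matcher stores every genomic k-mer (k = 18 default,
8 ≤ k ≤ 32) as a 2-bit-encoded integer in one sorted array; queries binary-
search their first k bases and candidates are verified by direct string
comparison, so the hit set provably equals a naive scan of both strands
(tested against that oracle). Mismatch tolerance is deliberately absent:
at desk scale exactness makes every downstream number reproducible
bit-for-bit, and the synthetic genome's repeat divergence (2 %) still
yields abundant multi-mapping reads.

Junction-spanning antisense reads have no genomic placement but do match
the spliced transcript; they count as mapped and classify as antisense-mRNA
rather than no-match.

**Multimappers.** Coverage uses fractional 1/n-hits weighting, which
conserves read mass exactly (Σ coverage = Σ count × length). For
classification a read is labelled once, taking the best (lowest-rank) label
over all of its hits. Per-gene antisense counts split a read fractionally
across its antisense transcript hits.

**Normalization.** Tracks are scaled to a target N₀ (default 30,000,000
reads — at ~22 nt this is ≈2.36× mean coverage of a 280 Mb genome). On
smaller genomes `scaled_norm_target` sets N₀ = 30 M × G/280 Mb so that the
genome-mean coverage, and therefore the absolute value of any
fold-over-mean threshold, is preserved (20-fold ≈ 50× in both regimes).
Coverage is strand-combined; strandedness is retained only in transcript
hits.

## Classification

The nine categories follow a strict priority cascade (rRNA, tRNA, miRNA,
WAGO-repeats, antisense-mRNA, intron, intergenic, no-match, sense-mRNA).
Design choices where the ordering alone under-determines behaviour:

- interval classes fire when any genome hit overlaps a class interval by
  ≥ 50 % of read length (robust to 1–2 bp boundary noise; configurable);
- "intergenic" requires a genome hit substantially outside every annotated
  class including exons and introns; a genome-mapped read with a sense
  transcript match therefore classifies sense-mRNA, not intergenic;
- a mapped read that fires nothing (e.g. 60/40 straddling an exon-intron
  boundary with no transcript match) falls back to intergenic;
- the miRNA class is an annotation overlap (mature-arm BED); no hairpin
  folding is attempted.

## WAGO-repeat locus calling

Per normalized library: maximal runs of bases ≥ F_seed × genome-mean
coverage (F_seed = 20) seed candidate windows. Windows pooled over all
libraries are merged when gaps are ≤ D = 2,000 bp (transitive, per contig —
the `mergeBed -d` semantics, verified against a union-find closure oracle);
merged loci shorter than L_min = 50 bp are dropped; loci are kept if mean
coverage within the locus is ≥ F_enr = 10 × the genome mean in at least one
library; finally loci overlapping rRNA/tRNA/miRNA annotation by ≥ 1 bp, or
on mitochondrial contigs, are removed (and reported separately). The
enrichment baseline is the genome-wide mean of the same library's
normalized track; mitochondrial contigs are excluded from the mean. Locus
rpkm values are reported per library from fractionally weighted read counts.

## mRNA targets, expression groups, metagene

Antisense rpkm uses mature-transcript length and the library's total
mapped reads; the target rule is strictly > 10 rpkm; the expressed-gene
background rule is ≥ 5 rpkm. Expression groups over a germline stage series
M1–M7: *constitutive* = expressed in all stages, *meiosis-specific* =
expressed in ≥1 of M5–M7 and none of M1–M4, *other* = remainder. This
operationalizes a verbal grouping; alternative rules (e.g. majority-stage
expression) would shift group sizes but not the target-calling logic.

Metagene profiles use the read 5′-end position in mature-transcript
coordinates (for a read antisense over transcript positions [p, p+L), the
5′ end is p+L−1), binned into B = 50 bins per transcript, count-weighted
across a gene set; genes shorter than B bases are excluded. The 5′-bias
ratio is first-quintile over last-quintile mass, with an all-5′ profile
reported as a capped sentinel (1000) rather than infinity.

## Comparative statistics

Z-scores standardize each feature row across libraries with the population
standard deviation; zero-variance rows become all-zero and are flagged.
Library PCA is specified deterministically rather than delegated to an
external differential-expression package: log2(rpkm+1), top-500
most-variable features, feature centering, SVD, component signs fixed by
making the largest-magnitude loading positive. Variance percentages are
over all retained dimensions and sum to 100. The test suite cross-checks
the coordinates against an independent PCA implementation up to sign.

## The synthetic study

The generator emulates the structure of a germline Argonaute-IP study at
desk scale. Defaults (the study conditions; all configurable):

- genome: 2 Mb in two nuclear contigs (1.00 + 0.98 Mb) plus a 20 kb
  mitochondrial contig, i.i.d. uniform ACGT background;
- 300 genes (1–8 exons of 120–400 bp, introns 60–300 bp), non-overlapping;
- 120 repeat loci: 40 planted dispersed TE-like loci (windows of 500–2,000
  bp into a 6 kb family consensus, 2 % per-base mutation), 40 cold
  dispersed loci from a second consensus (500–3,000 bp), 40 cold tandem
  arrays of a 120 bp unit — satellite-like tandem repeats are not small-RNA
  targets, so they are never planted. Shared consensus windows make reads
  multi-map within a family, exercising the fractional-weight policy, while
  the two-consensus split keeps cold-locus coverage spread far below the
  seed cutoff;
- every repeat locus is buffered > 2.6 kb from all other features so the
  2 kb merge cannot chain a locus to a gene or blacklist annotation — on
  real genomes such chaining is possible and is exactly why the standard
  procedure merges first and filters later;
- 30 miRNA, 8 rRNA, 20 tRNA loci;
- expression: log-normal rpkm (μ = ln 50, σ = 1) clipped to [8, 150],
  with 60 % constitutive (M1–M7), 20 % meiosis-specific (M5–M7), 20 %
  sporadically expressed genes. The cap keeps per-gene antisense coverage
  in WAGO-class libraries well below the locus seed cutoff, as in the real
  data where gene-antisense 22G coverage is orders of magnitude below
  repeat coverage;
- libraries: 200,000 reads, lengths ⌊Normal(mode, 1)⌉ clipped to 18–30 with
  archetype modes 22 (WAGO-1/2-, NRDE-3-, ALG-1-like), 23 (WAGO-3-like),
  24 (CSR-1-like), 26 (ALG-4-like); first-nucleotide bias 0.85 (G for
  siRNA archetypes, U for the miRNA archetype) implemented by rejection
  sampling of source windows so reads stay exact genome substrings;
- mixtures over {repeat-antisense, mRNA-antisense, mRNA-sense, miRNA,
  rRNA, tRNA, intergenic}: input is 85 % repeat-antisense (the canonical
  80–90 % band); WAGO-1/2-like 80 % repeat; CSR-1-like 75 % mRNA-antisense;
  ALG-1-like 70 % miRNA; ALG-4-like 80 % mRNA-antisense with depth reduced
  to 0.5 % before M6 (26G-RNAs only appear in late meiosis); the
  NRDE-3-like mixture switches at M5 from 70 % repeat to 55 % mRNA, with
  5′-weighted (Beta(1,4)) antisense sampling in the late phase;
  WAGO-3-like switches between germline ("early") and 4-cell-embryo
  ("late") mixtures. M8 (spermatids) is a noise library: uniform mixture
  over all source classes plus random unmappable sequences, uniform
  lengths, no 5′ bias — no class reaches 30 % after classification;
- mRNA-antisense mass is allocated across the planted target genes
  proportionally to expression × mature length (reads scale with molar
  abundance times transcript length); the analytic planted rpkm recorded in
  the truth tables is f · 10⁶ · pᵢ / Lᵢ(kb), which realized libraries
  fluctuate around multinomially.

Everything is deterministic under the config seed (per-library generators
derive from (seed, archetype, stage) via CRC32 tokens, independent of call
order).

**What the generator does not emulate,** and what passing tests therefore
do not show about real data: sequencing errors and quality variation,
5′-phosphate chemistry and ligation biases, RdRP biogenesis (reads are
sampled directly from targets), genome assembly gaps and nested/fragmented
repeats, expression estimation noise (truth expression is used directly),
and biological replicate variability beyond multinomial sampling.

## Problem sizes and numerical choices

The validation suite runs the default study end-to-end over ten seeds
(locus precision/recall at 50 % reciprocal overlap, target-set Jaccard,
switch-stage detection over M3–M6, input-library mixture recovery at 3σ);
oracle-equivalence checks use 1,000 random interval sets (≤200 intervals)
and 1,000 random reads on a 50 kb two-contig genome. These sizes were
chosen so the whole suite runs comfortably on one CPU while keeping every
statistical check's error bars far from its threshold. Degenerate inputs
fail loudly: zero mapped reads, zero genome-mean coverage, empty gene sets,
single-column Z-score matrices and >3-set Venn requests are all errors, not
silent zeros.

## Known limitations

- Exact matching understates mapping of reads from polymorphic or edited
  sites; a mismatch-tolerant mode is a config hook left unimplemented.
- The enrichment baseline follows the "relative to mean coverage" reading;
  benchmarking against the alternative (enrichment over the pre-filter
  locus set) is left to the caller via explicit parameters.
- The classifier's intergenic/sense-mRNA ordering follows the printed
  category numbering; under a different ordering a small fraction of
  genome-mapped exonic sense reads would relabel.
- Library PCA is a deterministic re-specification, not a re-implementation
  of any particular external package's transform; absolute coordinates may
  differ from such packages even when groupings agree.
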