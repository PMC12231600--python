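# Methods

## The synthetic paired-platform experiment

The generator emulates one 10x Genomics 3′ single-cell cDNA library read
out by two platforms. Its unit of truth is the molecule: a cell barcode
(16-mer), a UMI (12-mer), a transcript of origin, an artefact label, and
the genomic alignment blocks a faithful aligner would report. Downstream
stages are validated against these molecules rather than against each
other.

**Population structure.** Three barcode classes form the bimodal
barcode-rank curve seen in droplet data: high-RNA cells (default 60
barcodes, Poisson-distributed molecule counts with mean 150), low-RNA cells
(30 barcodes, mean 25) and ambient barcodes (300 barcodes, mean 2). A
configurable fraction of ambient barcodes (default 0.3) lies within edit
distance 2–3 of a real cell barcode so the empty-droplet edit-distance rule
has both near and far barcodes to act on. The whitelist contains all
generated barcodes plus 400 unused decoys.

**Reference.** A toy genome (three chromosomes, ~90 kb total) with 42
genes: spliced lengths log-uniform over 2^7–2^11 bp, 1–5 exons (adapted to
length), GT–AG junctions except one catalogued CT–AC gene, two
mitochondrial-flagged and two ribosomal-flagged genes, two lncRNA genes
(exercising the protein-coding subset), and second exon-skipping isoforms
for well over a third of genes. Gene-level length and GC metadata are the
means over each gene's isoforms.

**Artefact geometry.** Artefact molecules are planted with recoverable
signatures:

* *intra-priming* — six genes carry a 25-nt adenine tract inside the last
  exon, 150 nt before its end; artefact molecules truncate so their genomic
  3′ end abuts the tract (the 150 nt offset keeps them a separate isoform
  from full-length molecules at the default 50 bp end tolerance);
* *RT-switching* — six genes carry a novel donor 20 nt inside exon 0 whose
  junction windows share a planted exact 8-mer direct repeat;
* *LCNC* — six genes have a ~4.5 kb first intron; each artefact molecule
  extends exon 0 to a per-molecule novel donor chosen among offsets whose
  dinucleotide cannot form a canonical pair, so site coverage stays below
  3;
* *unspliced* — one contiguous block spanning the first exon–intron
  boundary, weighted toward the intron so short reads classify intronic or
  low-exonic;
* *TSO artefacts* — structurally normal molecules whose short reads begin
  with the 30-mer TSO (as a leading soft-clip when mapped, or unmapped);
  the long-read protocol removes them with efficiency 0.98.

Because the artefact flags detect sequence features, the generator also
*screens* the background: catalogued junction windows are rewritten until
they share no accidental 8-mer, and windows downstream of transcript 3′
ends are de-adenylated below the intra-priming threshold (planted features
are never touched). Without this screen, chance repeats would contaminate
the clean-molecule truth labels.

**Platform asymmetries.** Short reads: each surviving molecule emits k
reads, k uniform on [2, 6]; molecules are dropped with probability 0.8
times a clamped logistic in length (certain drop at or below 500 bp,
scale 50 bp above — the clamp makes sub-midpoint dropout exact while
keeping the roll-off smooth); reads are 91 nt from the 3′ end; 7% carry
multi-mapping markers (NH = 2, MAPQ 3); corrected-barcode and
corrected-UMI tags are each absent with probability 0.05 to exercise the
correction and UR-substitution paths; raw barcodes carry per-base errors at
0.005. Long reads: one read per surviving molecule, barcode/UMI tags
written reverse-complemented (CB/XM), 99.6% mapped; un-segmented MAS arrays
(16 segments joined by fixed distinct 16-mer adapters) are emitted
alongside for the segmentation operation.

TSO rates default to 0.06 for high-RNA and 0.20 for low-RNA/ambient cells,
mirroring the observation that low-quality cells are more contaminated.
Default artefact fractions (intra-priming 0.10, RT-switch 0.02, LCNC 0.15,
unspliced 0.10) put the filtered read fraction in the tens of percent, the
regime where filtering visibly moves the count matrices.

**What the generator does not emulate.** Base-level sequencing errors in
read bodies, quality scores, UMI sequencing errors (tag matching is exact,
as in the analysis it models), doublets, GC-dependent amplification
efficiency, and the platforms' depth asymmetry (both platforms see every
molecule; only the length-dependent dropout separates them). Passing tests
therefore demonstrate the correctness of the comparison machinery on
structurally faithful data, not robustness to raw-sequencer noise.

## Preprocessing

Barcode correction is dialect-specific. Short dialect: exact whitelist
match, else the unique 1-Hamming neighbour, else the highest-posterior
1-Hamming candidate under a per-base error model (error 10^(−q/10) from
base qualities, 0.001 without; whitelist abundances weight the posterior
when provided; ties break lexicographically). Long dialect: the whitelist
entry with lowest Levenshtein distance, ties by Hamming then lexicographic,
accepted only below distance 2. UMI resolution prefers the corrected tag
and substitutes the raw sequencer UMI when it is absent.

Deduplication: the short-read rule keeps, per tag, a mapped-and-counted
read if any, else a seeded-random mapped read, else the unmapped read;
"counted" is supplied by a prior classification pass (uniquely mapped,
exonic, single gene). The random choice is seeded from (global seed, tag
key) via BLAKE2, so results are order-independent and uniform across tags.
The long-read rule keeps the read with maximal aligned length (sum of
aligned blocks, robust to soft-clipping), ties by query name.

MAS array segmentation splits on exact adapter occurrences in order. A
missing adapter followed by a later hit counts as a corrupt junction
(warned); missing trailing adapters simply mean a shorter array.

## Annotation

Short-read classes: exonic if ≥ 50% of aligned bases fall in same-strand
exons of one gene, else intronic on gene-body overlap, else intergenic;
unique means MAPQ 255 and NH 1. Splice compatibility requires one
transcript whose exons contain every aligned block and whose introns equal
every alignment gap.

Isoform collapse groups mapped reads by (chromosome, strand, exact intron
chain); within a chain group, ends are clustered by single-linkage gaps
greater than the 5′/3′ tolerances (default 50 bp each) with the median as
representative — equivalent to the medoid rule on separated clusters and
deterministic. Mono-exonic reads cluster by ≥ 50% reciprocal overlap.

Classification order: fusion (span covers two mutually non-overlapping
genes), FSM (chain equals a catalogued chain), ISM (consecutive sub-chain),
NIC (all sites catalogued, combination novel), NNC (≥ 1 uncatalogued
site); mono-exonic isoforms are FSM on ≥ 50% reciprocal overlap with a
mono-exon transcript, ISM inside an exon, genic on gene overlap; intergenic
otherwise.

Artefact flags: intra-priming — adenine fraction ≥ 0.6 in the 20 genomic
nt downstream of the 3′ end (strand-aware; shorter windows at contig ends
are evaluated as available, below 5 nt the flag is false); RT-switching —
exact direct repeat ≥ 8 nt between the donor-side and acceptor-side 20-nt
junction windows; LCNC — a splice site that is both non-canonical by
dinucleotide (outside GT–AG/GC–AG/AT–AC) and absent from the catalogue,
with total supporting coverage over all isoforms sharing the site below 3.
Treating catalogued sites as "known" keeps FSM isoforms structurally exempt
from the LCNC flag, matching the observed behaviour of the upstream tools
this models. FSM isoforms skip the LCNC test entirely.

## Cell calling and QC

Knee calling sorts barcodes by count and takes the point of maximal
perpendicular distance to the chord of the log10(rank)–log10(count) curve;
flat curves warn and call nothing. The short-platform regime adds a rescue
of sub-knee barcodes above a count floor (default 10), standing in for the
ambient-profile test of droplet callers — the full Dirichlet-multinomial
empty-drops test is intentionally out of scope. Empty-droplet detection:
barcodes above (95th percentile of the top expected-cells counts)/20 are
cell-associated; of the rest, in descending count order and up to a cap of
2000, barcodes at edit distance ≥ 5 from every cell-associated barcode are
empty; the remainder are "other". TSO contamination matches the read head
(or leading soft-clip) to the TSO 30-mer within 3 mismatches; polyA
contamination is any 15-nt window with at most one non-A.

## Count matrices and comparison

Short-read counting: one count per tag for uniquely-mapped exonic tags
assigned to exactly one gene (≥ 50% exon overlap); intronic, intergenic,
multi-gene and multi-mapped tags are excluded. Long-read counting assigns
tags to genes through their collapsed isoform (FSM/ISM by match, NIC/NNC
and genic by overlap); multi-mapping reads and fusion/intergenic isoforms
are never counted; in artefact-filtered mode, tags of flagged isoforms are
excluded. Mitochondrial and ribosomal genes are retained in both modes.
The cross-platform comparison subsets to common cells and protein-coding
genes.

The exact test conditions on the per-gene total n after equalizing library
sizes (counts linearly rescaled to the geometric-mean library and rounded —
an approximation of quantile adjustment, validated against an enumeration
oracle and against the reference R implementation, with which it agrees to
numerical precision at equal library sizes). Given n, the split k follows
P(k) ∝ f(k) f(n−k) with f the NB(μ = n/2, φ = 0.1) pmf — a distribution
free of μ, so the conditional test is exact under the null regardless of
the true mean. The two-sided p-value is min(1, 2·min(lower tail, upper
tail)), each tail including the observed point once. Direction labels
require |log2 FC| > 1 (with 0.5 pseudo-counts on rates) and BH-adjusted
p < 0.05; genes absent from one side enter with count 0.

Pseudo-bulk correlation is Pearson's r between per-gene means of
log-normalized counts (ln(1 + 10⁴·count/cell total)). The KS statistic
compares the aligned lengths of artefact-flagged reads against all
deduplicated long reads. Tag sharing is summarized per log2 length bin
over 2^7–2^11 using truth lengths.

HVG selection ranks genes by residual log10 variance above a running-median
trend over quantile bins of log10 mean (linearly interpolated). A local
regression was considered and rejected: at tied or isolated means a loess
fit passes through single-gene outliers (self-leverage) and suppresses
exactly the genes the selection should find. Embedding: per-platform
log-normalization, HVG union, per-gene z-scoring, merged PCA (30 PCs,
deterministic full SVD); the 2-D embedding is the first two PCs by default,
with a nonlinear method pluggable but off in tests so paired distances are
reproducible. Distances are Euclidean between a cell's two platform points.

## Problem sizes and determinism

The standard configuration simulates ~10,500 molecules (~24,000 short-read
records, ~9,700 long-read records), which exercises every stage while a
full pipeline run completes in about ten seconds; recovery checks that need
tighter binomial bands (artefact-flag recall at 5,000 molecules per class,
the 2,000-gene null calibration) build dedicated fixtures at those sizes.
All randomness flows from a single integer seed through per-stage seeded
generators, and the report JSON is byte-identical across runs with the same
seed and configuration.

## Known limitations

The length bias of artefact filtering can only be demonstrated at
simulation scale: gene lengths top out at 2 kb, so the "long gene"
threshold defaults to 1.5 kb rather than the multi-kb thresholds meaningful
on a real annotation, and assertions about filtering are directional, not
numerical. The short-read platform's higher sequencing depth is not
modelled, so platform-unique tag fractions are not comparable to real
studies in magnitude — only the length-dependent direction of sharing is.
The RT-switching rule is a direct-repeat heuristic; real template switching
has subtler signatures. Barcode posterior correction simplifies the
proprietary error model of the upstream short-read pipeline to a per-base
likelihood ratio. Whether the exact test should run on raw or normalized
pseudo-bulk is genuinely ambiguous; it runs on raw counts with library-size
handling inside the test.
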