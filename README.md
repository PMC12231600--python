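# molmatch

Molecule-level comparison of paired long-read and short-read single-cell
RNA-seq readouts.

When the same barcoded 10x Genomics 3′ cDNA is sequenced both with short
reads (fragmented, deeply sampled) and with long reads (full-length, one
read per molecule after deduplication), every original cDNA molecule can be
matched across platforms through its **tag ID** — the 16 bp cell barcode
concatenated with the 12 bp UMI. `molmatch` implements that comparison as a
reusable, tested pipeline, together with a synthetic paired-platform data
generator that provides known ground truth for every stage. It is aimed at
people building or evaluating single-cell long-read workflows who want to
quantify what each platform's library chemistry and software stack does to
the recovered molecules.

## What it computes

* **Per-molecule tag matching.** Tags are canonicalized per platform (the
  long-read dialect stores barcode and UMI reverse-complemented), barcodes
  are corrected in each platform's dialect (1-Hamming with a base-quality
  posterior for short reads; lowest Levenshtein < 2 with Hamming tie-break
  for long reads), and reads are deduplicated per tag (short: counted ≻
  random mapped ≻ unmapped; long: longest aligned read).
* **Dual annotation.** Short-read vocabulary: exonic / intronic /
  intergenic / unmapped × unique / multi-mapped, plus a splice-compatibility
  flag. Long-read vocabulary: splice-junction isoform classes FSM / ISM /
  NIC / NNC / genic / intergenic / fusion, with artefact flags for
  intra-priming (A-rich genomic window downstream of the 3′ end),
  RT-switching (direct repeat across junction windows) and low-coverage
  non-canonical junctions (LCNC), and a crosswalk table between the two
  vocabularies over shared tags.
* **Cell calling and QC.** Knee-point calling on the log–log barcode-rank
  curve, knee-plus-rescue calling, quantile-threshold empty-droplet
  detection with an edit-distance ≥ 5 rule, TSO/polyA contamination and
  mitochondrial/ribosomal content.
* **Count-matrix comparison.** Platform-specific UMI counting (filtered and
  unfiltered of artefacts on the long-read side), pseudo-bulk Pearson
  correlation, a per-gene exact test under a negative binomial with fixed
  dispersion φ = 0.1 (conditioning on the per-gene total after library-size
  equalization, doubled-tail p-values, Benjamini–Hochberg correction),
  gene-length/GC stratification of the discordant genes, a
  Kolmogorov–Smirnov test on filtered-vs-unfiltered molecule lengths, and a
  merged PCA embedding with per-cell paired distances.

## Worked example

```
molmatch all --seed 2 --outdir run
```

prints

```
report written to run/report.json
shared tags: 5769; r(unfiltered)=0.700; r(filtered)=0.640
```

and writes the full report plus count matrices, DE tables, the isoform
table and the crosswalk into `run/`. Reading: of the simulated molecules
observed by both platforms, 5769 tag IDs matched across platforms; the
pseudo-bulk gene expression of the two platforms correlates at r = 0.70
before artefact filtering; removing intra-priming / RT-switching / LCNC
molecules from the long-read counts *lowers* the cross-platform correlation
to 0.64 — the filtering removes real concordant signal preferentially from
long genes, which is the central behaviour the pipeline measures. The
report also contains the per-length-bin tag-sharing table showing the
short-read platform's depletion of molecules below ~500 bp, the cell-set
overlap of the two calling regimes, and per-class TSO contamination.

The same analysis is available as a library:

```python
from molmatch import SimConfig
from molmatch.pipeline import run_all

res = run_all(SimConfig(seed=2))
res.sharing.bin_table       # shared fraction per log2 length bin
res.pearson_unfiltered      # 0.700...
res.crosswalk               # short-class x long-class contingency table
```

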