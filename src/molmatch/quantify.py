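"""Gene x cell UMI counting and cross-platform comparison statistics.

Counting rules mirror each platform's conventions: the short-read side
counts only uniquely-mapped (MAPQ 255, single alignment) exonic tags
assigned to exactly one gene, excluding intronic/intergenic tags; the
long-read side counts every gene-assigned tag in unfiltered mode and drops
tags of artefact-flagged or discarded isoforms in filtered mode, always
retaining mitochondrial/ribosomal genes.

The comparison statistics are pseudo-bulk Pearson correlation, a
fixed-dispersion negative-binomial exact test per gene with
Benjamini-Hochberg correction, per-direction gene length/GC summaries, a
Kolmogorov-Smirnov test on filtered-vs-unfiltered molecule lengths, and the
per-length-bin tag-sharing summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from molmatch.annotate import assigned_genes, classify_short
from molmatch.reference import ReferenceBundle


@dataclass
class CountMatrix:
    counts: pd.DataFrame              # genes x cells, integer
    gene_meta: pd.DataFrame           # length, gc, is_mito, is_ribo, biotype
    platform: str
    filter_mode: str = "unfiltered"   # or "artefact_filtered"

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def subset_genes(self, genes) -> "CountMatrix":
        genes = [g for g in genes if g in self.counts.index]
        return CountMatrix(self.counts.loc[genes], self.gene_meta.loc[genes],
                           self.platform, self.filter_mode)

    def subset_cells(self, cells) -> "CountMatrix":
        cells = [c for c in cells if c in self.counts.columns]
        return CountMatrix(self.counts[cells], self.gene_meta,
                           self.platform, self.filter_mode)

    def protein_coding(self) -> "CountMatrix":
        keep = self.gene_meta.index[self.gene_meta["biotype"] == "protein_coding"]
        return self.subset_genes(list(keep))


def _gene_meta_frame(ref: ReferenceBundle) -> pd.DataFrame:
    return pd.DataFrame.from_dict(ref.gene_meta, orient="index").sort_index()


def _empty_matrix(ref: ReferenceBundle, cells, platform, mode) -> CountMatrix:
    meta = _gene_meta_frame(ref)
    counts = pd.DataFrame(0, index=meta.index, columns=sorted(cells), dtype=int)
    return CountMatrix(counts, meta, platform, mode)


def count_short(survivors: dict[str, object], ref: ReferenceBundle,
                cells, exon_overlap_frac: float = 0.5) -> CountMatrix:
    """UMI counts from deduplicated short-read records: one count per
    (gene, cell, tag) for unique exonic single-gene tags."""
    cm = _empty_matrix(ref, cells, "short", "unfiltered")
    cell_set = set(cells)
    acc: dict[tuple[str, str], int] = {}
    for key in sorted(survivors):
        r = survivors[key]
        bc = key[:16]
        if bc not in cell_set:
            continue
        if not r.mapped or r.mapq != 255 or r.alignment_count != 1:
            continue
        region, _ = classify_short(r, ref, exon_overlap_frac)
        if region != "exonic":
            continue
        genes = assigned_genes(r, ref, exon_overlap_frac)
        if len(genes) != 1:
            continue  # ambiguous multi-gene overlap discarded
        acc[(genes[0], bc)] = acc.get((genes[0], bc), 0) + 1
    _fill(cm.counts, acc)
    return cm


def _fill(counts: pd.DataFrame, acc: dict[tuple[str, str], int]) -> None:
    gi = {g: i for i, g in enumerate(counts.index)}
    ci = {c: i for i, c in enumerate(counts.columns)}
    arr = counts.to_numpy()
    for (g, c), n in acc.items():
        arr[gi[g], ci[c]] += n
    counts.iloc[:, :] = arr


def count_long(survivors: dict[str, object], classifications: dict,
               tag_to_isoform: dict[str, str], ref: ReferenceBundle,
               cells, filter_mode: str = "unfiltered") -> CountMatrix:
    """UMI counts from long-read tags via their collapsed isoforms.

    Unfiltered mode counts every gene-assigned tag; artefact_filtered mode
    additionally drops tags of flagged or discarded isoforms.  Mito/ribo
    genes are retained in both modes.
    """
    if filter_mode not in ("unfiltered", "artefact_filtered"):
        raise ValueError(f"unknown filter_mode {filter_mode!r}")
    cm = _empty_matrix(ref, cells, "long", filter_mode)
    cell_set = set(cells)
    acc: dict[tuple[str, str], int] = {}
    for key in sorted(survivors):
        r = survivors[key]
        bc = key[:16]
        if bc not in cell_set or not r.mapped:
            continue
        if r.alignment_count != 1:
            continue  # multi-mapping long reads are eliminated from counts
        iso_id = tag_to_isoform.get(key)
        if iso_id is None:
            continue
        cls = classifications.get(iso_id)
        if cls is None or cls.matched_gene_id is None:
            continue
        if cls.category in ("intergenic", "fusion"):
            continue
        if cls.discard_reason != "none":
            continue
        if filter_mode == "artefact_filtered" and cls.artefact_flags:
            continue
        acc[(cls.matched_gene_id, bc)] = acc.get((cls.matched_gene_id, bc), 0) + 1
    _fill(cm.counts, acc)
    return cm


def pseudo_bulk(matrix: CountMatrix) -> pd.Series:
    """Per-gene sum of counts across all cells."""
    return matrix.counts.sum(axis=1)


def lognormalize(matrix: CountMatrix, scale_factor: float = 1e4) -> pd.DataFrame:
    """ln(1 + count / cell_total * scale_factor); zero-total cells dropped."""
    totals = matrix.counts.sum(axis=0)
    keep = totals[totals > 0].index
    if len(keep) < matrix.counts.shape[1]:
        import warnings
        warnings.warn(f"dropping {matrix.counts.shape[1] - len(keep)} "
                      "zero-total cells from normalization")
    sub = matrix.counts[keep]
    return np.log1p(sub / sub.sum(axis=0) * scale_factor)


# ---------------------------------------------------------------------------
# fixed-dispersion negative-binomial exact test

def _nb_split_logpmf(n_total: int, dispersion: float) -> np.ndarray:
    """Conditional log-probabilities of the split (k, n-k) for two iid
    NB(mu, dispersion) counts given their sum, before normalization."""
    r = 1.0 / dispersion
    mu = n_total / 2.0
    k = np.arange(n_total + 1)
    lp = stats.nbinom.logpmf(k, r, r / (r + mu))
    return lp + lp[::-1]


def nb_exact_test(count_a: float, count_b: float, lib_a: float, lib_b: float,
                  dispersion: float = 0.1) -> float:
    """Two-sided exact test of equal means under a fixed-dispersion negative
    binomial, conditioning on the total after equalizing library sizes.

    Counts are rescaled to the geometric-mean library size; the two-sided
    p-value is the doubled smaller conditional tail, capped at 1.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    lib_geo = float(np.sqrt(lib_a * lib_b))
    a = int(round(count_a * lib_geo / lib_a))
    b = int(round(count_b * lib_geo / lib_b))
    n = a + b
    if n == 0:
        return 1.0
    logp = _nb_split_logpmf(n, dispersion)
    p = np.exp(logp - logp.max())
    p /= p.sum()
    lower = p[: a + 1].sum()
    upper = p[a:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def de_by_platform(pb_a: pd.Series, pb_b: pd.Series, dispersion: float = 0.1,
                   lfc_threshold: float = 1.0, fdr_threshold: float = 0.05
                   ) -> pd.DataFrame:
    """Per-gene exact test between two pseudo-bulks.

    Genes missing from either side enter with count 0.  Returns a frame
    with counts, log2 fold change, p, BH-adjusted p and direction.
    """
    genes = sorted(set(pb_a.index) | set(pb_b.index))
    a = pb_a.reindex(genes, fill_value=0).astype(float)
    b = pb_b.reindex(genes, fill_value=0).astype(float)
    lib_a, lib_b = float(a.sum()), float(b.sum())
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("empty pseudo-bulk")
    pvals = np.array([nb_exact_test(a[g], b[g], lib_a, lib_b, dispersion)
                      for g in genes])
    padj = multipletests(pvals, method="fdr_bh")[1]
    logfc = np.log2(((a.to_numpy() + 0.5) / lib_a)
                    / ((b.to_numpy() + 0.5) / lib_b))
    direction = np.where(
        (padj < fdr_threshold) & (logfc > lfc_threshold), "higher_A",
        np.where((padj < fdr_threshold) & (logfc < -lfc_threshold),
                 "higher_B", "equal"))
    return pd.DataFrame({"count_a": a, "count_b": b, "logFC": logfc,
                         "pvalue": pvals, "padj": padj,
                         "direction": direction}, index=genes)


def stratify_by_length_gc(de: pd.DataFrame, gene_meta: pd.DataFrame) -> dict:
    """Mean gene length and GC per DE direction group, with t statistics
    between each 'higher' group and the 'equal' group."""
    out: dict = {}
    meta = gene_meta.reindex(de.index)
    for grp in ("higher_A", "higher_B", "equal"):
        sel = de["direction"] == grp
        sub = meta[sel]
        out[grp] = {
            "n": int(sel.sum()),
            "mean_length": float(sub["length"].mean()) if sel.sum() else float("nan"),
            "mean_gc": float(sub["gc"].mean()) if sel.sum() else float("nan"),
        }
    eq = meta[de["direction"] == "equal"]["length"].dropna()
    for grp in ("higher_A", "higher_B"):
        g = meta[de["direction"] == grp]["length"].dropna()
        if len(g) >= 2 and len(eq) >= 2:
            t, p = stats.ttest_ind(g, eq, equal_var=False)
            out[grp]["t_vs_equal"] = float(t)
            out[grp]["t_pvalue"] = float(p)
        else:
            out[grp]["t_vs_equal"] = None
            out[grp]["t_pvalue"] = None
    return out


def ks_length_bias(filtered_lengths, unfiltered_lengths) -> tuple[float, float]:
    """Two-sample KS statistic and p-value between length distributions."""
    filtered_lengths = np.asarray(list(filtered_lengths), dtype=float)
    unfiltered_lengths = np.asarray(list(unfiltered_lengths), dtype=float)
    if len(filtered_lengths) == 0 or len(unfiltered_lengths) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(filtered_lengths, unfiltered_lengths, method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# tag matching

@dataclass
class TagSharing:
    shared: set[str]
    short_only: set[str]
    long_only: set[str]
    bin_table: pd.DataFrame  # per log2-length bin: n_long, n_shared, frac

    @property
    def n_union(self) -> int:
        return len(self.shared) + len(self.short_only) + len(self.long_only)


def match_tags(short_tags, long_tags, lengths: dict[str, float] | None = None,
               bin_edges=(7, 8, 9, 10, 11)) -> TagSharing:
    """Partition tag IDs into shared / platform-unique and summarize the
    shared fraction of long-read tags per log2 molecule-length bin."""
    s, l = set(short_tags), set(long_tags)
    shared = s & l
    rows = []
    if lengths is not None:
        edges = list(bin_edges)
        for lo, hi in zip(edges[:-1], edges[1:]):
            in_bin = [t for t in l
                      if t in lengths and lo <= np.log2(max(lengths[t], 1)) < hi]
            n_shared = sum(1 for t in in_bin if t in shared)
            rows.append({"bin": f"{lo}-{hi}", "n_long": len(in_bin),
                         "n_shared": n_shared,
                         "frac_shared": (n_shared / len(in_bin)
                                         if in_bin else float("nan"))})
    bin_table = pd.DataFrame(rows, columns=["bin", "n_long", "n_shared",
                                            "frac_shared"])
    return TagSharing(shared, s - l, l - s, bin_table)


def pseudobulk_correlation(matrix_a: CountMatrix, matrix_b: CountMatrix,
                           scale_factor: float = 1e4) -> float:
    """Pearson r between per-gene means of log-normalized counts, over the
    union of genes detected on either side."""
    na = lognormalize(matrix_a, scale_factor).mean(axis=1)
    nb = lognormalize(matrix_b, scale_factor).mean(axis=1)
    genes = sorted(set(na.index) | set(nb.index))
    va = na.reindex(genes, fill_value=0.0).to_numpy()
    vb = nb.reindex(genes, fill_value=0.0).to_numpy()
    if np.allclose(va, va[0]) or np.allclose(vb, vb[0]):
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])
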