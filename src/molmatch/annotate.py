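"""Dual annotation of deduplicated molecules.

Short-read vocabulary: genomic-region classes (exonic / intronic /
intergenic / unmapped, crossed with unique / multi-mapped) plus a
splice-compatibility flag.  Long-read vocabulary: splice-junction isoform
classes in the SQANTI tradition (FSM / ISM / NIC / NNC / genic / intergenic /
fusion) with artefact flags for intra-priming, RT-switching and low-coverage
non-canonical (LCNC) junctions.  The crosswalk tabulates one vocabulary
against the other over the tags shared by both platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from molmatch.preprocess import ReadRecord
from molmatch.reference import ReferenceBundle, revcomp, CANONICAL_PAIRS

SHORT_REGIONS = ("exonic", "intronic", "intergenic", "unmapped")
ISO_CATEGORIES = ("FSM", "ISM", "NIC", "NNC", "genic", "intergenic", "fusion")


@dataclass
class JunctionChain:
    chromosome: str
    strand: str
    introns: tuple[tuple[int, int], ...]
    dinucleotides: list[tuple[str, str]]
    canonical: list[bool]


@dataclass
class Isoform:
    isoform_id: str
    chrom: str
    strand: str
    chain: tuple[tuple[int, int], ...]
    start: int
    end: int
    supporting_tags: list[str]

    @property
    def coverage(self) -> int:
        return len(self.supporting_tags)

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class IsoformClassification:
    category: str
    matched_transcript_id: str | None = None
    matched_gene_id: str | None = None
    artefact_flags: set[str] = field(default_factory=set)
    discard_reason: str = "none"


def junction_chain(chrom: str, strand: str, introns, genome) -> JunctionChain:
    seq = genome[chrom]
    ordered = list(introns) if strand == "+" else list(introns)[::-1]
    dinucs = []
    for a, b in ordered:
        if strand == "+":
            dinucs.append((seq[a:a + 2], seq[b - 2:b]))
        else:
            dinucs.append((revcomp(seq[b - 2:b]), revcomp(seq[a:a + 2])))
    return JunctionChain(chrom, strand, tuple(introns), dinucs,
                         [d in CANONICAL_PAIRS for d in dinucs])


# ---------------------------------------------------------------------------
# reference index (cached on the bundle)

class _Index:
    def __init__(self, ref: ReferenceBundle):
        self.ref = ref
        self.exon_union: dict[str, list[tuple[int, int]]] = {}
        for gid in sorted(ref.genes):
            ivs = sorted(
                (s, e) for t in ref.transcripts_of(gid) for (s, e) in t.exons)
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self.exon_union[gid] = [tuple(x) for x in merged]
        self.genes_by_loc: dict[tuple[str, str], list] = {}
        for gid in sorted(ref.genes):
            g = ref.genes[gid]
            self.genes_by_loc.setdefault((g.chrom, g.strand), []).append(g)
        self.chains = ref.catalog_chains()
        self.sites = ref.catalog_sites()
        self.tx_by_loc: dict[tuple[str, str], list] = {}
        for tid in sorted(ref.transcripts):
            t = ref.transcripts[tid]
            self.tx_by_loc.setdefault((t.chrom, t.strand), []).append(t)


def _index(ref: ReferenceBundle) -> _Index:
    idx = getattr(ref, "_annot_index", None)
    if idx is None:
        idx = _Index(ref)
        ref._annot_index = idx
    return idx


def _overlap(a, b) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _blocks_exon_overlap(blocks, exon_union) -> int:
    return sum(_overlap(b, e) for b in blocks for e in exon_union)


# ---------------------------------------------------------------------------
# short-read vocabulary

def classify_short(record: ReadRecord, ref: ReferenceBundle,
                   exon_overlap_frac: float = 0.5) -> tuple[str, str]:
    """(region class, mapping class) for a deduplicated short-read record."""
    mapping = ("unique"
               if record.mapq == 255 and record.alignment_count == 1
               else "multimapped")
    if not record.mapped:
        return "unmapped", mapping
    idx = _index(ref)
    total = record.aligned_length
    span = (record.start, record.end)
    best = 0
    for g in idx.genes_by_loc.get((record.chrom, record.strand), []):
        if g.end <= span[0] or g.start >= span[1]:
            continue
        best = max(best, _blocks_exon_overlap(record.blocks, idx.exon_union[g.gene_id]))
    if total and best / total >= exon_overlap_frac:
        return "exonic", mapping
    for g in idx.genes_by_loc.get((record.chrom, record.strand), []):
        if _overlap(span, (g.start, g.end)) > 0:
            return "intronic", mapping
    return "intergenic", mapping


def assigned_genes(record: ReadRecord, ref: ReferenceBundle,
                   exon_overlap_frac: float = 0.5) -> list[str]:
    """Genes whose exons cover at least the threshold fraction of the read."""
    if not record.mapped:
        return []
    idx = _index(ref)
    total = record.aligned_length or 1
    out = []
    for g in idx.genes_by_loc.get((record.chrom, record.strand), []):
        ov = _blocks_exon_overlap(record.blocks, idx.exon_union[g.gene_id])
        if ov / total >= exon_overlap_frac:
            out.append(g.gene_id)
    return out


def splice_compatible(record: ReadRecord, ref: ReferenceBundle) -> bool:
    """True iff some reference transcript explains the read's alignment:
    all blocks within exons and every alignment gap equal to an intron."""
    if not record.mapped:
        return False
    idx = _index(ref)
    gaps = tuple((record.blocks[i][1], record.blocks[i + 1][0])
                 for i in range(len(record.blocks) - 1))
    for t in idx.tx_by_loc.get((record.chrom, record.strand), []):
        if t.end <= record.start or t.start >= record.end:
            continue
        introns = set(t.introns)
        if any(g not in introns for g in gaps):
            continue
        exons = t.exons
        if all(any(s >= es and e <= ee for es, ee in exons)
               for s, e in record.blocks):
            return True
    return False


# ---------------------------------------------------------------------------
# isoform collapse

def _cluster_by_gap(values: list[float], tol: float) -> list[list[int]]:
    """Single-linkage 1-D clustering: split sorted values at gaps > tol."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    clusters = [[order[0]]]
    for i in order[1:]:
        if values[i] - values[clusters[-1][-1]] > tol:
            clusters.append([i])
        else:
            clusters[-1].append(i)
    return clusters


def collapse_isoforms(records: list[ReadRecord], end_tolerance_5p: int = 50,
                      end_tolerance_3p: int = 50) -> list[Isoform]:
    """Group mapped reads into isoforms by exact intron chain, with ends
    allowed to vary by the configured tolerances; mono-exonic reads are
    grouped by >= 50% reciprocal overlap."""
    mapped = [r for r in records if r.mapped and r.blocks]
    chain_groups: dict[tuple, list[ReadRecord]] = {}
    for r in mapped:
        gaps = tuple((r.blocks[i][1], r.blocks[i + 1][0])
                     for i in range(len(r.blocks) - 1))
        chain_groups.setdefault((r.chrom, r.strand, gaps), []).append(r)

    isoforms: list[Isoform] = []
    for key in sorted(chain_groups):
        chrom, strand, gaps = key
        group = chain_groups[key]
        if gaps:
            tol_start = end_tolerance_5p if strand == "+" else end_tolerance_3p
            tol_end = end_tolerance_3p if strand == "+" else end_tolerance_5p
            ends = [float(r.end) for r in group]
            for ci in _cluster_by_gap(ends, tol_end):
                sub = [group[i] for i in ci]
                starts = [float(r.start) for r in sub]
                for cj in _cluster_by_gap(starts, tol_start):
                    isoforms.append(_make_isoform(chrom, strand, gaps,
                                                  [sub[j] for j in cj]))
        else:
            # mono-exonic: greedy reciprocal-overlap clustering
            group = sorted(group, key=lambda r: (r.start, r.end, r.query_name))
            clusters: list[list[ReadRecord]] = []
            reps: list[tuple[int, int]] = []
            for r in group:
                placed = False
                for k, rep in enumerate(reps):
                    ov = _overlap((r.start, r.end), rep)
                    if (ov >= 0.5 * (r.end - r.start)
                            and ov >= 0.5 * (rep[1] - rep[0])):
                        clusters[k].append(r)
                        placed = True
                        break
                if not placed:
                    clusters.append([r])
                    reps.append((r.start, r.end))
            for cl in clusters:
                isoforms.append(_make_isoform(chrom, strand, (), cl))

    for n, iso in enumerate(isoforms):
        iso.isoform_id = f"ISO{n:06d}"
    return isoforms


def _make_isoform(chrom, strand, gaps, group) -> Isoform:
    starts = sorted(r.start for r in group)
    ends = sorted(r.end for r in group)
    start = starts[len(starts) // 2]
    end = ends[len(ends) // 2]
    tags = sorted(r.tag_key or r.query_name for r in group)
    return Isoform("", chrom, strand, gaps, start, end, tags)


# ---------------------------------------------------------------------------
# isoform classification

def _is_consecutive_subchain(sub, full) -> bool:
    n, m = len(sub), len(full)
    if n == 0 or n >= m:
        return False
    return any(tuple(full[i:i + n]) == tuple(sub) for i in range(m - n + 1))


def classify_isoform(iso: Isoform, ref: ReferenceBundle) -> IsoformClassification:
    idx = _index(ref)
    span = (iso.start, iso.end)
    genes = [g for g in idx.genes_by_loc.get((iso.chrom, iso.strand), [])
             if _overlap(span, (g.start, g.end)) > 0]

    # fusion: span covers >= 2 mutually non-overlapping genes
    if len(genes) >= 2:
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if _overlap((genes[i].start, genes[i].end),
                            (genes[j].start, genes[j].end)) == 0:
                    return IsoformClassification("fusion",
                                                 matched_gene_id=genes[i].gene_id)

    if iso.chain:
        hit = idx.chains.get((iso.chrom, iso.strand, iso.chain))
        if hit is not None:
            return IsoformClassification(
                "FSM", matched_transcript_id=hit,
                matched_gene_id=ref.transcripts[hit].gene_id)
        for (chrom, strand, full), tid in sorted(idx.chains.items(),
                                                 key=lambda kv: kv[1]):
            if chrom != iso.chrom or strand != iso.strand:
                continue
            if _is_consecutive_subchain(iso.chain, full):
                return IsoformClassification(
                    "ISM", matched_transcript_id=tid,
                    matched_gene_id=ref.transcripts[tid].gene_id)
        if not genes:
            return IsoformClassification("intergenic")
        gid = genes[0].gene_id
        all_known = True
        for a, b in iso.chain:
            if iso.strand == "+":
                donor = (iso.chrom, iso.strand, a, "donor")
                acceptor = (iso.chrom, iso.strand, b, "acceptor")
            else:
                donor = (iso.chrom, iso.strand, b, "donor")
                acceptor = (iso.chrom, iso.strand, a, "acceptor")
            if donor not in idx.sites or acceptor not in idx.sites:
                all_known = False
                break
        return IsoformClassification("NIC" if all_known else "NNC",
                                     matched_gene_id=gid)

    # mono-exonic
    if not genes:
        return IsoformClassification("intergenic")
    for t in idx.tx_by_loc.get((iso.chrom, iso.strand), []):
        if len(t.exons) == 1:
            ov = _overlap(span, (t.start, t.end))
            if (ov >= 0.5 * (iso.end - iso.start)
                    and ov >= 0.5 * (t.end - t.start)):
                return IsoformClassification("FSM", matched_transcript_id=t.transcript_id,
                                             matched_gene_id=t.gene_id)
    for t in idx.tx_by_loc.get((iso.chrom, iso.strand), []):
        if any(iso.start >= es and iso.end <= ee for es, ee in t.exons):
            return IsoformClassification("ISM", matched_transcript_id=t.transcript_id,
                                         matched_gene_id=t.gene_id)
    return IsoformClassification("genic", matched_gene_id=genes[0].gene_id)


# ---------------------------------------------------------------------------
# artefact flags

def flag_intrapriming(iso: Isoform, genome: dict[str, str],
                      window: int = 20, a_frac: float = 0.6) -> bool:
    """Adenine fraction >= threshold in the genomic window immediately
    downstream of the isoform 3' end (strand-aware)."""
    seq = genome[iso.chrom]
    if iso.strand == "+":
        down = seq[iso.end:iso.end + window]
    else:
        down = revcomp(seq[max(0, iso.start - window):iso.start])
    if len(down) < 5:
        return False
    return down.count("A") / len(down) >= a_frac


def _kmers(s: str, k: int) -> set[str]:
    return {s[i:i + k] for i in range(len(s) - k + 1)}


def flag_rtswitch(iso: Isoform, genome: dict[str, str],
                  repeat_len: int = 8, window: int = 10) -> bool:
    """Exact direct repeat >= ``repeat_len`` between the donor-side and
    acceptor-side junction windows of any intron."""
    if not iso.chain:
        return False
    seq = genome[iso.chrom]
    for a, b in iso.chain:
        if iso.strand == "+":
            donor_w = seq[max(0, a - window):a + window]
            acceptor_w = seq[max(0, b - window):b + window]
        else:
            donor_w = revcomp(seq[max(0, b - window):b + window])
            acceptor_w = revcomp(seq[max(0, a - window):a + window])
        if _kmers(donor_w, repeat_len) & _kmers(acceptor_w, repeat_len):
            return True
    return False


def _novel_noncanonical_sites(iso: Isoform, ref: ReferenceBundle):
    """Splice sites of ``iso`` that are non-canonical by dinucleotide and
    absent from the reference catalogue."""
    idx = _index(ref)
    chain = junction_chain(iso.chrom, iso.strand, iso.chain, ref.genome)
    ordered = list(iso.chain) if iso.strand == "+" else list(iso.chain)[::-1]
    out = []
    for (a, b), canonical in zip(ordered, chain.canonical):
        if canonical:
            continue
        if iso.strand == "+":
            donor = (iso.chrom, iso.strand, a, "donor")
            acceptor = (iso.chrom, iso.strand, b, "acceptor")
        else:
            donor = (iso.chrom, iso.strand, b, "donor")
            acceptor = (iso.chrom, iso.strand, a, "acceptor")
        for site in (donor, acceptor):
            if site not in idx.sites:
                out.append(site)
    return out


def flag_lcnc(iso: Isoform, all_isoforms: list[Isoform], ref: ReferenceBundle,
              min_coverage: int = 3) -> bool:
    """Uncatalogued non-canonical splice site with total supporting read
    coverage (summed over all isoforms sharing the site) below threshold."""
    targets = _novel_noncanonical_sites(iso, ref)
    if not targets:
        return False
    coverage: dict = {}
    for other in all_isoforms:
        if other.chrom != iso.chrom or other.strand != iso.strand:
            continue
        for site in _iso_sites(other):
            coverage[site] = coverage.get(site, 0) + other.coverage
    return any(coverage.get(site, 0) < min_coverage for site in targets)


def _iso_sites(iso: Isoform):
    for a, b in iso.chain:
        if iso.strand == "+":
            yield (iso.chrom, iso.strand, a, "donor")
            yield (iso.chrom, iso.strand, b, "acceptor")
        else:
            yield (iso.chrom, iso.strand, b, "donor")
            yield (iso.chrom, iso.strand, a, "acceptor")


def classify_and_flag(isoforms: list[Isoform], ref: ReferenceBundle,
                      intrapriming_window: int = 20,
                      intrapriming_a_frac: float = 0.6,
                      rt_repeat_len: int = 8, rt_window: int = 10,
                      lcnc_min_coverage: int = 3
                      ) -> dict[str, IsoformClassification]:
    """Classify every isoform and attach artefact flags (one pass)."""
    site_cov: dict = {}
    for iso in isoforms:
        for site in _iso_sites(iso):
            site_cov[site] = site_cov.get(site, 0) + iso.coverage

    out: dict[str, IsoformClassification] = {}
    for iso in isoforms:
        cls = classify_isoform(iso, ref)
        if flag_intrapriming(iso, ref.genome, intrapriming_window,
                             intrapriming_a_frac):
            cls.artefact_flags.add("intra_priming")
        if flag_rtswitch(iso, ref.genome, rt_repeat_len, rt_window):
            cls.artefact_flags.add("rt_switching")
        if cls.category != "FSM":
            novel_nc = _novel_noncanonical_sites(iso, ref)
            if any(site_cov.get(s, 0) < lcnc_min_coverage for s in novel_nc):
                cls.artefact_flags.add("lcnc")
        out[iso.isoform_id] = cls
    return out


# ---------------------------------------------------------------------------
# crosswalk

CROSSWALK_SHORT = SHORT_REGIONS
CROSSWALK_LONG = ISO_CATEGORIES + ("discarded",)


def crosswalk(tag_table: pd.DataFrame) -> pd.DataFrame:
    """Contingency table of short-read region class x long-read isoform class
    over shared tags.  ``tag_table`` needs columns ``short_class`` and
    ``long_class``; marginals equal the number of input tags."""
    table = pd.crosstab(tag_table["short_class"], tag_table["long_class"])
    table = table.reindex(index=list(CROSSWALK_SHORT),
                          columns=list(CROSSWALK_LONG), fill_value=0)
    table.index.name = "short_class"
    table.columns.name = "long_class"
    assert int(table.to_numpy().sum()) == len(tag_table)
    return table
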