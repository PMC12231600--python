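"""Ground-truth cDNA molecules for the paired-platform simulation.

Each molecule is one captured cDNA: a cell barcode (16-mer), a UMI (12-mer),
a transcript of origin, an artefact label, and the genomic alignment blocks a
faithful aligner would report for it.  The blocks fully determine the
molecule's length (its possibly truncated transcript span) and its intron
chain, so the downstream annotation stages can be validated against known
truth.

Artefact geometry (planted by :mod:`molmatch.reference`):

* ``intra_priming``    — transcript truncated so its genomic 3' end abuts the
  gene's adenine tract;
* ``rt_switch``        — intron 0 extended to the planted novel donor whose
  junction windows share an 8-mer direct repeat;
* ``lcnc``             — intron 0 shortened to a per-molecule novel donor with
  a non-canonical dinucleotide (coverage stays below 3);
* ``unspliced``        — one contiguous genomic block spanning the first
  exon/intron boundary;
* ``tso_artifact``     — normal structure, but reads carry the TSO sequence
  and the long-read protocol removes most of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from molmatch.config import SimConfig, BARCODE_LEN, UMI_LEN
from molmatch.reference import ReferenceBundle, Transcript

ARTEFACTS = ("none", "tso_artifact", "intra_priming", "rt_switch", "lcnc", "unspliced")
CELL_CLASSES = ("high_rna", "low_rna", "ambient")


@dataclass
class TrueMolecule:
    molecule_id: int
    cell_barcode: str
    umi: str
    cell_class: str
    gene_id: str
    transcript_id: str | None
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]  # genomic order, half-open
    artefact_label: str = "none"

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        )

    @property
    def tag_key(self) -> str:
        return self.cell_barcode + self.umi


@dataclass
class Population:
    """Barcode bookkeeping for the simulated droplet experiment."""

    high_barcodes: list[str]
    low_barcodes: list[str]
    ambient_barcodes: list[str]
    whitelist: list[str]

    def cell_class(self, barcode: str) -> str:
        if barcode in self._high:
            return "high_rna"
        if barcode in self._low:
            return "low_rna"
        return "ambient"

    def __post_init__(self):
        self._high = set(self.high_barcodes)
        self._low = set(self.low_barcodes)


def _random_kmers(rng: np.random.Generator, n: int, k: int,
                  taken: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        m = "".join("ACGT"[b] for b in rng.integers(0, 4, size=k))
        if m not in taken:
            taken.add(m)
            out.append(m)
    return out


def _mutate(rng: np.random.Generator, bc: str, n_sub: int) -> str:
    pos = rng.choice(len(bc), size=n_sub, replace=False)
    s = list(bc)
    for p in pos:
        s[p] = "ACGT"[(("ACGT".index(s[p])) + int(rng.integers(1, 4))) % 4]
    return "".join(s)


def generate_population(config: SimConfig, rng: np.random.Generator) -> Population:
    taken: set[str] = set()
    high = _random_kmers(rng, config.n_cells_high, BARCODE_LEN, taken)
    low = _random_kmers(rng, config.n_cells_low, BARCODE_LEN, taken)
    cells = high + low
    n_near = int(round(config.frac_ambient_near * config.n_ambient_barcodes))
    ambient: list[str] = []
    while len(ambient) < n_near and cells:
        base = cells[int(rng.integers(0, len(cells)))]
        m = _mutate(rng, base, int(rng.integers(2, 4)))  # edit distance 2-3
        if m not in taken:
            taken.add(m)
            ambient.append(m)
    ambient += _random_kmers(rng, config.n_ambient_barcodes - len(ambient),
                             BARCODE_LEN, taken)
    decoys = _random_kmers(rng, config.whitelist_decoys, BARCODE_LEN, taken)
    whitelist = sorted(high + low + ambient + decoys)
    return Population(high, low, ambient, whitelist)


# ---------------------------------------------------------------------------
# per-artefact block construction

def _truncate_at_atract(t: Transcript, tract: int, strand: str):
    """Blocks of a molecule whose 3' end abuts the adenine tract."""
    blocks = []
    if strand == "+":
        for s, e in t.exons:
            if e <= tract:
                blocks.append((s, e))
            elif s < tract:
                blocks.append((s, tract))
                break
            else:
                break
    else:  # 3' end is the genomic start; tract lies upstream of it
        keep = False
        for s, e in t.exons:
            if s <= tract < e:
                blocks.append((tract + 1, e))
                keep = True
            elif keep:
                blocks.append((s, e))
    return tuple(blocks)


def _rt_blocks(t: Transcript, donor: int):
    """Intron 0 extended: exon 0 ends at the planted novel donor."""
    (s0, _e0), *rest = t.exons
    return tuple([(s0, donor)] + rest)


def _lcnc_blocks(t: Transcript, offset: int):
    """Intron 0 shortened: exon 0 extended ``offset`` nt into the intron."""
    (s0, e0), *rest = t.exons
    return tuple([(s0, e0 + offset)] + rest)


def _unspliced_blocks(t: Transcript, rng: np.random.Generator):
    """One contiguous block spanning the first exon/intron boundary."""
    if len(t.exons) == 1:
        return (t.exons[0],)
    (s0, e0) = t.exons[0]
    (s1, _e1) = t.exons[1]
    left = max(s0, e0 - int(rng.integers(40, max(41, e0 - s0))))
    right = min(s1 + 40, t.exons[1][1])
    return ((left, right),)


def generate_molecules(config: SimConfig, ref: ReferenceBundle,
                       population: Population | None = None) -> list[TrueMolecule]:
    """Draw the molecule population with configured artefact fractions."""
    config.validate()
    if not ref.genes:
        raise ValueError("reference bundle is empty")
    rng = np.random.default_rng([config.seed, 0x301])
    pop = population or generate_population(config, rng)

    by_role: dict[str, list[str]] = {}
    for gid in sorted(ref.genes):
        by_role.setdefault(ref.genes[gid].role, []).append(gid)
    atract_genes = by_role.get("atract", [])
    rt_genes = by_role.get("rt", [])
    lcnc_genes = by_role.get("lcnc", [])
    spliceable = [gid for gid in sorted(ref.genes)
                  if any(t.introns for t in ref.transcripts_of(gid))]
    all_tids = sorted(ref.transcripts)

    barcodes = (
        [(b, "high_rna", config.umis_per_cell_high) for b in pop.high_barcodes]
        + [(b, "low_rna", config.umis_per_cell_low) for b in pop.low_barcodes]
        + [(b, "ambient", config.umis_per_ambient) for b in pop.ambient_barcodes]
    )

    probs = np.array([config.frac_intrapriming, config.frac_rtswitch,
                      config.frac_lcnc, config.frac_unspliced])
    labels = ("intra_priming", "rt_switch", "lcnc", "unspliced")

    molecules: list[TrueMolecule] = []
    mid = 0
    for barcode, cls, mean_umis in barcodes:
        n = int(rng.poisson(mean_umis))
        tso_rate = config.tso_rate_high if cls == "high_rna" else config.tso_rate_low
        used_umis: set[str] = set()
        for _ in range(n):
            umi = _random_kmers(rng, 1, UMI_LEN, used_umis)[0]

            if rng.random() < tso_rate:
                label = "tso_artifact"
            else:
                u = rng.random()
                c = np.cumsum(probs)
                label = "none"
                for lab, edge in zip(labels, c):
                    if u < edge:
                        label = lab
                        break

            mol = _make_molecule(rng, ref, mid, barcode, umi, cls, label,
                                 atract_genes, rt_genes, lcnc_genes,
                                 spliceable, all_tids)
            molecules.append(mol)
            mid += 1
    return molecules


def _make_molecule(rng, ref, mid, barcode, umi, cls, label,
                   atract_genes, rt_genes, lcnc_genes, spliceable, all_tids):
    if label == "intra_priming" and atract_genes:
        gid = atract_genes[int(rng.integers(0, len(atract_genes)))]
        t = ref.transcripts[f"{gid}.T1"]
        g = ref.genes[gid]
        blocks = _truncate_at_atract(t, g.atract_pos, g.strand)
        return TrueMolecule(mid, barcode, umi, cls, gid, t.transcript_id,
                            t.chrom, t.strand, blocks, label)
    if label == "rt_switch" and rt_genes:
        gid = rt_genes[int(rng.integers(0, len(rt_genes)))]
        t = ref.transcripts[f"{gid}.T1"]
        g = ref.genes[gid]
        blocks = _rt_blocks(t, g.rt_donor)
        return TrueMolecule(mid, barcode, umi, cls, gid, t.transcript_id,
                            t.chrom, t.strand, blocks, label)
    if label == "lcnc" and lcnc_genes:
        gid = lcnc_genes[int(rng.integers(0, len(lcnc_genes)))]
        t = ref.transcripts[f"{gid}.T1"]
        g = ref.genes[gid]
        off = g.lcnc_candidates[int(rng.integers(0, len(g.lcnc_candidates)))]
        blocks = _lcnc_blocks(t, off)
        return TrueMolecule(mid, barcode, umi, cls, gid, t.transcript_id,
                            t.chrom, t.strand, blocks, label)
    if label == "unspliced" and spliceable:
        gid = spliceable[int(rng.integers(0, len(spliceable)))]
        t = ref.transcripts[f"{gid}.T1"]
        blocks = _unspliced_blocks(t, rng)
        return TrueMolecule(mid, barcode, umi, cls, gid, t.transcript_id,
                            t.chrom, t.strand, blocks, label)
    # clean molecule (or tso_artifact): full transcript
    tid = all_tids[int(rng.integers(0, len(all_tids)))]
    t = ref.transcripts[tid]
    lab = label if label == "tso_artifact" else "none"
    return TrueMolecule(mid, barcode, umi, cls, t.gene_id, tid,
                        t.chrom, t.strand, tuple(t.exons), lab)


def write_truth(molecules: list[TrueMolecule], path) -> None:
    with open(path, "w") as fh:
        fh.write("molecule_id\tcell_barcode\tumi\tcell_class\tgene_id\t"
                 "transcript_id\tchrom\tstrand\tlength\tartefact_label\tblocks\n")
        for m in molecules:
            blocks = ";".join(f"{s}-{e}" for s, e in m.blocks)
            fh.write(f"{m.molecule_id}\t{m.cell_barcode}\t{m.umi}\t{m.cell_class}\t"
                     f"{m.gene_id}\t{m.transcript_id}\t{m.chrom}\t{m.strand}\t"
                     f"{m.length}\t{m.artefact_label}\t{blocks}\n")


def write_whitelist(population: Population, path) -> None:
    with open(path, "w") as fh:
        for bc in population.whitelist:
            fh.write(bc + "\n")
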