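"""Toy reference genome and transcript annotation with known truth.

The generated reference plays the role a genome build plus transcript
catalogue play in a real analysis: exon/intron structures with readable
splice-site dinucleotides, multiple isoforms per gene, mitochondrial and
ribosomal gene flags, and deliberately planted features that let artefact
molecules be simulated with known ground truth:

* ``atract`` genes carry a >=20-nt adenine tract inside their last exon, the
  substrate for intra-priming artefacts;
* ``rt`` genes carry a novel (uncatalogued) donor site whose junction windows
  share an exact 8-mer direct repeat, the substrate for RT-switching;
* ``lcnc`` genes carry one long first intron in which per-molecule novel
  non-canonical donors can be placed (low-coverage non-canonical artefacts);
* one gene has a catalogued non-canonical junction (CT-AC).

Coordinates are 0-based half-open throughout; exon lists are stored in
genomic order regardless of strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CANONICAL_PAIRS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}
_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic order, half-open, non-overlapping
    biotype: str = "protein_coding"

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "protein_coding"
    is_mito: bool = False
    is_ribo: bool = False
    role: str = "regular"
    # role-specific planted features (forward-strand genes only)
    atract_pos: int | None = None          # genomic start of the adenine tract
    rt_donor: int | None = None            # genomic pos of the novel RT donor
    lcnc_candidates: tuple[int, ...] = ()  # valid novel-donor offsets in intron 0


@dataclass
class ReferenceBundle:
    genome: dict[str, str]
    transcripts: dict[str, Transcript]
    genes: dict[str, Gene]
    gene_meta: dict[str, dict]  # gene_id -> {length, gc, is_mito, is_ribo, biotype}

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]

    def genes_on(self, chrom: str, strand: str | None = None) -> list[Gene]:
        return [
            g for g in self.genes.values()
            if g.chrom == chrom and (strand is None or g.strand == strand)
        ]

    def spliced_seq(self, t: Transcript) -> str:
        seq = "".join(self.genome[t.chrom][s:e] for s, e in t.exons)
        return revcomp(seq) if t.strand == "-" else seq

    def junction_dinucleotides(self, t: Transcript) -> list[tuple[str, str]]:
        """(donor, acceptor) dinucleotides of each intron, in transcript order."""
        out = []
        chrom_seq = self.genome[t.chrom]
        introns = list(t.introns)
        if t.strand == "-":
            introns = introns[::-1]
        for a, b in introns:
            if t.strand == "+":
                out.append((chrom_seq[a:a + 2], chrom_seq[b - 2:b]))
            else:
                out.append((revcomp(chrom_seq[b - 2:b]), revcomp(chrom_seq[a:a + 2])))
        return out

    def catalog_sites(self) -> set[tuple[str, str, int, str]]:
        """All reference splice sites as (chrom, strand, position, kind)."""
        sites: set[tuple[str, str, int, str]] = set()
        for t in self.transcripts.values():
            for a, b in t.introns:
                if t.strand == "+":
                    sites.add((t.chrom, t.strand, a, "donor"))
                    sites.add((t.chrom, t.strand, b, "acceptor"))
                else:
                    sites.add((t.chrom, t.strand, b, "donor"))
                    sites.add((t.chrom, t.strand, a, "acceptor"))
        return sites

    def catalog_chains(self) -> dict[tuple[str, str, tuple[tuple[int, int], ...]], str]:
        """Intron chain -> transcript id (multi-exon transcripts only)."""
        chains = {}
        for tid in sorted(self.transcripts):
            t = self.transcripts[tid]
            if t.introns:
                chains.setdefault((t.chrom, t.strand, t.introns), tid)
        return chains


# ---------------------------------------------------------------------------
# generation

_RT_SHIFT = 20          # novel RT donor sits this far inside the last exon0 bases
_ATRACT_LEN = 25
_ATRACT_FROM_END = 150  # tract starts this many nt before the last exon's end
_LCNC_INTRON = 4500


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _plant(arr: np.ndarray, pos: int, seq: str) -> None:
    arr[pos:pos + len(seq)] = np.frombuffer(seq.encode(), dtype="S1")


def _plant_junction(arr: np.ndarray, intron: tuple[int, int], strand: str,
                    pair: tuple[str, str] = ("GT", "AG")) -> None:
    donor, acceptor = pair
    a, b = intron
    if strand == "+":
        _plant(arr, a, donor)
        _plant(arr, b - 2, acceptor)
    else:
        _plant(arr, b - 2, revcomp(donor))
        _plant(arr, a, revcomp(acceptor))


def _gene_roles(cfg) -> list[str]:
    roles = ["mito", "mito", "ribo", "ribo", "noncanonical",
             "mono", "mono", "lnc", "lnc"]
    n_special = cfg.n_artefact_genes_per_role
    if n_special is None:
        n_special = min(6, max(1, cfg.n_genes // 7))
    roles += ["atract"] * n_special + ["rt"] * n_special + ["lcnc"] * n_special
    while len(roles) < cfg.n_genes:
        roles.append("regular")
    return roles[: cfg.n_genes]


def generate_reference(config) -> ReferenceBundle:
    """Build a deterministic toy genome + annotation from the config seed."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0x5EF])

    roles = _gene_roles(config)
    lo, hi = config.min_length_log2, config.max_length_log2

    # per-chromosome byte arrays, grown gene by gene
    chrom_parts: dict[str, list] = {f"chr{i + 1}": [] for i in range(config.n_chromosomes)}
    cursor = {c: 0 for c in chrom_parts}

    transcripts: dict[str, Transcript] = {}
    genes: dict[str, Gene] = {}
    protected: set[tuple[str, int]] = set()  # (chrom, pos) never rewritten

    for gi, role in enumerate(roles):
        gene_id = f"G{gi:03d}"
        chrom = f"chr{gi % config.n_chromosomes + 1}"
        # planted features assume forward-strand coordinates
        strand = "+" if role in ("atract", "rt", "lcnc", "noncanonical") \
            else ("+" if rng.random() < 0.6 else "-")

        lo_g = lo
        if (role in ("atract", "rt", "lcnc")
                and getattr(config, "artefact_gene_min_log2", None) is not None):
            lo_g = config.artefact_gene_min_log2
        spliced_len = int(round(2 ** rng.uniform(lo_g, hi)))
        min_exon = 60
        if role == "mono":
            n_exons = 1
        elif role == "mito":
            n_exons = 1 if gi % 2 else 2
        elif role in ("atract", "rt", "lcnc", "noncanonical"):
            n_exons = 3
        else:
            # adapt exon count to the target length so short genes stay short
            allowed = max(1, spliced_len // (min_exon + 30))
            n_exons = min(int(rng.integers(2, 6)), allowed)

        # split spliced length into exon lengths (min 60 nt each)
        spliced_len = max(spliced_len, n_exons * min_exon + 10)
        cuts = np.sort(rng.uniform(0, 1, size=n_exons - 1)) if n_exons > 1 else np.array([])
        free = spliced_len - n_exons * min_exon
        parts = np.diff(np.concatenate([[0.0], cuts, [1.0]])) * free
        exon_lens = [min_exon + int(p) for p in parts]
        exon_lens[-1] += spliced_len - sum(exon_lens)
        if role == "atract":
            # last exon must hold the tract well before its end
            need = _ATRACT_FROM_END + _ATRACT_LEN + 30
            if exon_lens[-1] < need:
                exon_lens[-1] = need
        if role == "rt" and exon_lens[0] < _RT_SHIFT + 40:
            exon_lens[0] = _RT_SHIFT + 40

        intron_lens = [int(rng.integers(80, 400)) for _ in range(n_exons - 1)]
        if role == "lcnc" and intron_lens:
            intron_lens[0] = _LCNC_INTRON + int(rng.integers(0, 400))

        gene_start = cursor[chrom] + 300
        pos = gene_start
        exons = []
        for k, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if k < len(intron_lens):
                pos += intron_lens[k]
        gene_end = pos

        # materialize this gene's sequence chunk (with the 300 nt gap before it)
        chunk = _random_seq(rng, gene_end - cursor[chrom])
        offset = cursor[chrom]  # chunk[i] is genome position offset + i
        arr_view = chunk  # plant via local coordinates

        def plant_local(p, s, _o=offset, _a=arr_view):
            _plant(_a, p - _o, s)

        tid = f"{gene_id}.T1"
        t1 = Transcript(tid, gene_id, chrom, strand, exons,
                        biotype="lncRNA" if role == "lnc" else "protein_coding")
        introns = list(t1.introns)
        for i, intr in enumerate(introns):
            d, a = ("CT", "AC") if (role == "noncanonical" and i == 0) else ("GT", "AG")
            ia, ib = intr
            if strand == "+":
                plant_local(ia, d)
                plant_local(ib - 2, a)
            else:
                plant_local(ib - 2, revcomp(d))
                plant_local(ia, revcomp(a))
            protected.update(((chrom, ia), (chrom, ia + 1),
                              (chrom, ib - 2), (chrom, ib - 1)))

        gene = Gene(gene_id, chrom, strand, gene_start, gene_end,
                    biotype=t1.biotype,
                    is_mito=(role == "mito"), is_ribo=(role == "ribo"),
                    role=role)

        if role == "atract":
            tract = exons[-1][1] - _ATRACT_FROM_END
            plant_local(tract, "A" * _ATRACT_LEN)
            gene.atract_pos = tract
            protected.update((chrom, p) for p in range(tract, tract + _ATRACT_LEN))
        if role == "rt":
            e0s, e0e = exons[0]
            donor = e0e - _RT_SHIFT
            rep = "".join("ACGT"[i] for i in rng.integers(0, 4, size=8))
            if "A" * 4 in rep:  # avoid accidental polyA-looking repeats
                rep = "CGTTGACC"
            plant_local(donor, "GT")
            plant_local(donor + 2, rep)               # inside novel intron, after GT
            plant_local(introns[0][1], rep)           # first 8 nt of exon 1
            gene.rt_donor = donor
            protected.update((chrom, p) for p in range(donor, donor + 10))
            protected.update((chrom, p)
                             for p in range(introns[0][1], introns[0][1] + 8))

        transcripts[tid] = t1
        genes[gene_id] = gene

        # second isoform: skip one internal exon (multi-exon genes)
        if role in ("regular", "atract", "rt", "lcnc") and n_exons >= 3:
            skip = 1
            exons2 = [e for k, e in enumerate(exons) if k != skip]
            transcripts[f"{gene_id}.T2"] = Transcript(
                f"{gene_id}.T2", gene_id, chrom, strand, exons2, biotype=t1.biotype)

        chrom_parts[chrom].append(chunk)
        cursor[chrom] = gene_end

    genome_ba: dict[str, bytearray] = {}
    for chrom, parts in chrom_parts.items():
        tail = _random_seq(np.random.default_rng([config.seed, 77, len(genome_ba)]), 300)
        parts = parts + [tail]
        genome_ba[chrom] = bytearray(b"".join(p.tobytes() for p in parts))

    _screen_accidental_artefacts(genome_ba, transcripts, protected,
                                 np.random.default_rng([config.seed, 0x5C]))
    genome = {c: bytes(ba).decode() for c, ba in genome_ba.items()}

    # lcnc novel-donor candidates: offsets t in intron 0 where the resulting
    # donor dinucleotide cannot form a canonical pair with the AG acceptor
    for gene in genes.values():
        if gene.role != "lcnc":
            continue
        t1 = transcripts[f"{gene.gene_id}.T1"]
        (a, b) = t1.introns[0]
        seq = genome[gene.chrom]
        cands = []
        for t in range(60, b - a - 60):
            dinuc = seq[a + t:a + t + 2]
            if dinuc not in ("GT", "GC", "AT"):
                cands.append(t)
        gene.lcnc_candidates = tuple(cands)

    gene_meta = {}
    bundle = ReferenceBundle(genome, transcripts, genes, gene_meta)
    for gid in sorted(genes):
        isos = bundle.transcripts_of(gid)
        seqs = [bundle.spliced_seq(t) for t in isos]
        gene_meta[gid] = {
            "length": float(np.mean([len(s) for s in seqs])),
            "gc": float(np.mean([gc_fraction(s) for s in seqs])),
            "is_mito": genes[gid].is_mito,
            "is_ribo": genes[gid].is_ribo,
            "biotype": genes[gid].biotype,
        }
    return bundle


# ---------------------------------------------------------------------------
# accidental-artefact screening
#
# The artefact flags downstream detect direct repeats across junction windows
# and A-rich tracts downstream of 3' ends.  For the ground truth to be clean,
# catalogued junctions must not *accidentally* look like RT-switching sites
# and transcript ends must not sit upstream of chance adenine runs, so the
# generator rewrites such background bases (never touching planted features).

def _kmer_set(s: bytes, k: int) -> set[bytes]:
    return {s[i:i + k] for i in range(len(s) - k + 1)}


def _screen_accidental_artefacts(genome_ba, transcripts, protected, rng,
                                 window: int = 10, k: int = 8) -> None:
    bases = b"ACGT"
    for tid in sorted(transcripts):
        t = transcripts[tid]
        ba = genome_ba[t.chrom]
        for a, b in t.introns:
            for _ in range(40):
                wd = bytes(ba[a - window:a + window])
                wa = bytes(ba[b - window:b + window])
                shared = _kmer_set(wd, k) & _kmer_set(wa, k)
                if not shared:
                    break
                kmer = sorted(shared)[0]
                fixed = False
                for w, origin in ((wd, a - window), (wa, b - window)):
                    i = w.find(kmer)
                    pos = [origin + i + j for j in range(k)
                           if (t.chrom, origin + i + j) not in protected]
                    if pos:
                        p = pos[int(rng.integers(0, len(pos)))]
                        old = ba[p]
                        ba[p] = bases[(bases.index(bytes([old]))
                                       + int(rng.integers(1, 4))) % 4]
                        fixed = True
                        break
                if not fixed:
                    break
        # downstream-of-3'-end adenine screen
        if t.strand == "+":
            lo, hi = t.end, min(len(ba), t.end + 20)
            target = ord("A")
        else:
            lo, hi = max(0, t.start - 20), t.start
            target = ord("T")
        win = list(range(lo, hi))
        a_pos = [p for p in win if ba[p] == target
                 and (t.chrom, p) not in protected]
        n_a = sum(1 for p in win if ba[p] == target)
        while n_a > 9 and a_pos:
            p = a_pos.pop(int(rng.integers(0, len(a_pos))))
            ba[p] = bases[int(rng.integers(0, 3))] if target == ord("T") \
                else ord("CGT"[int(rng.integers(0, 3))])
            n_a -= 1


# ---------------------------------------------------------------------------
# serialization

def write_fasta(bundle: ReferenceBundle, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(bundle.genome):
            fh.write(f">{chrom}\n")
            seq = bundle.genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gtf(bundle: ReferenceBundle, path) -> None:
    def attrs(**kw):
        return " ".join(f'{k} "{v}";' for k, v in kw.items())

    with open(path, "w") as fh:
        for gid in sorted(bundle.genes):
            g = bundle.genes[gid]
            fh.write("\t".join([
                g.chrom, "molmatch", "gene", str(g.start + 1), str(g.end), ".",
                g.strand, ".", attrs(gene_id=gid, gene_type=g.biotype, gene_name=gid),
            ]) + "\n")
            for t in sorted(bundle.transcripts_of(gid), key=lambda t: t.transcript_id):
                fh.write("\t".join([
                    g.chrom, "molmatch", "transcript", str(t.start + 1), str(t.end),
                    ".", g.strand, ".",
                    attrs(gene_id=gid, transcript_id=t.transcript_id,
                          gene_type=g.biotype),
                ]) + "\n")
                for (s, e) in t.exons:
                    fh.write("\t".join([
                        g.chrom, "molmatch", "exon", str(s + 1), str(e), ".",
                        g.strand, ".",
                        attrs(gene_id=gid, transcript_id=t.transcript_id),
                    ]) + "\n")
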