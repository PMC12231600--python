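"""Render ground-truth molecules into platform-specific alignment files.

Short-read dialect: single-end reads from the molecule 3' end (3' gene
expression chemistry), several PCR duplicates per molecule, size-selection
dropout of short molecules, multi-mapping markers, forward-orientation
barcode tags (CB corrected / CR raw, UB corrected / UR raw UMI), TSO
contamination as leading soft-clips or unmapped reads.

Long-read dialect: one full-length read per surviving molecule (the upstream
pipeline deduplicates to one read before mapping), reverse-complemented
barcode/UMI tags (CB/XM), near-complete mapping, most TSO artefacts removed
by the library protocol.  Un-segmented MAS arrays (concatenations of
``mas_segments`` reads joined by known adapters) are emitted alongside.
"""

from __future__ import annotations

import warnings

import numpy as np
import pysam

from molmatch.config import SimConfig
from molmatch.molecules import TrueMolecule
from molmatch.reference import ReferenceBundle, revcomp


def three_prime_sub_blocks(blocks, strand: str, n: int):
    """Sub-blocks covering the 3'-most ``n`` spliced nucleotides."""
    out = []
    need = n
    if strand == "+":
        for s, e in reversed(blocks):
            take = min(e - s, need)
            out.append((e - take, e))
            need -= take
            if need == 0:
                break
        return tuple(reversed(out))
    for s, e in blocks:
        take = min(e - s, need)
        out.append((s, s + take))
        need -= take
        if need == 0:
            break
    return tuple(out)


def blocks_seq(genome: dict[str, str], chrom: str, blocks, strand: str) -> str:
    """Spliced sequence of the blocks in read (5'->3') orientation."""
    seq = "".join(genome[chrom][s:e] for s, e in blocks)
    return revcomp(seq) if strand == "-" else seq


def _cigar(blocks, lead_clip: int, strand: str):
    ops = []
    for i, (s, e) in enumerate(blocks):
        if i:
            ops.append((3, s - blocks[i - 1][1]))  # N
        ops.append((0, e - s))  # M
    if lead_clip:
        clip = (4, lead_clip)
        ops = ([clip] + ops) if strand == "+" else (ops + [clip])
    return ops


def _sam_header(ref: ReferenceBundle) -> pysam.AlignmentHeader:
    sq = [{"SN": c, "LN": len(ref.genome[c])} for c in sorted(ref.genome)]
    return pysam.AlignmentHeader.from_dict({"HD": {"VN": "1.6", "SO": "unsorted"},
                                            "SQ": sq})


def _seq_with_errors(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    s = list(seq)
    for i in range(len(s)):
        if rng.random() < rate:
            s[i] = "ACGT"[("ACGT".index(s[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(s)


def _dropout_prob(length: int, config: SimConfig) -> float:
    """Clamped logistic: certain dropout at/below the midpoint, smooth above."""
    z = (length - config.dropout_length) / config.dropout_scale
    s = min(1.0, 2.0 / (1.0 + np.exp(min(z, 50.0))))
    return config.illumina_short_dropout * s


def render_short_reads(molecules: list[TrueMolecule], ref: ReferenceBundle,
                       config: SimConfig, path) -> int:
    """Write the short-read dialect SAM; returns number of records."""
    if not molecules:
        warnings.warn("no molecules: writing an empty short-read SAM")
    rng = np.random.default_rng([config.seed, 0x51])
    header = _sam_header(ref)
    chrom_ids = {c: i for i, c in enumerate(sorted(ref.genome))}
    tso = config.tso_sequence
    lo, hi = config.pcr_dup_range
    n_written = 0

    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for mol in molecules:
            if rng.random() < _dropout_prob(mol.length, config):
                continue
            k = int(rng.integers(lo, hi + 1))
            body = three_prime_sub_blocks(
                mol.blocks, mol.strand, min(config.short_read_length, mol.length))
            body_fwd = "".join(ref.genome[mol.chrom][s:e] for s, e in body)
            for j in range(k):
                a = pysam.AlignedSegment(header)
                a.query_name = f"mol{mol.molecule_id}_r{j}"
                is_tso = mol.artefact_label == "tso_artifact"
                unmapped = is_tso and rng.random() < config.tso_unmapped_prob
                if unmapped:
                    a.flag = 4
                    a.mapping_quality = 0
                    read_seq = tso + blocks_seq(ref.genome, mol.chrom, body,
                                                mol.strand)
                    a.query_sequence = read_seq
                    nh = 1
                else:
                    clip = len(tso) if is_tso else 0
                    a.flag = 16 if mol.strand == "-" else 0
                    a.reference_id = chrom_ids[mol.chrom]
                    a.reference_start = body[0][0]
                    multi = rng.random() < config.multimap_rate
                    nh = 2 if multi else 1
                    a.mapping_quality = 3 if multi else 255
                    a.cigartuples = _cigar(body, clip, mol.strand)
                    if clip:
                        if mol.strand == "+":
                            a.query_sequence = tso + body_fwd
                        else:
                            a.query_sequence = body_fwd + revcomp(tso)
                    else:
                        a.query_sequence = body_fwd
                a.set_tag("NH", nh)
                raw_bc = _seq_with_errors(rng, mol.cell_barcode,
                                          config.barcode_error_rate)
                a.set_tag("CR", raw_bc)
                if rng.random() >= config.p_missing_cb:
                    a.set_tag("CB", mol.cell_barcode)
                a.set_tag("UR", mol.umi)
                if rng.random() >= config.p_missing_ub:
                    a.set_tag("UB", mol.umi)
                out.write(a)
                n_written += 1
    return n_written


def mas_adapters(config: SimConfig) -> list[str]:
    """Fixed distinct 16-mer adapters, one per junction position."""
    rng = np.random.default_rng([config.seed, 0xADA])
    adapters = []
    seen = set()
    while len(adapters) < max(1, config.mas_segments - 1):
        a = "".join("ACGT"[b] for b in rng.integers(0, 4, size=16))
        if a not in seen:
            seen.add(a)
            adapters.append(a)
    return adapters


def render_long_reads(molecules: list[TrueMolecule], ref: ReferenceBundle,
                      config: SimConfig, path, array_path=None) -> int:
    """Write the long-read dialect SAM (and optional MAS array FASTA)."""
    if not molecules:
        warnings.warn("no molecules: writing an empty long-read SAM")
    rng = np.random.default_rng([config.seed, 0x52])
    header = _sam_header(ref)
    chrom_ids = {c: i for i, c in enumerate(sorted(ref.genome))}
    n_written = 0
    read_seqs: list[tuple[str, str]] = []

    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for mol in molecules:
            if (mol.artefact_label == "tso_artifact"
                    and rng.random() < config.tso_removal_efficiency):
                continue
            a = pysam.AlignedSegment(header)
            a.query_name = f"mol{mol.molecule_id}"
            seq_fwd = "".join(ref.genome[mol.chrom][s:e] for s, e in mol.blocks)
            if rng.random() < config.long_unmapped_rate:
                a.flag = 4
                a.mapping_quality = 0
                a.query_sequence = blocks_seq(ref.genome, mol.chrom, mol.blocks,
                                              mol.strand)
            else:
                a.flag = 16 if mol.strand == "-" else 0
                a.reference_id = chrom_ids[mol.chrom]
                a.reference_start = mol.blocks[0][0]
                a.mapping_quality = 60
                a.cigartuples = _cigar(mol.blocks, 0, mol.strand)
                a.query_sequence = seq_fwd
            a.set_tag("NH", 1)
            a.set_tag("CB", revcomp(mol.cell_barcode))
            a.set_tag("XM", revcomp(mol.umi))
            out.write(a)
            n_written += 1
            read_seqs.append((a.query_name,
                              blocks_seq(ref.genome, mol.chrom, mol.blocks,
                                         mol.strand)))

    if array_path is not None:
        adapters = mas_adapters(config)
        with open(array_path, "w") as fh:
            for i in range(0, len(read_seqs), config.mas_segments):
                chunk = read_seqs[i:i + config.mas_segments]
                parts = []
                for j, (_qn, s) in enumerate(chunk):
                    if j:
                        parts.append(adapters[(j - 1) % len(adapters)])
                    parts.append(s)
                fh.write(f">array{i // config.mas_segments}\n")
                fh.write("".join(parts) + "\n")
    return n_written
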