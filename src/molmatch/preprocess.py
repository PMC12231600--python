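"""Normalize both platforms' alignment records into per-molecule units.

The unit of comparison is the tag ID: the 16-mer cell barcode concatenated
with the 12-mer UMI, in canonical forward orientation.  The long-read
dialect stores both tags reverse-complemented, so canonicalization applies
the (involutive) reverse complement there.  Each platform also has its own
barcode-correction dialect and its own deduplication rule: the short-read
side keeps one read per tag hierarchically (counted > random mapped >
unmapped), the long-read side keeps the longest aligned read.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import edlib
import pysam

from molmatch.config import BARCODE_LEN, UMI_LEN
from molmatch.reference import revcomp


@dataclass
class ReadRecord:
    platform: str                 # "short" | "long"
    query_name: str
    mapped: bool
    chrom: str | None
    start: int
    blocks: tuple[tuple[int, int], ...]
    strand: str
    mapq: int
    alignment_count: int
    raw_barcode: str | None
    corrected_barcode: str | None
    raw_umi: str | None
    corrected_umi: str | None
    leading_softclip_seq: str = ""
    sequence: str = ""            # read orientation (5'->3' as sequenced)
    counted: bool = False
    tag_key: str | None = None

    @property
    def aligned_length(self) -> int:
        return sum(e - s for s, e in self.blocks)

    @property
    def end(self) -> int:
        return self.blocks[-1][1] if self.blocks else self.start


@dataclass(frozen=True)
class TagID:
    barcode: str
    umi: str

    @property
    def key(self) -> str:
        return self.barcode + self.umi


# ---------------------------------------------------------------------------
# SAM loading

def _record_from_segment(a: pysam.AlignedSegment, platform: str) -> ReadRecord:
    mapped = not a.is_unmapped
    blocks: tuple = ()
    lead_clip = ""
    if mapped:
        blocks = tuple(a.get_blocks())
        ct = a.cigartuples or []
        # leading soft clip in read orientation
        if a.is_reverse:
            if ct and ct[-1][0] == 4:
                lead_clip = revcomp(a.query_sequence[-ct[-1][1]:])
        else:
            if ct and ct[0][0] == 4:
                lead_clip = a.query_sequence[:ct[0][1]]
    seq = a.get_forward_sequence() or ""

    def tag(name):
        return a.get_tag(name) if a.has_tag(name) else None

    if platform == "short":
        raw_bc, cor_bc = tag("CR"), tag("CB")
        raw_umi, cor_umi = tag("UR"), tag("UB")
    else:
        raw_bc, cor_bc = tag("CB"), tag("CB")
        raw_umi, cor_umi = tag("XM"), tag("XM")
    return ReadRecord(
        platform=platform,
        query_name=a.query_name,
        mapped=mapped,
        chrom=a.reference_name if mapped else None,
        start=a.reference_start if mapped else -1,
        blocks=blocks,
        strand="-" if (mapped and a.is_reverse) else "+",
        mapq=a.mapping_quality,
        alignment_count=int(tag("NH") or 1),
        raw_barcode=raw_bc,
        corrected_barcode=cor_bc,
        raw_umi=raw_umi,
        corrected_umi=cor_umi,
        leading_softclip_seq=lead_clip,
        sequence=seq,
    )


def load_sam(path, platform: str) -> list[ReadRecord]:
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_secondary or a.is_supplementary:
                continue
            records.append(_record_from_segment(a, platform))
    return records


# ---------------------------------------------------------------------------
# MAS array segmentation

@dataclass
class SegmentationResult:
    segments: list[str]
    warnings: int = 0


def segment_array(array_read: str, adapters: list[str]) -> SegmentationResult:
    """Split a concatenated array on exact adapter occurrences, in order.

    Returns the maximal adapter-free substrings between adapter hits.  A
    missing adapter followed by a later adapter hit counts as a corrupt
    junction (warning); missing trailing adapters simply mean a shorter
    array.
    """
    if not adapters:
        raise ValueError("adapter list is empty")
    if len(set(adapters)) != len(adapters):
        raise ValueError("adapters must be mutually distinct")
    segments: list[str] = []
    warnings = 0
    pos = 0
    for i, ad in enumerate(adapters):
        hit = array_read.find(ad, pos)
        if hit < 0:
            # corrupt only if some later adapter is still present
            later = next((array_read.find(a2, pos) for a2 in adapters[i + 1:]
                          if array_read.find(a2, pos) >= 0), -1)
            if later >= 0:
                warnings += 1
                continue
            break
        segments.append(array_read[pos:hit])
        pos = hit + len(ad)
    segments.append(array_read[pos:])
    return SegmentationResult([s for s in segments if s], warnings)


# ---------------------------------------------------------------------------
# barcode correction

_Q_DEFAULT_ERR = 0.001


def _check16(observed: str) -> None:
    if len(observed) != BARCODE_LEN:
        raise ValueError(f"barcode must be {BARCODE_LEN} nt, got {len(observed)}")


def correct_barcode_short(observed: str, whitelist, base_qualities=None):
    """Short-read dialect: exact, else unique 1-Hamming neighbour, else the
    highest-posterior 1-Hamming candidate under a per-base error model."""
    _check16(observed)
    wl = whitelist if isinstance(whitelist, (set, frozenset, dict)) else set(whitelist)
    if not wl:
        raise ValueError("whitelist is empty")
    if observed in wl:
        return observed
    candidates = []
    for i, base in enumerate(observed):
        for b in "ACGT":
            if b == base:
                continue
            cand = observed[:i] + b + observed[i + 1:]
            if cand in wl:
                err = (10 ** (-base_qualities[i] / 10)
                       if base_qualities is not None else _Q_DEFAULT_ERR)
                abundance = wl[cand] if isinstance(wl, dict) else 1.0
                candidates.append((abundance * err / 3.0, cand))
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0][1]
    candidates.sort(key=lambda c: (-c[0], c[1]))
    return candidates[0][1]


class LongBarcodeCorrector:
    """Long-read dialect: whitelist entry with the lowest Levenshtein
    distance (ties by Hamming, then lexicographic), accepted only below 2."""

    def __init__(self, whitelist):
        self.whitelist = sorted(set(whitelist))
        if not self.whitelist:
            raise ValueError("whitelist is empty")
        self._exact = set(self.whitelist)
        self._cache: dict[str, str | None] = {}

    def __call__(self, observed: str):
        _check16(observed)
        if observed in self._exact:
            return observed
        if observed in self._cache:
            return self._cache[observed]
        best = None  # (lev, hamming, barcode)
        for w in self.whitelist:
            lev = edlib.align(observed, w, task="distance", k=2)["editDistance"]
            if lev < 0:
                continue
            ham = (sum(a != b for a, b in zip(observed, w))
                   if len(w) == len(observed) else len(w))
            cand = (lev, ham, w)
            if best is None or cand < best:
                best = cand
        result = best[2] if best is not None and best[0] <= 1 else None
        self._cache[observed] = result
        return result


def correct_barcode_long(observed: str, whitelist):
    return LongBarcodeCorrector(whitelist)(observed)


# ---------------------------------------------------------------------------
# tag resolution

def resolve_umi(record: ReadRecord) -> str:
    """Corrected UMI if present, else the raw sequencer-reported UMI."""
    if record.corrected_umi is not None:
        return record.corrected_umi
    if record.raw_umi is not None:
        return record.raw_umi
    raise ValueError(f"record {record.query_name} carries no UMI tag")


def canonical_barcode(record: ReadRecord) -> str | None:
    bc = record.corrected_barcode or record.raw_barcode
    if bc is None:
        return None
    return revcomp(bc) if record.platform == "long" else bc


def canonical_tag(record: ReadRecord) -> TagID:
    """Canonical forward-orientation tag ID (barcode ++ UMI key)."""
    bc = canonical_barcode(record)
    if bc is None:
        raise ValueError(f"record {record.query_name} has no resolvable barcode")
    umi = resolve_umi(record)
    if record.platform == "long":
        umi = revcomp(umi)
    return TagID(bc, umi)


def subsample_by_prefix(records, prefix: str):
    """Keep records whose canonical barcode starts with ``prefix``."""
    if len(prefix) > BARCODE_LEN:
        raise ValueError("prefix longer than a barcode")
    if not prefix:
        return list(records)
    out = []
    for r in records:
        bc = canonical_barcode(r)
        if bc is not None and bc.startswith(prefix):
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# deduplication

def _seeded_index(seed: int, key: str, n: int) -> int:
    h = hashlib.blake2b(f"{seed}:{key}".encode(), digest_size=8).digest()
    return int.from_bytes(h, "big") % n


def dedup_short(groups: dict[str, list[ReadRecord]], seed: int) -> dict[str, ReadRecord]:
    """One survivor per tag: counted+mapped, else seeded-random mapped,
    else the unmapped read."""
    survivors: dict[str, ReadRecord] = {}
    for key in groups:
        group = groups[key]
        if not group:
            raise ValueError(f"empty read group for tag {key}")
        counted = sorted((r for r in group if r.mapped and r.counted),
                         key=lambda r: r.query_name)
        if counted:
            pool = counted
        else:
            mapped = sorted((r for r in group if r.mapped),
                            key=lambda r: r.query_name)
            if mapped:
                pool = mapped
            else:
                pool = sorted(group, key=lambda r: r.query_name)
        survivors[key] = pool[_seeded_index(seed, key, len(pool))] \
            if len(pool) > 1 else pool[0]
    return survivors


def dedup_long(groups: dict[str, list[ReadRecord]]) -> dict[str, ReadRecord]:
    """One survivor per tag: maximal aligned length, ties by query name."""
    survivors: dict[str, ReadRecord] = {}
    for key, group in groups.items():
        if not group:
            raise ValueError(f"empty read group for tag {key}")
        survivors[key] = min(group, key=lambda r: (-r.aligned_length, r.query_name))
    return survivors


def group_by_tag(records, whitelist=None, prefix: str = "") -> tuple[dict, dict]:
    """Correct barcodes where needed, canonicalize tags, group records.

    Returns (groups keyed by tag key, exclusion counts by reason).
    """
    excluded = {"no_barcode": 0, "uncorrectable": 0, "no_umi": 0}
    long_corr = LongBarcodeCorrector(whitelist) if whitelist is not None else None
    wl = set(whitelist) if whitelist is not None else None
    groups: dict[str, list[ReadRecord]] = {}
    for r in records:
        if r.corrected_barcode is None and r.raw_barcode is not None and wl is not None:
            if r.platform == "short":
                r.corrected_barcode = correct_barcode_short(r.raw_barcode, wl)
            else:
                observed = revcomp(r.raw_barcode)
                fixed = long_corr(observed)
                r.corrected_barcode = revcomp(fixed) if fixed else None
        bc = canonical_barcode(r)
        if bc is None:
            excluded["no_barcode"] += 1
            continue
        if wl is not None and bc not in wl:
            excluded["uncorrectable"] += 1
            continue
        if prefix and not bc.startswith(prefix):
            continue
        try:
            tag = canonical_tag(r)
        except ValueError:
            excluded["no_umi"] += 1
            continue
        r.tag_key = tag.key
        groups.setdefault(tag.key, []).append(r)
    return groups, excluded
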