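"""Tag canonicalization, barcode-correction dialects, segmentation, dedup."""

import collections

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molmatch.preprocess import (LongBarcodeCorrector, TagID, canonical_tag,
                                 correct_barcode_long, correct_barcode_short,
                                 dedup_long, dedup_short, group_by_tag,
                                 resolve_umi, segment_array,
                                 subsample_by_prefix)
from molmatch.reference import revcomp
from tests.conftest import make_record

DNA = st.text(alphabet="ACGT", min_size=1, max_size=40)


# ---------------------------------------------------------------------------
# array segmentation

def test_segment_single_junction():
    res = segment_array("AAAA" + "CGCGCGCG" + "TTTT", ["CGCGCGCG"])
    assert res.segments == ["AAAA", "TTTT"]
    assert res.warnings == 0


def test_segment_roundtrip_through_renderer(run, tmp_path):
    from molmatch.render import mas_adapters, render_long_reads
    cfg = run.config
    adapters = mas_adapters(cfg)
    arrays = {}
    # re-render a small array file for the round trip
    sub = [m for m in run.molecules if m.artefact_label == "none"][:32]
    from molmatch.config import SimConfig
    cfg2 = SimConfig(**{**cfg.to_dict(), "long_unmapped_rate": 0.0})
    render_long_reads(sub, run.ref, cfg2, tmp_path / "l.sam",
                      tmp_path / "arr.fa")
    name = None
    for line in open(tmp_path / "arr.fa"):
        if line.startswith(">"):
            name = line.strip()[1:]
        else:
            arrays[name] = line.strip()
    assert arrays
    for seq in arrays.values():
        res = segment_array(seq, adapters)
        assert res.warnings == 0
        # reconstruction: joining segments with the adapters restores input
        parts = []
        for j, s in enumerate(res.segments):
            if j:
                parts.append(adapters[j - 1])
            parts.append(s)
        assert "".join(parts) == seq


def test_segment_missing_adapter_warns():
    a1, a2, a3 = "ACACACACACAC", "GTGTGTGTGTGT", "CTCTCTCTCTCT"
    arr = "AAA" + a1 + "CCC" + "GGG" + a3 + "TTT"  # a2 absent
    res = segment_array(arr, [a1, a2, a3])
    assert res.warnings == 1
    assert res.segments[0] == "AAA"


def test_segment_rejects_bad_adapters():
    with pytest.raises(ValueError):
        segment_array("ACGT", [])
    with pytest.raises(ValueError):
        segment_array("ACGT", ["AA", "AA"])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.text(alphabet="AC", min_size=3, max_size=12),
                min_size=2, max_size=6))
def test_segment_roundtrip_property(segments):
    # adapters contain G, segments are A/C-only, so hits are unambiguous
    adapters = ["GGGG" + format(i, "04b").replace("0", "T").replace("1", "G")
                for i in range(len(segments) - 1)]
    arr = segments[0]
    for ad, seg in zip(adapters, segments[1:]):
        arr += ad + seg
    res = segment_array(arr, adapters)
    assert res.segments == segments
    assert res.warnings == 0


# ---------------------------------------------------------------------------
# barcode correction

WL = ["A" * 16, "C" * 16, "G" * 16, "A" * 8 + "C" * 8]


def test_short_correction_identity():
    assert correct_barcode_short("A" * 16, WL) == "A" * 16


def test_short_correction_single_mismatch():
    obs = "A" * 15 + "G"
    assert correct_barcode_short(obs, WL) == "A" * 16


def test_short_correction_distance_two_fails():
    obs = "A" * 14 + "GG"
    assert correct_barcode_short(obs, WL) is None


def test_short_correction_posterior_tie_break():
    # observed is 1-Hamming from two entries mismatching at different
    # positions; the low-quality position is the likelier sequencing error
    wl = ["C" + "A" * 15, "A" * 15 + "C"]
    obs = "A" * 16
    quals = [40] * 15 + [3]  # last base unreliable
    assert correct_barcode_short(obs, wl, quals) == "A" * 15 + "C"
    quals2 = [3] + [40] * 15  # first base unreliable
    assert correct_barcode_short(obs, wl, quals2) == "C" + "A" * 15


def test_short_correction_rejects_bad_length():
    with pytest.raises(ValueError):
        correct_barcode_short("ACGT", WL)


def test_long_correction_identity_and_single_edit():
    assert correct_barcode_long("A" * 16, WL) == "A" * 16
    assert correct_barcode_long("A" * 15 + "G", WL) == "A" * 16


def test_long_correction_two_edits_rejected():
    assert correct_barcode_long("A" * 14 + "GG", WL) is None


def test_long_correction_never_exceeds_distance_one():
    import edlib
    corr = LongBarcodeCorrector(WL)
    out = corr("AACCAACCAACCAACC")
    if out is not None:
        assert edlib.align(out, "AACCAACCAACCAACC")["editDistance"] <= 1


# ---------------------------------------------------------------------------
# UMI resolution and canonical tags

def test_resolve_umi_prefers_corrected():
    r = make_record(corrected_umi="G" * 12, raw_umi="T" * 12)
    assert resolve_umi(r) == "G" * 12


def test_resolve_umi_substitutes_raw():
    r = make_record(corrected_umi=None, raw_umi="T" * 12)
    assert resolve_umi(r) == "T" * 12


def test_resolve_umi_error_when_absent():
    r = make_record(corrected_umi=None, raw_umi=None)
    with pytest.raises(ValueError):
        resolve_umi(r)


def test_canonical_tag_short_concatenation():
    r = make_record(corrected_barcode="ACGT" * 4, corrected_umi="AAAC" * 3)
    tag = canonical_tag(r)
    assert tag.key == "ACGT" * 4 + "AAAC" * 3
    assert len(tag.key) == 28


def test_canonical_tag_long_involution():
    bc, umi = "ACGTACGTACGTACGT", "ACGTACGTACGT"
    r = make_record(platform="long", corrected_barcode=revcomp(bc),
                    raw_barcode=revcomp(bc), corrected_umi=revcomp(umi),
                    raw_umi=revcomp(umi))
    tag = canonical_tag(r)
    assert tag == TagID(bc, umi)


def test_cross_platform_tags_identical(run):
    """The same molecule rendered by both platforms yields the same tag."""
    shared = run.sharing.shared
    truth = {m.tag_key for m in run.molecules}
    assert shared <= truth
    assert len(shared) > 1000


# ---------------------------------------------------------------------------
# prefix subsampling

def test_prefix_empty_is_identity():
    recs = [make_record(query_name=f"q{i}") for i in range(5)]
    assert subsample_by_prefix(recs, "") == recs


def test_prefix_filters_by_barcode():
    recs = [make_record(corrected_barcode="AA" + "C" * 14),
            make_record(corrected_barcode="GC" + "A" * 14),
            make_record(corrected_barcode="TT" + "T" * 14)]
    kept = subsample_by_prefix(recs, "AA")
    assert len(kept) == 1
    assert kept[0].corrected_barcode.startswith("AA")


def test_prefix_fraction_binomial(run):
    # barcodes are uniform random, so P(prefix AA) = 1/16 per barcode
    import numpy as np
    barcodes = {m.cell_barcode for m in run.molecules}
    n = len(barcodes)
    assert n >= 300
    frac = sum(b.startswith("AA") for b in barcodes) / n
    p = 1 / 16
    assert abs(frac - p) <= 4 * np.sqrt(p * (1 - p) / n)


# ---------------------------------------------------------------------------
# deduplication

def _group(*recs):
    return {"T" * 28: list(recs)}


def test_dedup_short_prefers_counted():
    a = make_record(query_name="a", counted=True)
    b = make_record(query_name="b")
    c = make_record(query_name="c", mapped=False, blocks=(), chrom=None)
    out = dedup_short(_group(a, b, c), seed=0)
    assert out["T" * 28] is a


def test_dedup_short_unmapped_fallback():
    c = make_record(query_name="c", mapped=False, blocks=(), chrom=None)
    out = dedup_short(_group(c), seed=0)
    assert out["T" * 28] is c


def test_dedup_short_empty_group_errors():
    with pytest.raises(ValueError):
        dedup_short({"T" * 28: []}, seed=0)


def test_dedup_short_random_choice_uniform():
    """Seeded tie-break between two mapped reads is uniform over tags."""
    hits = 0
    n = 10000
    for i in range(n):
        key = f"{i:028d}"
        a = make_record(query_name="a")
        b = make_record(query_name="b")
        out = dedup_short({key: [a, b]}, seed=123)
        hits += out[key].query_name == "a"
    assert abs(hits / n - 0.5) <= 0.015


def test_dedup_short_order_independent():
    a = make_record(query_name="a")
    b = make_record(query_name="b")
    k = "G" * 28
    out1 = dedup_short({k: [a, b]}, seed=5)[k].query_name
    out2 = dedup_short({k: [b, a]}, seed=5)[k].query_name
    assert out1 == out2


def test_dedup_long_prefers_longest():
    a = make_record(query_name="a", blocks=((0, 800),))
    b = make_record(query_name="b", blocks=((0, 600),))
    out = dedup_long(_group(a, b))
    assert out["T" * 28] is a


def test_dedup_long_tie_breaks_by_name():
    a = make_record(query_name="b", blocks=((0, 700),))
    b = make_record(query_name="a", blocks=((100, 800),))
    out = dedup_long(_group(a, b))
    assert out["T" * 28].query_name == "a"


def test_dedup_one_record_per_tag(run):
    """Dedup keeps the tag set and yields exactly one record per tag."""
    assert len(run.short_survivors) == len(set(run.short_survivors))
    for key, rec in list(run.short_survivors.items())[:200]:
        assert rec.tag_key == key
    for key, rec in list(run.long_survivors.items())[:200]:
        assert rec.tag_key == key
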