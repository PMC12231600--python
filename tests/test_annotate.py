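"""Dual annotation: region classes, splice compatibility, isoform taxonomy,
artefact flags and the crosswalk."""

import collections

import pandas as pd
import pytest

from molmatch.annotate import (Isoform, classify_and_flag, classify_isoform,
                               classify_short, collapse_isoforms, crosswalk,
                               flag_intrapriming, flag_lcnc, flag_rtswitch,
                               junction_chain, splice_compatible)
from tests.conftest import make_record
from tests.toy import iso, toy_reference, truth_table


@pytest.fixture(scope="module")
def toy():
    return toy_reference()


# ---------------------------------------------------------------------------
# short-read vocabulary

def test_classify_short_exonic_unique(toy):
    r = make_record(chrom="toy", blocks=((110, 190),))
    assert classify_short(r, toy) == ("exonic", "unique")


def test_classify_short_intronic(toy):
    r = make_record(chrom="toy", blocks=((210, 290),))
    assert classify_short(r, toy) == ("intronic", "unique")


def test_classify_short_intergenic_and_unmapped(toy):
    r = make_record(chrom="toy", blocks=((1200, 1290),))
    assert classify_short(r, toy)[0] == "intergenic"
    u = make_record(mapped=False, blocks=(), chrom=None)
    assert classify_short(u, toy)[0] == "unmapped"


def test_classify_short_multimapped(toy):
    r = make_record(chrom="toy", blocks=((110, 190),), alignment_count=2,
                    mapq=3)
    assert classify_short(r, toy) == ("exonic", "multimapped")


def test_splice_compatible_cases(toy):
    spliced = make_record(chrom="toy", blocks=((150, 200), (300, 350)))
    assert splice_compatible(spliced, toy)
    unspliced = make_record(chrom="toy", blocks=((150, 250),))
    assert not splice_compatible(unspliced, toy)
    wrong_gap = make_record(chrom="toy", blocks=((150, 200), (320, 350)))
    assert not splice_compatible(wrong_gap, toy)


def test_splice_compatible_on_simulated_truth(run):
    """Reads of unspliced molecules are incompatible with reference
    splicing; reads of clean spliced molecules are compatible."""
    truth = {m.tag_key: m for m in run.molecules}
    frac = {"none": [], "unspliced": []}
    for key, rec in run.short_survivors.items():
        m = truth.get(key)
        if m is None or not rec.mapped:
            continue
        if m.artefact_label in frac:
            frac[m.artefact_label].append(splice_compatible(rec, run.ref))
    assert len(frac["unspliced"]) > 100
    assert sum(frac["unspliced"]) / len(frac["unspliced"]) < 0.1
    assert sum(frac["none"]) / len(frac["none"]) > 0.9


# ---------------------------------------------------------------------------
# collapse

def test_collapse_merges_close_ends():
    a = make_record(query_name="a", blocks=((100, 200), (300, 400)),
                    tag_key="t1")
    b = make_record(query_name="b", blocks=((110, 200), (300, 395)),
                    tag_key="t2")
    isos = collapse_isoforms([a, b])
    assert len(isos) == 1
    assert isos[0].coverage == 2


def test_collapse_splits_on_chain_difference():
    a = make_record(query_name="a", blocks=((100, 200), (300, 400)))
    b = make_record(query_name="b", blocks=((100, 200), (310, 400)))
    assert len(collapse_isoforms([a, b])) == 2


def test_collapse_splits_on_distant_ends():
    a = make_record(query_name="a", blocks=((100, 200), (300, 400)))
    b = make_record(query_name="b", blocks=((100, 200), (300, 600)))
    assert len(collapse_isoforms([a, b], 50, 50)) == 2


def test_collapse_identical_reads_one_isoform():
    recs = [make_record(query_name=f"r{i}", blocks=((100, 200), (300, 400)),
                        tag_key=f"t{i}") for i in range(7)]
    isos = collapse_isoforms(recs)
    assert len(isos) == 1
    assert isos[0].coverage == 7


def test_collapse_mono_exon_reciprocal_overlap():
    a = make_record(query_name="a", blocks=((100, 300),))
    b = make_record(query_name="b", blocks=((150, 320),))   # >50% reciprocal
    c = make_record(query_name="c", blocks=((290, 600),))   # <50%
    assert len(collapse_isoforms([a, b, c])) == 2


# ---------------------------------------------------------------------------
# isoform taxonomy

def test_truth_table(toy):
    for isoform, expected in truth_table():
        got = classify_isoform(isoform, toy)
        assert got.category == expected, (isoform.chain, got.category)


def test_fsm_matches_transcript(toy):
    cls = classify_isoform(iso([(200, 300), (400, 500), (600, 700)],
                               100, 800), toy)
    assert cls.matched_transcript_id == "A.T1"
    assert cls.matched_gene_id == "A"


def test_classification_is_total_on_pipeline(run):
    cats = {c.category for c in run.classifications.values()}
    assert cats <= {"FSM", "ISM", "NIC", "NNC", "genic", "intergenic",
                    "fusion"}
    assert len(run.classifications) == len(run.isoforms)


# ---------------------------------------------------------------------------
# artefact flags

def _flag_ref():
    # genome with an A-tract at 500-540 and a planted junction repeat
    seq = bytearray(b"C" * 2000)
    seq[500:540] = b"A" * 40
    return {"toy": bytes(seq).decode()}


def test_intrapriming_pure_a_downstream():
    genome = _flag_ref()
    i = iso([], 400, 500)  # 3' end at 500, downstream = A*20
    assert flag_intrapriming(i, genome)


def test_intrapriming_half_a_downstream():
    seq = bytearray(b"C" * 1000)
    seq[500:510] = b"A" * 10  # 10 A in the 20-nt window: fraction 0.5
    genome = {"toy": bytes(seq).decode()}
    assert not flag_intrapriming(iso([], 400, 500), genome)


def test_intrapriming_minus_strand():
    seq = bytearray(b"C" * 1000)
    seq[380:400] = b"T" * 20  # upstream of start; revcomp gives A*20
    genome = {"toy": bytes(seq).decode()}
    i = Isoform("I", "toy", "-", (), 400, 600, ["t"])
    assert flag_intrapriming(i, genome)


def test_rtswitch_planted_repeat():
    seq = bytearray(b"C" * 1000)
    rep = b"ACGTTGCA"
    seq[195:203] = rep   # donor window of intron (200, 400)
    seq[395:403] = rep   # acceptor window
    genome = {"toy": bytes(seq).decode()}
    assert flag_rtswitch(iso([(200, 400)], 100, 500), genome)


def test_rtswitch_no_repeat():
    seq = bytearray(b"ACGT" * 250)  # periodic: every 8-mer repeats everywhere
    seq[190:210] = b"AACCGGTTAACCGGTTAACC"
    seq[390:410] = b"CATGCATGCATGCATGCATG"
    genome = {"toy": bytes(seq).decode()}
    assert not flag_rtswitch(iso([(200, 400)], 100, 500), genome)


def test_lcnc_coverage_boundary(toy):
    # junction 200-520: acceptor 520 is uncatalogued; dinucleotides in the
    # toy genome are C* (non-canonical)
    low = iso([(200, 520)], 120, 600, tags=2, iso_id="L")
    assert flag_lcnc(low, [low], toy, min_coverage=3)
    high = iso([(200, 520)], 120, 600, tags=3, iso_id="H")
    assert not flag_lcnc(high, [high], toy, min_coverage=3)
    # coverage shared across isoforms with the same site counts together
    assert not flag_lcnc(low, [low, iso([(200, 520)], 130, 610, tags=1,
                                        iso_id="X")], toy, min_coverage=3)


def test_canonical_junction_never_lcnc(toy):
    fsm = iso([(200, 300), (400, 500), (600, 700)], 100, 800, tags=1)
    assert not flag_lcnc(fsm, [fsm], toy, min_coverage=3)


def test_fsm_never_flagged_lcnc(run):
    for iso_id, cls in run.classifications.items():
        if cls.category == "FSM":
            assert "lcnc" not in cls.artefact_flags


def test_junction_chain_canonical_flags(toy):
    # toy genome has GT..AG planted at gene A introns
    chain = junction_chain("toy", "+", ((200, 300), (400, 500)), toy.genome)
    assert chain.canonical == [True, True]
    chain2 = junction_chain("toy", "+", ((210, 310),), toy.genome)
    assert chain2.canonical == [False]


# ---------------------------------------------------------------------------
# crosswalk

def test_crosswalk_single_cell():
    df = pd.DataFrame({"tag": [f"t{i}" for i in range(10)],
                       "short_class": ["exonic"] * 10,
                       "long_class": ["FSM"] * 10})
    table = crosswalk(df)
    assert table.loc["exonic", "FSM"] == 10
    assert int(table.to_numpy().sum()) == 10


def test_crosswalk_unmapped_and_conservation():
    df = pd.DataFrame({
        "tag": ["a", "b", "c"],
        "short_class": ["unmapped", "exonic", "intronic"],
        "long_class": ["FSM", "discarded", "genic"]})
    table = crosswalk(df)
    assert table.loc["unmapped", "FSM"] == 1
    assert int(table.to_numpy().sum()) == 3


def test_crosswalk_marginals_conserve_tags(run):
    assert int(run.crosswalk.to_numpy().sum()) == len(run.sharing.shared)
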