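"""Hand-built toy annotation covering every isoform category.

Synthetic stand-in for a reference bundle, constructed by hand so that the
expected classification of every test isoform is known by enumeration.
"""

from molmatch.annotate import Isoform
from molmatch.reference import Gene, ReferenceBundle, Transcript, revcomp


def toy_reference() -> ReferenceBundle:
    n = 4000
    seq = bytearray(b"C" * n)

    def plant(pos, s):
        seq[pos:pos + len(s)] = s.encode()

    # gene A (+): exons 100-200, 300-400, 500-600, 700-800
    exons_a = [(100, 200), (300, 400), (500, 600), (700, 800)]
    for a, b in [(200, 300), (400, 500), (600, 700)]:
        plant(a, "GT")
        plant(b - 2, "AG")
    # gene B (+): exons 2000-2100, 2200-2300
    exons_b = [(2000, 2100), (2200, 2300)]
    plant(2100, "GT")
    plant(2198, "AG")
    # gene M (+): mono-exon 3000-3300
    genome = {"toy": bytes(seq).decode()}

    transcripts = {
        "A.T1": Transcript("A.T1", "A", "toy", "+", exons_a),
        "B.T1": Transcript("B.T1", "B", "toy", "+", exons_b),
        "M.T1": Transcript("M.T1", "M", "toy", "+", [(3000, 3300)]),
    }
    genes = {
        "A": Gene("A", "toy", "+", 100, 800),
        "B": Gene("B", "toy", "+", 2000, 2300),
        "M": Gene("M", "toy", "+", 3000, 3300),
    }
    bundle = ReferenceBundle(genome, transcripts, genes, {})
    for gid in genes:
        isos = bundle.transcripts_of(gid)
        bundle.gene_meta[gid] = {
            "length": float(sum(t.spliced_length for t in isos) / len(isos)),
            "gc": 0.5, "is_mito": False, "is_ribo": False,
            "biotype": "protein_coding"}
    return bundle


def iso(chain, start, end, tags=1, iso_id="I0") -> Isoform:
    return Isoform(iso_id, "toy", "+", tuple(chain), start, end,
                   [f"tag{i}" for i in range(tags)])


# (isoform, expected category) pairs enumerating the taxonomy
def truth_table():
    return [
        (iso([(200, 300), (400, 500), (600, 700)], 100, 800), "FSM"),
        (iso([(400, 500), (600, 700)], 350, 800), "ISM"),
        (iso([(200, 500)], 120, 600), "NIC"),        # known donor + acceptor, novel combo
        (iso([(200, 520)], 120, 600), "NNC"),        # acceptor 520 unknown
        (iso([], 150, 350), "genic"),                # exon+intron, no junctions
        (iso([], 1200, 1300), "intergenic"),
        (iso([(200, 300), (2100, 2200)], 100, 2300), "fusion"),
        (iso([], 3010, 3290), "FSM"),                # mono-exon reference match
    ]
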