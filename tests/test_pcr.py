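import pytest

from silico16s.genefinder import GeneHit
from silico16s.iupac import reverse_complement
from silico16s.pcr import (
    AmbiguousReferenceMatch,
    PrimerPair,
    amplify_all,
    amplify_gene,
    bundled_primer_pairs,
    classify_length_category,
    inclusive_span_length,
    locate_on_reference,
    paper_span_length,
)


def _gene(seq, uid="u1"):
    return GeneHit(unit_id=uid, start=0, end=len(seq), strand="+", sequence=seq)


def _pair(fwd, rev_site, pid="p1"):
    # rev primer is written 5'->3' on the antisense strand: the sequence
    # whose reverse complement is the sense-strand binding site
    return PrimerPair(
        pair_id=pid, fwd_id="F", fwd_seq=fwd, rev_id="R",
        rev_seq=reverse_complement(rev_site),
    )


def test_amplicon_spans_leftmost_forward_to_rightmost_reverse():
    #          0123456789012345
    gene = _gene("TTAAGGCCCCTTCAGG")
    pair = _pair("ARG", "TCAG")  # fwd matches AAG@2 and AGG@3; rev TCAG@11
    amp = amplify_gene(gene, pair)
    assert amp is not None
    assert (amp.fwd_start, amp.rev_end) == (2, 15)
    assert amp.sequence == "AAGGCCCCTTCAG"
    assert amp.length_bp == 13
    # the amplicon includes both primer binding sites
    assert amp.sequence.startswith("AAG") and amp.sequence.endswith("TCAG")


def test_rightmost_reverse_site_wins():
    gene = _gene("AAGG" + "TCAG" + "CCCC" + "TCAG" + "GG")
    amp = amplify_gene(gene, _pair("AAGG", "TCAG"))
    assert amp.rev_end == 16


def test_no_amplicon_without_forward_or_downstream_reverse():
    assert amplify_gene(_gene("CCCCTCAGCCCC"), _pair("AAG", "TCAG")) is None
    # reverse site strictly upstream of the forward start
    assert amplify_gene(_gene("TCAGCCAAGCC"), _pair("AAG", "TCAG")) is None


def test_degenerate_positions_match_every_expansion_member():
    pair = _pair("ARG", "TCAG")
    for mid in "AG":
        gene = _gene("CCA" + mid + "GCCCCTCAGCC")
        assert amplify_gene(gene, pair) is not None
    for mid in "CT":
        gene = _gene("CCA" + mid + "GCCCCTCAGCC")
        assert amplify_gene(gene, pair) is None


def test_amplify_all_never_exceeds_gene_count():
    genes = {
        "u1": [_gene("AAGGCCTCAGCC", "u1"), _gene("CCCCCCCCCC", "u1")],
        "u2": [_gene("AAGGCCTCAGCC", "u2")],
    }
    out = amplify_all(genes, [_pair("AAGG", "TCAG")], {"u1": "S a", "u2": "S b"})
    amps = out["p1"]
    assert len(amps) == 2
    assert {a.unit_id for a in amps} == {"u1", "u2"}
    assert {a.species for a in amps} == {"S a", "S b"}


def test_locate_on_reference_unique_u_and_ambiguous():
    ref = "AAACCCGGGTTT"
    assert locate_on_reference("CCGG", ref) == (5, 8)  # 1-based inclusive
    assert locate_on_reference("TTTT", ref) == "U"
    # reverse primer located via its reverse complement on the sense strand
    assert locate_on_reference(reverse_complement("CCGG"), ref, is_reverse=True) == (5, 8)
    with pytest.raises(AmbiguousReferenceMatch):
        locate_on_reference("AA", ref)


def test_span_length_conventions():
    assert paper_span_length(342, 1079) == 737
    assert inclusive_span_length(342, 1079) == 738
    with pytest.raises(ValueError):
        paper_span_length(100, 50)


def test_length_category_boundaries():
    assert classify_length_category(99.99) == "undersized"
    assert classify_length_category(100.0) == "S"
    assert classify_length_category(300.0) == "S"
    assert classify_length_category(300.01) == "M"
    assert classify_length_category(600.0) == "M"
    assert classify_length_category(600.01) == "L"


def test_bundled_panel_shape():
    pairs = bundled_primer_pairs()
    assert len(pairs) == 39
    assert len({p.pair_id for p in pairs}) == 39
    assert {p.scope for p in pairs} <= {"bacteria", "archaea", "both"}
    for p in pairs:
        assert p.pair_id == f"{p.fwd_id}-{p.rev_id}"
        assert set(p.fwd_seq) <= set("ACGTRYSWKMBDHVN")
        assert set(p.rev_seq) <= set("ACGTRYSWKMBDHVN")
    assert sum(p.group == "most_used" for p in pairs) == 6
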