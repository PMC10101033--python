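import random

import pytest

from silico16s.genefinder import (
    build_reference_panel,
    extract_genes,
    read_genes_fasta,
    scan_candidates,
)
from silico16s.io import RANKS, GenomeRecord
from silico16s.iupac import reverse_complement
from silico16s.simulate import build_template

TEMPLATE = build_template()
PANEL = build_reference_panel(sequences=[TEMPLATE])


def _unit(seq, unit_id="u1"):
    tax = dict(zip(RANKS, ["Bacteria", "P", "C", "O", "F", "G", "S s", "S s"]))
    return GenomeRecord(unit_id=unit_id, genome_id="g1", taxonomy=tax, sequence=seq)


def _background(n, seed=0):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def test_panel_is_strand_closed_and_has_terminal_motifs():
    assert PANEL.start_motifs == [TEMPLATE[:15]]
    assert PANEL.end_motifs == [TEMPLATE[-15:]]
    kmer = TEMPLATE[100:113]
    assert kmer in PANEL.kmer_set_both
    assert reverse_complement(kmer) in PANEL.kmer_set_both
    assert PANEL.median_length == len(TEMPLATE)


def test_extracts_single_plus_strand_gene_exactly():
    seq = _background(500, 1) + TEMPLATE + _background(500, 2)
    hits = extract_genes(_unit(seq), PANEL)
    assert len(hits) == 1
    h = hits[0]
    assert (h.start, h.end, h.strand) == (500, 500 + len(TEMPLATE), "+")
    assert h.sequence == TEMPLATE


def test_strand_symmetry_of_extraction():
    # inserting the reverse complement must recover the identical sense gene
    fwd = _background(400, 3) + TEMPLATE + _background(400, 4)
    rev = _background(400, 3) + reverse_complement(TEMPLATE) + _background(400, 4)
    h_fwd = extract_genes(_unit(fwd), PANEL)
    h_rev = extract_genes(_unit(rev), PANEL)
    assert len(h_fwd) == len(h_rev) == 1
    assert h_fwd[0].sequence == h_rev[0].sequence == TEMPLATE
    assert h_rev[0].strand == "-"
    assert (h_rev[0].start, h_rev[0].end) == (400, 400 + len(TEMPLATE))


def test_tandem_copies_are_both_recovered():
    seq = (
        _background(300, 5)
        + TEMPLATE
        + _background(250, 6)
        + TEMPLATE
        + _background(300, 7)
    )
    hits = extract_genes(_unit(seq), PANEL)
    assert [h.sequence for h in hits] == [TEMPLATE, TEMPLATE]
    assert hits[0].end <= hits[1].start


def test_no_candidates_in_pure_background():
    hits = extract_genes(_unit(_background(5000, 8)), PANEL)
    assert hits == []
    assert scan_candidates(_unit(_background(5000, 8)), PANEL) == []


def test_recall_with_5pct_diverged_gene():
    # mutate 5% of positions outside the terminal anchor motifs
    rng = random.Random(11)
    gene = list(TEMPLATE)
    positions = rng.sample(range(15, len(gene) - 15), int(0.05 * len(gene)))
    for p in positions:
        gene[p] = rng.choice([b for b in "ACGT" if b != gene[p]])
    diverged = "".join(gene)
    seq = _background(400, 12) + diverged + _background(400, 13)
    hits = extract_genes(_unit(seq), PANEL)
    assert len(hits) == 1
    assert hits[0].sequence == diverged
    assert (hits[0].start, hits[0].end) == (400, 400 + len(diverged))


def test_bypass_reader_groups_by_unit(tmp_path):
    p = tmp_path / "genes.fasta"
    p.write_text(">u1|gene1\nACGT\n>u1|gene2\nGGGG\n>u2|gene1\nTTTT\n")
    hits = read_genes_fasta(p)
    assert sorted(hits) == ["u1", "u2"]
    assert [h.sequence for h in hits["u1"]] == ["ACGT", "GGGG"]
    assert all(h.strand == "+" for h in hits["u1"])


def test_length_bounds_reject_truncated_genes():
    truncated = TEMPLATE[:15] + TEMPLATE[600:]  # start motif + tail, too short? 965nt
    assert len(truncated) < 1200
    seq = _background(400, 14) + truncated + _background(400, 15)
    hits = extract_genes(_unit(seq), PANEL)
    assert hits == []


def test_window_must_hold_a_kmer():
    with pytest.raises(ValueError):
        scan_candidates(_unit(_background(300, 16)), PANEL, window=5)
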