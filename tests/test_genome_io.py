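import pytest

from silico16s.io import (
    RANKS,
    GenomeRecord,
    TaxonomyFormatError,
    TaxonomyLookupError,
    read_genomes_fasta,
    read_taxonomy,
    sanitize_sequence,
    split_units,
)

TAX_HEADER = "genome_id\t" + "\t".join(RANKS)


def _tax_row(gid, species, strain=""):
    return "\t".join(
        [gid, "Bacteria", "P", "C", "O", "F", "G", species, strain]
    )


def _write_tax(tmp_path, rows):
    p = tmp_path / "tax.tsv"
    p.write_text(TAX_HEADER + "\n" + "\n".join(rows) + "\n")
    return p


def test_read_taxonomy_strain_falls_back_to_species(tmp_path):
    p = _write_tax(tmp_path, [_tax_row("g1", "Foo bar")])
    tax = read_taxonomy(p)
    assert tax["g1"]["strain"] == "Foo bar"


def test_read_taxonomy_rejects_duplicates_and_missing_columns(tmp_path):
    p = _write_tax(tmp_path, [_tax_row("g1", "A a"), _tax_row("g1", "B b")])
    with pytest.raises(TaxonomyFormatError, match="duplicate"):
        read_taxonomy(p)
    q = tmp_path / "bad.tsv"
    q.write_text("genome_id\tspecies\ng1\tA a\n")
    with pytest.raises(TaxonomyFormatError, match="missing columns"):
        read_taxonomy(q)


def test_sanitize_replaces_within_expansion_set_and_preserves_length():
    seq = "ACGRYNACGT"
    clean, rep = sanitize_sequence(seq, rng_seed=5)
    assert len(clean) == len(seq)
    assert set(clean) <= set("ACGT")
    assert rep.n_replaced == 3
    assert clean[3] in "AG" and clean[4] in "CT"  # R and Y expansion sets
    # untouched positions are identical
    for i, ch in enumerate(seq):
        if ch in "ACGT":
            assert clean[i] == ch


def test_sanitize_is_deterministic_and_idempotent():
    seq = "NNNRYKWSBDHVMN" * 10 + "ACGT"
    a, _ = sanitize_sequence(seq, rng_seed=42)
    b, _ = sanitize_sequence(seq, rng_seed=42)
    assert a == b
    c, rep = sanitize_sequence(a, rng_seed=42)
    assert c == a and rep.n_replaced == 0


def test_run_threshold_boundary():
    # a run of exactly `threshold` ambiguous characters is kept;
    # threshold + 1 excludes the unit
    keep = "ACGT" + "N" * 10 + "ACGT"
    drop = "ACGT" + "N" * 11 + "ACGT"
    _, rep_keep = sanitize_sequence(keep, rng_seed=1, run_threshold=10)
    _, rep_drop = sanitize_sequence(drop, rng_seed=1, run_threshold=10)
    assert not rep_keep.excluded and rep_keep.max_ambiguity_run == 10
    assert rep_drop.excluded and rep_drop.max_ambiguity_run == 11


def test_split_units_naming_exclusion_and_conservation(tmp_path):
    tax = read_taxonomy(
        _write_tax(tmp_path, [_tax_row("g1", "A a"), _tax_row("g2", "B b")])
    )
    genomes = [
        ("g1", ["ACGT" * 100, "ACGT" * 50]),
        ("g2", ["ACGT" * 10 + "N" * 11 + "ACGT" * 10]),
    ]
    units, reports = split_units(genomes, tax, seed=3)
    assert [u.unit_id for u in units] == ["g1__c1", "g1__c2"]
    assert len(reports) == 3  # every chromosome accounted for
    assert sum(r.excluded for r in reports) == 1
    assert len(units) + 1 == len(reports)


def test_split_units_requires_taxonomy(tmp_path):
    tax = read_taxonomy(_write_tax(tmp_path, [_tax_row("g1", "A a")]))
    with pytest.raises(TaxonomyLookupError):
        split_units([("gX", ["ACGT"])], tax)


def test_genome_record_validates_ranks():
    with pytest.raises(ValueError, match="ranks"):
        GenomeRecord("u", "g", {"species": "x"}, "ACGT")


def test_read_genomes_fasta_groups_chromosomes(tmp_path):
    p = tmp_path / "g.fasta"
    p.write_text(">g1|chr1\nACGT\n>g1|chr2\nGGCC\n>g2\nTTTT\n")
    genomes = read_genomes_fasta(p)
    assert genomes == [("g1", ["ACGT", "GGCC"]), ("g2", ["TTTT"])]


def test_unit_seeds_are_input_order_independent(tmp_path):
    tax = read_taxonomy(
        _write_tax(tmp_path, [_tax_row("g1", "A a"), _tax_row("g2", "B b")])
    )
    seq1, seq2 = "ACGTN" * 20, "NRYKM" * 20
    a, _ = split_units([("g1", [seq1]), ("g2", [seq2])], tax, seed=9)
    b, _ = split_units([("g2", [seq2]), ("g1", [seq1])], tax, seed=9)
    assert [(u.unit_id, u.sequence) for u in a] == [
        (u.unit_id, u.sequence) for u in b
    ]
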