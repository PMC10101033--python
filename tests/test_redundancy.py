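import pytest

from silico16s.genefinder import GeneHit
from silico16s.io import RANKS, GenomeRecord
from silico16s.redundancy import (
    ARCHAEAL_BANDS,
    aggregate,
    copy_number_spectrum,
    count_variants,
    summarize_genome,
)


def _tax(species, strain=None, genus="G", family="F"):
    return dict(
        zip(
            RANKS,
            ["Bacteria", "P", "C", "O", family, genus, species, strain or species],
        )
    )


def _unit(uid, gid, species, **kw):
    return GenomeRecord(uid, gid, _tax(species, **kw), "ACGT" * 10)


def _hits(uid, seqs, strands=None):
    strands = strands or ["+"] * len(seqs)
    return [
        GeneHit(uid, i * 100, i * 100 + len(s), st, s)
        for i, (s, st) in enumerate(zip(seqs, strands))
    ]


def test_count_variants_is_distinct_exact_sequences():
    assert count_variants([]) == 0
    assert count_variants(["AA", "AA", "AA"]) == 1
    assert count_variants(["AA", "AT", "AA", "TT"]) == 3
    # a single-nucleotide or length difference is a distinct variant
    assert count_variants(["ACGT", "ACGA"]) == 2
    assert count_variants(["ACGT", "ACG"]) == 2


def test_summarize_genome_counts_strands_and_checks_unit():
    u = _unit("g1__c1", "g1", "A a")
    s = summarize_genome(_hits("g1__c1", ["AC", "AC", "GT"], ["+", "-", "+"]), u)
    assert (s.n_genes, s.n_variants, s.n_plus_strand, s.n_minus_strand) == (3, 2, 2, 1)
    with pytest.raises(ValueError):
        summarize_genome(_hits("other", ["AC"]), u)


def _toy_stats():
    # species X: two units with 2 and 4 genes (mean 3); species Y: one unit
    # with 5 genes. Same genus -> genus mean of species means = (3+5)/2 = 4,
    # whereas the pooled unit mean would be (2+4+5)/3.
    units = [
        ("g1__c1", "g1", "X x", ["AA", "CC"]),
        ("g2__c1", "g2", "X x", ["AA", "AA", "CC", "GG"]),
        ("g3__c1", "g3", "Y y", ["AA"] * 5),
    ]
    tax = {}
    stats = []
    for uid, gid, sp, seqs in units:
        u = _unit(uid, gid, sp)
        tax[gid] = u.taxonomy
        stats.append(summarize_genome(_hits(uid, seqs), u))
    return stats, tax


def test_aggregate_species_and_mean_of_means_at_genus():
    stats, tax = _toy_stats()
    sp = {t.taxon: t for t in aggregate(stats, tax, "species")}
    assert sp["X x"].mean_genes == pytest.approx(3.0)
    assert sp["Y y"].mean_genes == pytest.approx(5.0)
    genus = aggregate(stats, tax, "genus")
    assert len(genus) == 1
    assert genus[0].mean_genes == pytest.approx(4.0)  # mean of species means
    pooled = aggregate(stats, tax, "genus", pooled=True)
    assert pooled[0].mean_genes == pytest.approx(11 / 3)


def test_strain_rank_reports_max_min_counts():
    stats, tax = _toy_stats()
    strains = {t.taxon: t for t in aggregate(stats, tax, "strain")}
    assert strains["X x"].strain_range == (4, 2)
    assert strains["Y y"].strain_range == (5, 5)


def test_copy_number_spectrum_band_edges():
    # means: X=3 (band 2-6), Y=5 (band 2-6) under bacterial bands
    stats, tax = _toy_stats()
    spec = copy_number_spectrum(stats, tax)
    assert spec["n_species"] == 2
    assert spec["bands"]["1"] == (0, 0.0)
    assert spec["bands"]["2-6"][0] == 2
    assert spec["percent_multi_copy"] == 100.0


def test_archaeal_bands_boundaries():
    # mean exactly 3 falls in "2-3"; above 3 falls in ">3"
    u1 = _unit("a1__c1", "a1", "Z z")
    u2 = _unit("a2__c1", "a2", "W w")
    stats = [
        summarize_genome(_hits("a1__c1", ["AA"] * 3), u1),
        summarize_genome(_hits("a2__c1", ["AA"] * 4), u2),
    ]
    tax = {"a1": u1.taxonomy, "a2": u2.taxonomy}
    spec = copy_number_spectrum(stats, tax, bands=ARCHAEAL_BANDS)
    assert spec["bands"]["2-3"][0] == 1
    assert spec["bands"][">3"][0] == 1


def test_aggregate_rejects_unknown_rank():
    stats, tax = _toy_stats()
    with pytest.raises(ValueError):
        aggregate(stats, tax, "kingdom")
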