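import pytest

from silico16s.iupac import find_matches
from silico16s.pcr import bundled_primer_pairs
from silico16s.simulate import (
    CommunitySpec,
    SpeciesSpec,
    StrainSpec,
    build_template,
    generate_community,
    pair_window,
    primer_sites,
    spec_from_dict,
    table1_like_spec,
)

PAIRS = bundled_primer_pairs()


def _tax(superkingdom="Bacteria"):
    return {
        "superkingdom": superkingdom, "phylum": "P", "class": "C",
        "order": "O", "family": "F", "genus": "G",
    }


def test_template_contains_every_primer_site_exactly_where_planted():
    t = build_template()
    assert len(t) == 1550
    assert set(t) <= set("ACGT")
    for site in primer_sites(PAIRS).values():
        assert (site.start, site.end) in find_matches(site.iupac, t)


def test_template_is_deterministic():
    assert build_template() == build_template()


def test_trivial_spec_truth_by_construction():
    spec = CommunitySpec(
        seed=5,
        species=[
            SpeciesSpec("Solo unum", _tax(), [StrainSpec("s1", copies=4)])
        ],
    )
    c = generate_community(spec)
    stats = c.truth_gene_stats()
    assert len(stats) == 1
    (st,) = stats.values()
    assert st["n_genes"] == 4 and st["n_variants"] == 1


def test_ma_link_flags_both_species_for_the_linked_pair():
    spec = CommunitySpec(
        seed=6,
        species=[
            SpeciesSpec("Alpha a", _tax(), [StrainSpec("a1", copies=2)]),
            SpeciesSpec("Beta b", _tax(), [StrainSpec("b1", copies=2)]),
        ],
    )
    link_pair = "KP_F048-OP_R043"
    c = generate_community(spec, ma_links=[("Alpha a", "Beta b", link_pair)])
    pair = next(p for p in PAIRS if p.pair_id == link_pair)
    tr = c.truth_pair_metrics(pair, "bacteria")
    assert tr["ma_species"] == {"Alpha a", "Beta b"}
    assert tr["sc_nma_pct"] == pytest.approx(0.0)
    # a pair whose window is not contained in the linked window stays clean
    other = next(p for p in PAIRS if p.pair_id == "KP_F034-KP_R065")
    tr2 = c.truth_pair_metrics(other, "bacteria")
    assert tr2["ma_species"] == set()
    assert tr2["sc_nma_pct"] == pytest.approx(100.0)


def test_same_seed_gives_byte_identical_fasta(tmp_path):
    spec, links = table1_like_spec(seed=99)
    a = generate_community(spec, ma_links=links).write(tmp_path / "a")
    b = generate_community(spec, ma_links=links).write(tmp_path / "b")
    assert a["genomes"].read_bytes() == b["genomes"].read_bytes()
    assert a["genes"].read_bytes() == b["genes"].read_bytes()


def test_spec_validation_errors():
    with pytest.raises(ValueError, match="negative"):
        CommunitySpec(seed=1, species=[
            SpeciesSpec("X x", _tax(), [StrainSpec("s", copies=-1)])
        ])
    with pytest.raises(ValueError, match="divergence"):
        CommunitySpec(seed=1, species=[
            SpeciesSpec("X x", _tax(), [StrainSpec("s", copies=1)], divergence=0.5)
        ])
    with pytest.raises(ValueError, match="n_variants"):
        CommunitySpec(seed=1, species=[
            SpeciesSpec("X x", _tax(), [StrainSpec("s", copies=2)], n_variants=3)
        ])


def test_fixture_shape(community):
    spec = community.spec
    max_copies = max(
        st.copies for sp in spec.species for st in sp.strains
    )
    assert max_copies == 11
    assert max(sp.n_variants for sp in spec.species) == 9
    assert any(
        st.n_chromosomes == 5 for sp in spec.species for st in sp.strains
    )
    # at least one decoy unit excluded by an ambiguity run
    assert sum(u.excluded for u in community.units) >= 1
    # at least one species undetectable by one pair
    assert community.knockouts
    # three planted MA links
    assert len(community.ma_links) == 3


def test_fixture_knockout_species_is_undetected_only_by_its_pair(community):
    (ko_species, ko_primers), = community.knockouts.items()
    ko_pairs = [
        p for p in PAIRS if p.fwd_id in ko_primers or p.rev_id in ko_primers
    ]
    assert len(ko_pairs) == 1
    tr = community.truth_pair_metrics(ko_pairs[0], "bacteria")
    assert ko_species not in tr["detected_species"]
    # every other bacterial pair still detects it
    probe = next(p for p in PAIRS if p.pair_id == "KP_F048-OP_R043")
    assert ko_species in community.truth_pair_metrics(probe, "bacteria")[
        "detected_species"
    ]


def test_fixture_minus_strand_copies_exist(community):
    stats = community.truth_gene_stats()
    assert sum(s["n_minus"] for s in stats.values()) > 0


def test_truth_amplicons_are_window_slices(community):
    pair = next(p for p in PAIRS if p.pair_id == "KP_F048-OP_R043")
    sites = primer_sites(PAIRS)
    w0, w1 = pair_window(pair, sites)
    for sp, uid, seq, gi in community.truth_amplicons(pair, sites)[:20]:
        unit = next(u for u in community.units if u.unit_id == uid)
        assert seq == unit.genes[gi].sequence[w0:w1]
        assert len(seq) == w1 - w0


def test_spec_from_dict_roundtrip():
    spec, links = spec_from_dict(
        {
            "seed": 7,
            "ma_links": [["A a", "B b", "OP_F066-OP_R073"]],
            "species": [
                {
                    "name": "A a", "taxonomy": _tax(), "n_variants": 2,
                    "strains": [
                        {"name": "s1", "copies": 3, "minus_strand": 1,
                         "ambiguity_runs": [[11, "N"]]}
                    ],
                },
                {"name": "B b", "taxonomy": _tax("Archaea"),
                 "strains": [{"name": "t1", "copies": 1}]},
            ],
        }
    )
    assert spec.seed == 7
    assert spec.species[0].strains[0].ambiguity_runs == [(11, "N")]
    assert links == [("A a", "B b", "OP_F066-OP_R073")]
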