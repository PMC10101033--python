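"""Synthetic genome communities with known 16S redundancy and planted
matching-amplicon structure.

The generator builds genomes around a synthetic 1,550-nt 16S-like template
that carries an exact binding site for every bundled primer pair. Primers
with published reference coordinates are planted at those coordinates (a
consistent assignment exists because the real reference satisfies them
simultaneously); primers with no reference alignment are assigned positions
that roughly reproduce their published mean amplicon lengths. The template
is NOT an organismal sequence.

Every species gets a unique "signature" (a base-4 code written into each
unconstrained segment of the template), so no two species ever share an
amplicon by accident; identical amplicons across species exist only where an
MA link deliberately copies one species' amplified window into another.
Truth tables are computed by direct construction from the planted
coordinates — never by calling the pipeline's matching code — so they can
serve as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import defaultdict
from pathlib import Path

import numpy as np

from .iupac import IUPAC_SETS, reverse_complement
from .io import RANKS
from .pcr import PrimerPair, bundled_primer_pairs

TEMPLATE_LEN = 1550
MOTIF_LEN = 15
GENE_SPACING = 400

#: 1-based template positions assigned to primers with no published
#: reference coordinates ("U" rows): forward primers anchored on their first
#: base, reverse primers on their last base. Chosen inside otherwise
#: unconstrained template segments so the resulting amplicon lengths are
#: close to the published per-pair means.
PLACED_FWD_FIRST = {"KP_F014": 412, "KP_F018": 370, "KP_F022": 931}
PLACED_REV_LAST = {"KP_R011": 1018, "KP_R013": 1058, "OP_R016": 1423}


@dataclass(frozen=True)
class Site:
    """A primer binding site on the template (sense strand, 0-based
    half-open), as the IUPAC sequence it must satisfy."""

    primer_id: str
    start: int
    end: int
    iupac: str


def primer_sites(pairs: list[PrimerPair]) -> dict[str, Site]:
    """Template binding site of every distinct primer in ``pairs``."""
    sites: dict[str, Site] = {}
    for p in pairs:
        if p.fwd_id not in sites:
            first = p.f_first if p.f_first is not None else PLACED_FWD_FIRST[p.fwd_id]
            s0 = first - 1
            sites[p.fwd_id] = Site(p.fwd_id, s0, s0 + len(p.fwd_seq), p.fwd_seq)
        if p.rev_id not in sites:
            last = p.r_last if p.r_last is not None else PLACED_REV_LAST[p.rev_id]
            e0 = last
            sites[p.rev_id] = Site(p.rev_id, e0 - len(p.rev_seq), e0, p.rev_site)
    return sites


def pair_window(pair: PrimerPair, sites: dict[str, Site]) -> tuple[int, int]:
    """Template coordinates of the amplicon a pair produces (half-open)."""
    return sites[pair.fwd_id].start, sites[pair.rev_id].end


def build_template(
    pairs: list[PrimerPair] | None = None,
    length: int = TEMPLATE_LEN,
    seed: int = 424243,
) -> str:
    """Synthetic 16S-like template satisfying every primer site exactly.

    Per-position allowed sets start at {A,C,G,T}, are intersected with the
    expansion set of every site letter covering the position, and remaining
    freedom is resolved by a fixed-seed uniform draw.
    """
    if pairs is None:
        pairs = bundled_primer_pairs()
    allowed: list[frozenset[str]] = [frozenset("ACGT")] * length
    for site in primer_sites(pairs).values():
        if site.start < 0 or site.end > length:
            raise ValueError(f"site {site.primer_id} outside the template")
        for i, ch in enumerate(site.iupac):
            inter = allowed[site.start + i] & IUPAC_SETS[ch]
            if not inter:
                raise ValueError(
                    f"incompatible primer constraints at template position "
                    f"{site.start + i} ({site.primer_id})"
                )
            allowed[site.start + i] = inter
    rng = np.random.default_rng(seed)
    return "".join(
        sorted(s)[int(rng.integers(len(s)))] for s in allowed
    )


def _protected_intervals(sites: dict[str, Site], length: int) -> list[tuple[int, int]]:
    ivals = [(s.start, s.end) for s in sites.values()]
    ivals += [(0, MOTIF_LEN), (length - MOTIF_LEN, length)]  # conserved termini
    ivals.sort()
    merged = [list(ivals[0])]
    for a, b in ivals[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def _free_segments(sites: dict[str, Site], length: int) -> list[tuple[int, int]]:
    out = []
    prev = 0
    for a, b in _protected_intervals(sites, length):
        if a > prev:
            out.append((prev, a))
        prev = max(prev, b)
    if prev < length:
        out.append((prev, length))
    return out


# --------------------------------------------------------------------------
# community specification


@dataclass
class StrainSpec:
    name: str
    copies: int
    n_chromosomes: int = 1
    minus_strand: int = 0  # number of copies inserted as reverse complements
    ambiguity_runs: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class SpeciesSpec:
    name: str
    taxonomy: dict[str, str]  # ranks superkingdom..genus (species/strain filled in)
    strains: list[StrainSpec]
    n_variants: int = 1
    divergence: float = 0.0  # extra per-base substitution rate outside protected windows
    knockout_primers: list[str] = field(default_factory=list)


@dataclass
class CommunitySpec:
    seed: int
    species: list[SpeciesSpec]
    run_threshold: int = 10

    def __post_init__(self) -> None:
        for sp in self.species:
            if not 0.0 <= sp.divergence <= 0.1:
                raise ValueError(f"{sp.name}: divergence outside [0, 0.1]")
            for st in sp.strains:
                if st.copies < 0:
                    raise ValueError(f"{st.name}: negative copy number")
                if st.minus_strand > st.copies:
                    raise ValueError(f"{st.name}: minus-strand copies > copies")
            if sp.n_variants < 1 or (
                max(st.copies for st in sp.strains) < sp.n_variants
            ):
                raise ValueError(f"{sp.name}: n_variants must be in [1, max copies]")


#: MA link: force species_b's amplified window for pair_id to be identical
#: to species_a's.
MALink = tuple[str, str, str]


def spec_from_dict(data: dict) -> tuple[CommunitySpec, list[MALink]]:
    """Build a (CommunitySpec, ma_links) pair from a plain mapping (the YAML
    file format of the simulate subcommand)."""
    species = []
    for sp in data.get("species", []):
        strains = [
            StrainSpec(
                name=st["name"],
                copies=int(st["copies"]),
                n_chromosomes=int(st.get("n_chromosomes", 1)),
                minus_strand=int(st.get("minus_strand", 0)),
                ambiguity_runs=[
                    (int(r[0]), str(r[1])) for r in st.get("ambiguity_runs", [])
                ],
            )
            for st in sp["strains"]
        ]
        species.append(
            SpeciesSpec(
                name=sp["name"],
                taxonomy=dict(sp.get("taxonomy", {})),
                strains=strains,
                n_variants=int(sp.get("n_variants", 1)),
                divergence=float(sp.get("divergence", 0.0)),
                knockout_primers=list(sp.get("knockout_primers", [])),
            )
        )
    spec = CommunitySpec(
        seed=int(data["seed"]),
        species=species,
        run_threshold=int(data.get("run_threshold", 10)),
    )
    links = [tuple(link) for link in data.get("ma_links", [])]
    return spec, links


# --------------------------------------------------------------------------
# generated community + truth


@dataclass
class TruthGene:
    sequence: str  # sense orientation
    start: int
    end: int
    strand: str
    variant_index: int


@dataclass
class TruthUnit:
    unit_id: str
    genome_id: str
    species: str
    domain: str  # bacteria | archaea
    excluded: bool
    sequence: str  # raw chromosome (may contain ambiguity runs)
    genes: list[TruthGene]


@dataclass
class Community:
    spec: CommunitySpec
    template: str
    units: list[TruthUnit]
    taxonomy: dict[str, dict[str, str]]
    ma_links: list[MALink]
    knockouts: dict[str, set[str]]  # species -> knocked-out primer ids

    # -- convenience views ------------------------------------------------
    def analysis_units(self) -> list[TruthUnit]:
        return [u for u in self.units if not u.excluded]

    def domain_totals(self) -> dict[str, tuple[int, int]]:
        """domain -> (n_units, n_species) over non-excluded units."""
        units: dict[str, int] = defaultdict(int)
        species: dict[str, set[str]] = defaultdict(set)
        for u in self.analysis_units():
            units[u.domain] += 1
            species[u.domain].add(u.species)
        return {d: (units[d], len(species[d])) for d in units}

    # -- truth construction (independent of pipeline code) ----------------
    def truth_gene_stats(self) -> dict[str, dict]:
        out = {}
        for u in self.analysis_units():
            seqs = [g.sequence for g in u.genes]
            out[u.unit_id] = {
                "species": u.species,
                "domain": u.domain,
                "n_genes": len(u.genes),
                "n_variants": len(set(seqs)),
                "n_plus": sum(1 for g in u.genes if g.strand == "+"),
                "n_minus": sum(1 for g in u.genes if g.strand == "-"),
            }
        return out

    def truth_species_means(self, key: str = "n_genes") -> dict[str, float]:
        per_species: dict[str, list[int]] = defaultdict(list)
        for stats in self.truth_gene_stats().values():
            per_species[stats["species"]].append(stats[key])
        return {sp: sum(v) / len(v) for sp, v in per_species.items()}

    def truth_amplicons(
        self, pair: PrimerPair, sites: dict[str, Site] | None = None
    ) -> list[tuple[str, str, str, int]]:
        """(species, unit_id, amplicon_seq, gene_index) for every gene the
        pair amplifies, by direct slicing at the planted coordinates."""
        if sites is None:
            sites = primer_sites(bundled_primer_pairs())
        w0, w1 = pair_window(pair, sites)
        out = []
        for u in self.analysis_units():
            if pair.fwd_id in self.knockouts.get(u.species, set()) or (
                pair.rev_id in self.knockouts.get(u.species, set())
            ):
                continue
            for gi, g in enumerate(u.genes):
                out.append((u.species, u.unit_id, g.sequence[w0:w1], gi))
        return out

    def truth_pair_metrics(self, pair: PrimerPair, domain: str) -> dict:
        """Detected units/species, MA species, SC-NMA and per-species OF /
        OF-MA for one pair on one domain, from the truth amplicons."""
        sites = primer_sites(bundled_primer_pairs())
        amps = [
            a
            for a in self.truth_amplicons(pair, sites)
            if self._domain_of_unit(a[1]) == domain
        ]
        n_units_total, n_species_total = self.domain_totals().get(domain, (0, 0))
        det_units = {a[1] for a in amps}
        det_species = {a[0] for a in amps}
        by_seq: dict[str, set[str]] = defaultdict(set)
        for sp, _, seq, _ in amps:
            by_seq[seq].add(sp)
        mas = {sp for seqs in by_seq.values() if len(seqs) >= 2 for sp in seqs}
        sc = (
            100.0 * (len(det_species) - len(mas)) / n_species_total
            if n_species_total
            else 0.0
        )
        # per-species OF / OF-MA under the documented interpretation
        per_unit: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
        species_seqs: dict[str, set[str]] = defaultdict(set)
        for sp, uid, seq, _ in amps:
            per_unit[sp][uid] += 1
            species_seqs[sp].add(seq)
        of: dict[str, tuple[float, float]] = {}
        for sp, units in per_unit.items():
            copies = sum(units.values()) / len(units)
            foreign_per_unit: dict[str, int] = defaultdict(int)
            for osp, uid, seq, _ in amps:
                if osp != sp and seq in species_seqs[sp]:
                    foreign_per_unit[uid] += 1
            foreign = (
                sum(foreign_per_unit.values()) / len(foreign_per_unit)
                if foreign_per_unit
                else 0.0
            )
            of[sp] = (copies + foreign, (copies + foreign) / copies)
        return {
            "detected_units": det_units,
            "detected_species": det_species,
            "ma_species": mas,
            "sc_nma_pct": sc,
            "amplicons_per_unit": {
                uid: sum(1 for a in amps if a[1] == uid) for uid in det_units
            },
            "of": of,
            "n_total_units": n_units_total,
            "n_total_species": n_species_total,
        }

    def _domain_of_unit(self, unit_id: str) -> str:
        for u in self.units:
            if u.unit_id == unit_id:
                return u.domain
        raise KeyError(unit_id)

    # -- file output -------------------------------------------------------
    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genomes": out_dir / "genomes.fasta",
            "taxonomy": out_dir / "taxonomy.tsv",
            "genes": out_dir / "truth_genes.fasta",
            "truth_units": out_dir / "truth_units.tsv",
        }
        with paths["genomes"].open("w") as fh:
            by_genome: dict[str, list[TruthUnit]] = defaultdict(list)
            for u in self.units:
                by_genome[u.genome_id].append(u)
            for gid in sorted(by_genome):
                for i, u in enumerate(by_genome[gid], start=1):
                    fh.write(f">{gid}|chr{i}\n{u.sequence}\n")
        with paths["taxonomy"].open("w") as fh:
            fh.write("genome_id\t" + "\t".join(RANKS) + "\n")
            for gid in sorted(self.taxonomy):
                tax = self.taxonomy[gid]
                fh.write(gid + "\t" + "\t".join(tax[r] for r in RANKS) + "\n")
        with paths["genes"].open("w") as fh:
            for u in self.analysis_units():
                for i, g in enumerate(u.genes, start=1):
                    fh.write(f">{u.unit_id}|gene{i}\n{g.sequence}\n")
        with paths["truth_units"].open("w") as fh:
            fh.write(
                "unit_id\tspecies\tdomain\texcluded\tn_genes\tn_variants\t"
                "n_plus\tn_minus\n"
            )
            for u in self.units:
                seqs = [g.sequence for g in u.genes]
                fh.write(
                    f"{u.unit_id}\t{u.species}\t{u.domain}\t"
                    f"{str(u.excluded).lower()}\t{len(u.genes)}\t"
                    f"{len(set(seqs))}\t"
                    f"{sum(1 for g in u.genes if g.strand == '+')}\t"
                    f"{sum(1 for g in u.genes if g.strand == '-')}\n"
                )
        return paths


# --------------------------------------------------------------------------
# generation


_BASES = "ACGT"


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(4, size=n))


def _substitute(seq: list[str], pos: int, rng: np.random.Generator) -> None:
    alternatives = [b for b in _BASES if b != seq[pos]]
    seq[pos] = alternatives[int(rng.integers(3))]


def _signature_positions(sites: dict[str, Site], length: int) -> list[list[int]]:
    """Per free segment (length >= 8), the four positions carrying the
    species code."""
    return [
        [a + 1 + k for k in range(4)]
        for a, b in _free_segments(sites, length)
        if b - a >= 8
    ]


def _species_code(index: int) -> list[int]:
    if not 0 <= index < 256:
        raise ValueError("at most 256 species are supported")
    return [(index >> (2 * k)) & 3 for k in range(4)]


def _knockout_position(primer_id: str, sites: dict[str, Site]) -> tuple[int, str]:
    """A template position covered only by ``primer_id``'s site where the
    site letter excludes at least one base; returns (position, new_base)."""
    site = sites[primer_id]
    others = [s for pid, s in sites.items() if pid != primer_id]
    for i, ch in enumerate(site.iupac):
        pos = site.start + i
        if len(IUPAC_SETS[ch]) == 4:
            continue
        if any(o.start <= pos < o.end for o in others):
            continue
        new_base = sorted(set(_BASES) - IUPAC_SETS[ch])[0]
        return pos, new_base
    raise ValueError(f"no isolated position to knock out {primer_id}")


def generate_community(
    spec: CommunitySpec,
    ma_links: list[MALink] | None = None,
    pairs: list[PrimerPair] | None = None,
) -> Community:
    """Deterministic community generation under ``spec.seed``.

    Each genome is i.i.d.-uniform background with template-derived gene
    copies inserted at non-overlapping positions (minus-strand copies as
    reverse complements). Species differ at signature positions in every
    unconstrained template segment; gene variants add substitutions outside
    all protected windows; MA-linked species share byte-identical amplified
    windows for the linked pair.
    """
    ma_links = ma_links or []
    if pairs is None:
        pairs = bundled_primer_pairs()
    pair_by_id = {p.pair_id: p for p in pairs}
    sites = primer_sites(pairs)
    template = build_template(pairs)
    sig_positions = _signature_positions(sites, len(template))
    protected = _protected_intervals(sites, len(template))
    protected_mask = np.zeros(len(template), dtype=bool)
    for a, b in protected:
        protected_mask[a:b] = True
    for seg in sig_positions:
        protected_mask[seg] = True

    species_names = [sp.name for sp in spec.species]
    if len(set(species_names)) != len(species_names):
        raise ValueError("duplicate species names")

    # species base genes: template + signature code (+ knockouts)
    base_gene: dict[str, list[str]] = {}
    knockouts: dict[str, set[str]] = {}
    for idx, sp in enumerate(spec.species):
        gene = list(template)
        for seg in sig_positions:
            for pos, digit in zip(seg, _species_code(idx)):
                gene[pos] = _BASES[digit]
        for primer_id in sp.knockout_primers:
            pos, new_base = _knockout_position(primer_id, sites)
            gene[pos] = new_base
        if sp.knockout_primers:
            knockouts[sp.name] = set(sp.knockout_primers)
        base_gene[sp.name] = gene

    # MA links: copy A's amplified window into B; freeze it in both species
    link_frozen: dict[str, np.ndarray] = {
        sp.name: np.zeros(len(template), dtype=bool) for sp in spec.species
    }
    for sp_a, sp_b, pair_id in ma_links:
        w0, w1 = pair_window(pair_by_id[pair_id], sites)
        base_gene[sp_b][w0:w1] = base_gene[sp_a][w0:w1]
        link_frozen[sp_a][w0:w1] = True
        link_frozen[sp_b][w0:w1] = True

    # per-species variant pool
    variant_pool: dict[str, list[str]] = {}
    for idx, sp in enumerate(spec.species):
        rng = np.random.default_rng([spec.seed % (2**31), 101, idx])
        mutable = np.flatnonzero(~(protected_mask | link_frozen[sp.name]))
        markers = rng.choice(mutable, size=sp.n_variants - 1, replace=False)
        pool = ["".join(base_gene[sp.name])]
        current = list(base_gene[sp.name])
        n_div = int(round(sp.divergence * len(mutable)))
        for j, marker in enumerate(markers, start=1):
            variant = list(current)
            _substitute(variant, int(marker), rng)
            current = variant
            if n_div:
                extra = list(variant)
                div_pos = rng.choice(
                    np.setdiff1d(mutable, markers), size=n_div, replace=False
                )
                for p in div_pos:
                    _substitute(extra, int(p), rng)
                variant = extra
            pool.append("".join(variant))
        variant_pool[sp.name] = pool

    # assemble genomes
    units: list[TruthUnit] = []
    taxonomy: dict[str, dict[str, str]] = {}
    genome_counter = 0
    for idx, sp in enumerate(spec.species):
        domain = (
            "archaea"
            if sp.taxonomy.get("superkingdom", "").lower() == "archaea"
            else "bacteria"
        )
        for st_idx, st in enumerate(sp.strains):
            genome_counter += 1
            gid = f"G{genome_counter:04d}"
            tax = {r: sp.taxonomy.get(r, "") for r in RANKS}
            tax["species"] = sp.name
            tax["strain"] = st.name or sp.name
            taxonomy[gid] = tax

            rng = np.random.default_rng([spec.seed % (2**31), 202, idx, st_idx])
            # distribute copies over chromosomes (first chromosomes get extras)
            per_chrom = [
                st.copies // st.n_chromosomes
                + (1 if c < st.copies % st.n_chromosomes else 0)
                for c in range(st.n_chromosomes)
            ]
            minus_left = st.minus_strand
            copy_counter = 0
            for c, n_genes in enumerate(per_chrom, start=1):
                length = GENE_SPACING + n_genes * (len(template) + GENE_SPACING)
                length = max(length, 3000)
                chrom = list(_random_dna(rng, length))
                genes: list[TruthGene] = []
                for gidx in range(n_genes):
                    variant_idx = copy_counter % sp.n_variants
                    copy_counter += 1
                    gene_seq = variant_pool[sp.name][variant_idx]
                    strand = "-" if minus_left > 0 else "+"
                    if minus_left > 0:
                        minus_left -= 1
                    start = GENE_SPACING + gidx * (len(template) + GENE_SPACING)
                    insert = (
                        gene_seq if strand == "+" else reverse_complement(gene_seq)
                    )
                    chrom[start : start + len(template)] = insert
                    genes.append(
                        TruthGene(
                            sequence=gene_seq,
                            start=start,
                            end=start + len(template),
                            strand=strand,
                            variant_index=variant_idx,
                        )
                    )
                # ambiguity runs go into the leading background margin
                excluded = False
                if c == 1 and st.ambiguity_runs:
                    offset = 50
                    for run_len, code in st.ambiguity_runs:
                        chrom[offset : offset + run_len] = code * run_len
                        offset += run_len + 20
                        if run_len > spec.run_threshold:
                            excluded = True
                units.append(
                    TruthUnit(
                        unit_id=f"{gid}__c{c}",
                        genome_id=gid,
                        species=sp.name,
                        domain=domain,
                        excluded=excluded,
                        sequence="".join(chrom),
                        genes=genes,
                    )
                )
    return Community(
        spec=spec,
        template=template,
        units=units,
        taxonomy=taxonomy,
        ma_links=list(ma_links),
        knockouts=knockouts,
    )


# --------------------------------------------------------------------------
# the bundled default fixture


def _tax(superkingdom, phylum, klass, order, family, genus):
    return {
        "superkingdom": superkingdom,
        "phylum": phylum,
        "class": klass,
        "order": order,
        "family": family,
        "genus": genus,
    }


def table1_like_spec(seed: int = 20240917) -> tuple[CommunitySpec, list[MALink]]:
    """Default test community: ~18 species over two superkingdoms spanning
    copy numbers 1-11 and 1-9 variants, a five-chromosome genome,
    minus-strand copies, an ambiguity-excluded decoy chromosome, a species
    undetectable by one primer pair, and three planted MA links.

    All species names are synthetic.
    """
    bac = lambda g: _tax("Bacteria", *g)  # noqa: E731
    arc = lambda g: _tax("Archaea", *g)  # noqa: E731
    firm = ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae")
    strep = ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae")
    fuso = ("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae")
    prot = ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Synthomonadaceae")
    actino = ("Actinobacteria", "Actinomycetia", "Micrococcales", "Parvibacteraceae")
    spiro = ("Spirochaetes", "Spirochaetia", "Spirochaetales", "Spirochaetaceae")
    eury = ("Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanosynthaceae")
    halo = ("Euryarchaeota", "Halobacteria", "Halobacteriales", "Halosynthaceae")
    cren = ("Crenarchaeota", "Thermoprotei", "Sulfolobales", "Crenosynthaceae")
    thaum = ("Thaumarchaeota", "Nitrososphaeria", "Nitrososphaerales", "Nitrososynthaceae")

    species = [
        SpeciesSpec(
            "Synthobacillus grandis",
            bac((*firm, "Synthobacillus")),
            strains=[
                StrainSpec(f"SG{i:02d}", copies=11 if i < 5 else 10, minus_strand=3)
                for i in range(6)
            ],
            n_variants=4,
            divergence=0.002,
        ),
        SpeciesSpec(
            "Synthobacillus multiplex",
            bac((*firm, "Synthobacillus")),
            strains=[StrainSpec("SM01", copies=9)],
            n_variants=9,
            divergence=0.002,
        ),
        SpeciesSpec(
            "Synthococcus oralis",
            bac((*strep, "Synthococcus")),
            strains=[StrainSpec("SO01", copies=5, minus_strand=2),
                     StrainSpec("SO02", copies=5)],
            n_variants=2,
        ),
        SpeciesSpec(
            "Synthococcus mitis",
            bac((*strep, "Synthococcus")),
            strains=[StrainSpec("SMI1", copies=5)],
            n_variants=1,
        ),
        SpeciesSpec(
            "Fictobacterium nucleatum",
            bac((*fuso, "Fictobacterium")),
            strains=[StrainSpec("FN01", copies=4)],
            n_variants=3,
        ),
        SpeciesSpec(
            "Fictobacterium periodonticum",
            bac((*fuso, "Fictobacterium")),
            strains=[StrainSpec("FP01", copies=4)],
            n_variants=2,
        ),
        SpeciesSpec(
            "Synthomonas gingivalis",
            bac((*prot, "Synthomonas")),
            strains=[StrainSpec("SYG1", copies=3),
                     StrainSpec("SYG2", copies=4, n_chromosomes=2)],
            n_variants=2,
        ),
        SpeciesSpec(
            "Synthomonas catoniae",
            bac((*prot, "Synthomonas")),
            strains=[StrainSpec("SYC1", copies=2)],
            n_variants=1,
            knockout_primers=["OP_F101"],
        ),
        SpeciesSpec(
            "Parvibacter unicus",
            bac((*actino, "Parvibacter")),
            strains=[StrainSpec("PU01", copies=1)],
            n_variants=1,
        ),
        SpeciesSpec(
            "Parvibacter duplex",
            bac((*actino, "Parvibacter")),
            strains=[StrainSpec("PD01", copies=2, minus_strand=1)],
            n_variants=2,
        ),
        SpeciesSpec(
            "Spirosimplex tenuis",
            bac((*spiro, "Spirosimplex")),
            strains=[
                StrainSpec("ST01", copies=2, n_chromosomes=2,
                           ambiguity_runs=[(3, "R")]),
                # decoy strain excluded by an 11-N ambiguity run
                StrainSpec("ST02", copies=2, ambiguity_runs=[(11, "N")]),
            ],
            n_variants=1,
        ),
        SpeciesSpec(
            "Megasynthia rara",
            bac((*prot, "Megasynthia")),
            strains=[StrainSpec("MR01", copies=8, minus_strand=4)],
            n_variants=5,
            divergence=0.002,
        ),
        SpeciesSpec(
            "Methanosynthus smithii",
            arc((*eury, "Methanosynthus")),
            strains=[StrainSpec("MS01", copies=2), StrainSpec("MS02", copies=2)],
            n_variants=2,
        ),
        SpeciesSpec(
            "Methanosynthus oralis",
            arc((*eury, "Methanosynthus")),
            strains=[StrainSpec("MO01", copies=3)],
            n_variants=2,
        ),
        SpeciesSpec(
            "Halosynthus salis",
            arc((*halo, "Halosynthus")),
            strains=[StrainSpec("HS01", copies=4, minus_strand=2)],
            n_variants=3,
        ),
        SpeciesSpec(
            "Crenosynthus calidus",
            arc((*cren, "Crenosynthus")),
            strains=[StrainSpec("CC01", copies=5, n_chromosomes=5)],
            n_variants=2,
        ),
        SpeciesSpec(
            "Crenosynthus unicus",
            arc((*cren, "Crenosynthus")),
            strains=[StrainSpec("CU01", copies=1)],
            n_variants=1,
        ),
        SpeciesSpec(
            "Nitrososynthus minor",
            arc((*thaum, "Nitrososynthus")),
            strains=[StrainSpec("NM01", copies=2, minus_strand=1)],
            n_variants=1,
        ),
    ]
    links: list[MALink] = [
        ("Synthococcus oralis", "Synthococcus mitis", "OP_F066-KP_R040"),
        ("Fictobacterium nucleatum", "Fictobacterium periodonticum",
         "OP_F066-OP_R073"),
        ("Methanosynthus smithii", "Methanosynthus oralis", "KP_F018-KP_R002"),
    ]
    return CommunitySpec(seed=seed, species=species), links


__all__ = [
    "TEMPLATE_LEN",
    "Site",
    "StrainSpec",
    "SpeciesSpec",
    "CommunitySpec",
    "Community",
    "TruthGene",
    "TruthUnit",
    "primer_sites",
    "pair_window",
    "build_template",
    "generate_community",
    "table1_like_spec",
]
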