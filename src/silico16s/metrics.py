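"""Matching-amplicon detection and primer-pair coverage metrics.

A matching amplicon (MA) is an in silico amplicon whose sequence is 100%
identical to an amplicon produced by a *different species* with the same
primer pair; intragenomic copies and identical amplicons from strains of the
same species are not MAs. The headline primer-quality metric is

    SC-NMA (%) = (species detected - species with MAs) / total species x 100

and the abundance-side metrics are the overestimation factor OF (a species'
own mean amplicon copy number plus the identical copies contributed by other
species) and its copy-normalised form OF-MA = OF / copies, which equals 1.00
exactly when the species has no MAs.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from .pcr import AmpliconRecord


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, applied only at report time."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MAGroup:
    pair_id: str
    amplicon_sequence: str
    members: list[tuple[str, str, int]]  # (species, unit_id, gene_index)

    @property
    def n_species(self) -> int:
        return len({m[0] for m in self.members})


@dataclass
class PrimerEvaluation:
    pair_id: str
    domain: str
    n_genomes_detected: int
    pct_genomes_detected: float
    n_species_detected: int
    pct_species_detected: float
    n_species_with_ma: int
    pct_species_with_ma: float  # denominator: detected species
    sc_nma_count: int
    sc_nma_pct: float  # denominator: all species
    of_mean: float
    of_ma_mean: float
    mean_amplicon_length: float
    n_total_genomes: int
    n_total_species: int


def find_ma_groups(amplicons: list[AmpliconRecord], pair_id: str) -> list[MAGroup]:
    """Group amplicons by exact sequence identity; keep groups spanning at
    least two distinct species. A species "has MAs" iff it appears in at
    least one group."""
    by_seq: dict[str, list[AmpliconRecord]] = defaultdict(list)
    for a in amplicons:
        if a.pair_id != pair_id:
            raise ValueError(f"amplicon from pair {a.pair_id!r}, expected {pair_id!r}")
        by_seq[a.sequence].append(a)
    groups: list[MAGroup] = []
    for seq in sorted(by_seq):
        members = by_seq[seq]
        if len({a.species for a in members}) >= 2:
            groups.append(
                MAGroup(
                    pair_id=pair_id,
                    amplicon_sequence=seq,
                    members=[(a.species, a.unit_id, a.gene_index) for a in members],
                )
            )
    return groups


def ma_species(groups: list[MAGroup]) -> set[str]:
    return {sp for g in groups for sp, _, _ in g.members}


def sc_nma(n_detected: int, n_ma_species: int, n_total: int) -> float:
    """Species coverage with no matching amplicons, percent to 2 decimals."""
    if not 0 <= n_ma_species <= n_detected <= n_total or n_total <= 0:
        raise ValueError(
            f"need 0 <= MA ({n_ma_species}) <= detected ({n_detected}) "
            f"<= total ({n_total}), total > 0"
        )
    return round_half_up(100.0 * (n_detected - n_ma_species) / n_total)


def overall_sc_nma(
    counts: list[tuple[int, int, int]],
) -> float:
    """Combined SC-NMA across evaluation domains:
    sum(detected - MA) over domains divided by the summed species totals."""
    num = 0
    den = 0
    for det, ma, total in counts:
        if not 0 <= ma <= det <= total:
            raise ValueError("inconsistent counts")
        num += det - ma
        den += total
    if den <= 0:
        raise ValueError("no species evaluated")
    return round_half_up(100.0 * num / den)


def overestimation_factors(
    amplicons: list[AmpliconRecord],
    ma_groups: list[MAGroup],
) -> dict[str, tuple[float, float]]:
    """Per-species (OF, OF-MA) for every species with at least one amplicon.

    copies(s)  = mean amplicons per detected unit of species s.
    foreign(s) = mean per-unit count of amplicons in other species' units
                 whose sequence is identical to one of s's amplicons (mean
                 over the foreign units carrying at least one such amplicon;
                 0 when there are none).
    OF(s) = copies(s) + foreign(s); OF-MA(s) = OF(s) / copies(s).
    """
    per_unit: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    unit_species: dict[str, str] = {}
    species_seqs: dict[str, set[str]] = defaultdict(set)
    for a in amplicons:
        per_unit[a.species][a.unit_id] += 1
        unit_species[a.unit_id] = a.species
        species_seqs[a.species].add(a.sequence)

    out: dict[str, tuple[float, float]] = {}
    for sp, units in per_unit.items():
        copies = sum(units.values()) / len(units)
        # foreign identical amplicons, grouped per foreign unit
        foreign_counts: dict[str, int] = defaultdict(int)
        for a in amplicons:
            if a.species != sp and a.sequence in species_seqs[sp]:
                foreign_counts[a.unit_id] += 1
        foreign = (
            sum(foreign_counts.values()) / len(foreign_counts)
            if foreign_counts
            else 0.0
        )
        of = copies + foreign
        out[sp] = (of, of / copies)
    return out


def evaluate_pair(
    pair_id: str,
    amplicons: list[AmpliconRecord],
    *,
    domain: str,
    n_total_genomes: int,
    n_total_species: int,
) -> PrimerEvaluation:
    """Coverage/MA metrics for one primer pair on one evaluation domain.

    Percentage denominators: total genomes and total species of the domain,
    except "species with MAs" which uses the detected-species count.
    """
    units = {a.unit_id for a in amplicons}
    species = {a.species for a in amplicons}
    groups = find_ma_groups(amplicons, pair_id)
    mas = ma_species(groups)
    n_det_sp = len(species)
    n_ma = len(mas)
    ofs = overestimation_factors(amplicons, groups)
    of_mean = sum(v[0] for v in ofs.values()) / len(ofs) if ofs else 0.0
    of_ma_mean = sum(v[1] for v in ofs.values()) / len(ofs) if ofs else 0.0
    lengths = [a.length_bp for a in amplicons]
    return PrimerEvaluation(
        pair_id=pair_id,
        domain=domain,
        n_genomes_detected=len(units),
        pct_genomes_detected=round_half_up(100.0 * len(units) / n_total_genomes)
        if n_total_genomes
        else 0.0,
        n_species_detected=n_det_sp,
        pct_species_detected=round_half_up(100.0 * n_det_sp / n_total_species)
        if n_total_species
        else 0.0,
        n_species_with_ma=n_ma,
        pct_species_with_ma=round_half_up(100.0 * n_ma / n_det_sp) if n_det_sp else 0.0,
        sc_nma_count=n_det_sp - n_ma,
        sc_nma_pct=sc_nma(n_det_sp, n_ma, n_total_species) if n_total_species else 0.0,
        of_mean=round_half_up(of_mean),
        of_ma_mean=round_half_up(of_ma_mean),
        mean_amplicon_length=round_half_up(sum(lengths) / len(lengths))
        if lengths
        else 0.0,
        n_total_genomes=n_total_genomes,
        n_total_species=n_total_species,
    )


def cross_primer_ma_tally(
    ma_flags: dict[str, dict[str, bool]], threshold: int = 10
) -> list[str]:
    """Species flagged as having MAs in at least ``threshold`` primer pairs.
    ``ma_flags`` maps pair_id -> {species: has_ma}."""
    counts: dict[str, int] = defaultdict(int)
    for flags in ma_flags.values():
        for sp, has in flags.items():
            if has:
                counts[sp] += 1
    return sorted(sp for sp, c in counts.items() if c >= threshold)


def write_evaluation_table(
    evaluations: list[PrimerEvaluation], path: str | Path
) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["pair_id", "domain", "n_genomes_detected", "pct_genomes_detected",
             "n_species_detected", "pct_species_detected", "n_species_with_ma",
             "pct_species_with_ma", "sc_nma_count", "sc_nma_pct", "of_mean",
             "of_ma_mean", "mean_amplicon_length"]
        )
        for e in evaluations:
            w.writerow(
                [e.pair_id, e.domain, e.n_genomes_detected,
                 f"{e.pct_genomes_detected:.2f}", e.n_species_detected,
                 f"{e.pct_species_detected:.2f}", e.n_species_with_ma,
                 f"{e.pct_species_with_ma:.2f}", e.sc_nma_count,
                 f"{e.sc_nma_pct:.2f}", f"{e.of_mean:.2f}",
                 f"{e.of_ma_mean:.2f}", f"{e.mean_amplicon_length:.2f}"]
            )


def write_ma_groups(groups: list[MAGroup], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["pair_id", "group_index", "n_species", "species", "unit_id",
                    "gene_index", "amplicon_length"])
        for i, g in enumerate(groups):
            for sp, unit_id, gi in g.members:
                w.writerow([g.pair_id, i, g.n_species, sp, unit_id, gi,
                            len(g.amplicon_sequence)])


def write_flag_matrix(
    ma_flags: dict[str, dict[str, bool]], path: str | Path
) -> None:
    """Species x primer-pair boolean MA matrix."""
    pairs = sorted(ma_flags)
    species = sorted({sp for flags in ma_flags.values() for sp in flags})
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["species", *pairs])
        for sp in species:
            w.writerow([sp, *[int(bool(ma_flags[p].get(sp, False))) for p in pairs]])


__all__ = [
    "MAGroup",
    "PrimerEvaluation",
    "round_half_up",
    "find_ma_groups",
    "ma_species",
    "sc_nma",
    "overall_sc_nma",
    "overestimation_factors",
    "evaluate_pair",
    "cross_primer_ma_tally",
    "write_evaluation_table",
    "write_ma_groups",
    "write_flag_matrix",
]
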