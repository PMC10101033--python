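"""Genome and taxonomy input: FASTA reading, ambiguity sanitization,
exclusion rules, and splitting multi-chromosome genomes into per-chromosome
analysis units.

Each chromosome is evaluated as an independent complete genome ("unit"), so
a genome with two chromosomes contributes two units to every downstream
statistic. Ambiguous IUPAC positions are replaced by a uniformly random
member of their expansion set (seeded, hence reproducible); a unit carrying
a run of more than ``run_threshold`` consecutive ambiguous characters is
excluded from all downstream analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .iupac import AMBIGUOUS, IUPAC_SETS, InvalidNucleotideError, validate

RANKS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)


class TaxonomyFormatError(ValueError):
    pass


class TaxonomyLookupError(KeyError):
    pass


@dataclass(frozen=True)
class GenomeRecord:
    """One analysis unit: a single sanitized chromosome plus its taxonomy."""

    unit_id: str
    genome_id: str
    taxonomy: dict[str, str]
    sequence: str

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if tuple(self.taxonomy) != RANKS:
            raise ValueError(f"taxonomy of {self.unit_id} must have ranks {RANKS}")
        if not self.taxonomy["species"]:
            raise ValueError(f"empty species label for {self.unit_id}")


@dataclass
class SanitizationReport:
    """What sanitization did to one unit."""

    unit_id: str
    n_replaced: int = 0
    replacement_positions: list[tuple[int, str, str]] = field(default_factory=list)
    excluded: bool = False
    max_ambiguity_run: int = 0


def read_taxonomy(table_path: str | Path) -> dict[str, dict[str, str]]:
    """Read the eight-rank taxonomy TSV into ``genome_id -> {rank: label}``.

    A missing strain label falls back to the species label (the convention
    for genomes with no designated strain name). Duplicate genome_id rows
    and missing rank columns are format errors.
    """
    table_path = Path(table_path)
    out: dict[str, dict[str, str]] = {}
    with table_path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise TaxonomyFormatError(f"{table_path}: empty taxonomy table")
        missing = {"genome_id", *RANKS} - set(reader.fieldnames)
        # strain may be absent entirely; it falls back to species
        missing -= {"strain"}
        if missing:
            raise TaxonomyFormatError(
                f"{table_path}: missing columns {sorted(missing)}"
            )
        for row in reader:
            gid = (row["genome_id"] or "").strip()
            if not gid:
                raise TaxonomyFormatError(f"{table_path}: row with empty genome_id")
            if gid in out:
                raise TaxonomyFormatError(f"{table_path}: duplicate genome_id {gid!r}")
            tax = {r: (row.get(r) or "").strip() for r in RANKS}
            if not tax["species"]:
                raise TaxonomyFormatError(f"{table_path}: empty species for {gid!r}")
            if not tax["strain"]:
                tax["strain"] = tax["species"]
            out[gid] = tax
    return out


def sanitize_sequence(
    seq: str,
    rng_seed: int,
    run_threshold: int = 10,
    *,
    unit_id: str = "",
) -> tuple[str, SanitizationReport]:
    """Replace every ambiguous IUPAC position by a uniform random member of
    its expansion set; flag the unit excluded if it contains a run of more
    than ``run_threshold`` consecutive ambiguous characters.

    Deterministic under ``rng_seed``: the generator is consumed in scan order
    over the sequence. Length-preserving, and idempotent on its own output.
    """
    seq = validate(seq, context=unit_id or "sequence")
    rng = np.random.default_rng(rng_seed)
    report = SanitizationReport(unit_id=unit_id)
    chars = list(seq)
    run = 0
    for i, ch in enumerate(chars):
        if ch in AMBIGUOUS:
            run += 1
            report.max_ambiguity_run = max(report.max_ambiguity_run, run)
            options = sorted(IUPAC_SETS[ch])
            chosen = options[int(rng.integers(len(options)))]
            chars[i] = chosen
            report.n_replaced += 1
            report.replacement_positions.append((i, ch, chosen))
        else:
            run = 0
    report.excluded = report.max_ambiguity_run > run_threshold
    return "".join(chars), report


def split_units(
    genomes: list[tuple[str, list[str]]],
    taxonomy: dict[str, dict[str, str]],
    *,
    seed: int = 0,
    run_threshold: int = 10,
) -> tuple[list[GenomeRecord], list[SanitizationReport]]:
    """Sanitize every chromosome and emit one :class:`GenomeRecord` per
    non-excluded chromosome.

    ``genomes`` is a list of ``(genome_id, [chromosome sequences])``. Units
    are named ``<genome_id>__c<i>`` (1-based ordinal). Units are sanitized in
    sorted unit_id order with per-unit seeds derived from ``seed`` so results
    are independent of input order and machine.
    """
    pending: list[tuple[str, str, str]] = []  # (unit_id, genome_id, seq)
    for genome_id, chroms in genomes:
        if not chroms:
            raise ValueError(f"genome {genome_id!r} has no sequences")
        if genome_id not in taxonomy:
            raise TaxonomyLookupError(f"no taxonomy for genome {genome_id!r}")
        for i, chrom in enumerate(chroms, start=1):
            pending.append((f"{genome_id}__c{i}", genome_id, chrom))

    pending.sort(key=lambda t: t[0])
    units: list[GenomeRecord] = []
    reports: list[SanitizationReport] = []
    for k, (unit_id, genome_id, chrom) in enumerate(pending):
        clean, rep = sanitize_sequence(
            chrom, rng_seed=(seed * 1_000_003 + k) % (2**31), run_threshold=run_threshold,
            unit_id=unit_id,
        )
        reports.append(rep)
        if rep.excluded:
            continue
        units.append(
            GenomeRecord(
                unit_id=unit_id,
                genome_id=genome_id,
                taxonomy=dict(taxonomy[genome_id]),
                sequence=clean,
            )
        )
    return units, reports


def read_genomes_fasta(
    path: str | Path, *, delimiter: str = "|"
) -> list[tuple[str, list[str]]]:
    """Read a multi-record genome FASTA with record IDs
    ``<genome_id><delimiter><chromosome_id>`` into ``(genome_id, [seqs])``
    pairs (chromosomes kept in file order; a record ID without the delimiter
    is a single-chromosome genome)."""
    grouped: dict[str, list[str]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gid = rec.id.split(delimiter, 1)[0]
        if gid not in grouped:
            grouped[gid] = []
            order.append(gid)
        grouped[gid].append(str(rec.seq).upper())
    if not order:
        raise ValueError(f"{path}: no FASTA records")
    return [(gid, grouped[gid]) for gid in order]


def load_units(
    genomes_fasta: str | Path,
    taxonomy_tsv: str | Path,
    *,
    seed: int = 0,
    run_threshold: int = 10,
    delimiter: str = "|",
) -> tuple[list[GenomeRecord], list[SanitizationReport]]:
    """Convenience composition: FASTA + taxonomy TSV -> sanitized units."""
    taxonomy = read_taxonomy(taxonomy_tsv)
    genomes = read_genomes_fasta(genomes_fasta, delimiter=delimiter)
    return split_units(genomes, taxonomy, seed=seed, run_threshold=run_threshold)


def write_sanitization_report(
    reports: list[SanitizationReport], path: str | Path
) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["unit_id", "n_replaced", "max_ambiguity_run", "excluded"])
        for rep in reports:
            w.writerow(
                [rep.unit_id, rep.n_replaced, rep.max_ambiguity_run,
                 str(rep.excluded).lower()]
            )


__all__ = [
    "RANKS",
    "GenomeRecord",
    "SanitizationReport",
    "TaxonomyFormatError",
    "TaxonomyLookupError",
    "InvalidNucleotideError",
    "read_taxonomy",
    "sanitize_sequence",
    "split_units",
    "read_genomes_fasta",
    "load_units",
    "write_sanitization_report",
]
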