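"""In silico PCR with IUPAC-degenerate primer pairs.

Primers match extracted 16S gene sequences under exact degenerate identity
(zero mismatches): the forward primer is searched as written, the reverse
primer as its IUPAC reverse complement downstream of the forward match. The
amplicon spans from the first base of the leftmost forward match to the last
base of the rightmost compatible reverse match, so it includes both
primer-binding sites.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .genefinder import GeneHit
from .iupac import find_matches, iupac_pattern, reverse_complement

# re-exported: per-position matcher construction is the matching policy
__all__pattern = iupac_pattern

PANEL_RESOURCE = "oral_primer_panel.tsv"

#: Amplicon length categories from the mean amplicon length of a pair:
#: S = [100, 300], M = (300, 600], L = > 600; below 100 is "undersized".
LENGTH_BANDS = (("S", 100.0, 300.0), ("M", 300.0, 600.0))


@dataclass(frozen=True)
class PrimerPair:
    pair_id: str
    fwd_id: str
    fwd_seq: str
    rev_id: str
    rev_seq: str
    scope: str = "both"  # bacteria | archaea | both
    group: str = "panel"  # panel | most_used
    alc: str = ""  # declared length category, if any
    region: str = ""
    f_first: int | None = None  # printed 1-based reference positions
    f_last: int | None = None
    r_first: int | None = None
    r_last: int | None = None

    @property
    def rev_site(self) -> str:
        """Binding site of the reverse primer on the sense strand."""
        return reverse_complement(self.rev_seq)


@dataclass(frozen=True)
class AmpliconRecord:
    pair_id: str
    unit_id: str
    gene_index: int
    species: str
    sequence: str
    fwd_start: int  # 0-based on the gene's sense sequence
    rev_end: int  # half-open end

    @property
    def length_bp(self) -> int:
        return self.rev_end - self.fwd_start


def _parse_pos(v: str) -> int | None:
    v = v.strip()
    return None if v in {"", "U"} else int(v)


def read_primer_table(path: str | Path) -> list[PrimerPair]:
    """Read a primer-pair TSV (pair identifiers, 5'->3' IUPAC sequences,
    target scope, optional printed reference positions)."""
    pairs: list[PrimerPair] = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pairs.append(
                PrimerPair(
                    pair_id=f"{row['fwd_id']}-{row['rev_id']}",
                    fwd_id=row["fwd_id"],
                    fwd_seq=row["fwd_seq"].upper(),
                    rev_id=row["rev_id"],
                    rev_seq=row["rev_seq"].upper(),
                    scope=row.get("scope", "both"),
                    group=row.get("group", "panel"),
                    alc=row.get("alc", ""),
                    region=row.get("region", ""),
                    f_first=_parse_pos(row.get("f_first", "")),
                    f_last=_parse_pos(row.get("f_last", "")),
                    r_first=_parse_pos(row.get("r_first", "")),
                    r_last=_parse_pos(row.get("r_last", "")),
                )
            )
    return pairs


def bundled_primer_pairs() -> list[PrimerPair]:
    """The 39 bundled oral-microbiome primer pairs (bacterium-specific,
    archaeon-specific, dual-domain, and the literature's most-used pairs)."""
    ref = resources.files("silico16s.data").joinpath(PANEL_RESOURCE)
    with resources.as_file(ref) as p:
        return read_primer_table(p)


def amplify_gene(
    gene: GeneHit, pair: PrimerPair, *, gene_index: int = 0, species: str = ""
) -> AmpliconRecord | None:
    """Amplicon of one sense-oriented gene, or None if either primer has no
    exact degenerate match (or the reverse site is not downstream)."""
    seq = gene.sequence
    fwd = find_matches(pair.fwd_seq, seq)
    if not fwd:
        return None
    f_start = fwd[0][0]  # leftmost forward match -> maximal amplicon
    rev = [m for m in find_matches(pair.rev_site, seq) if m[1] > f_start]
    if not rev:
        return None
    r_end = rev[-1][1]  # rightmost reverse match
    return AmpliconRecord(
        pair_id=pair.pair_id,
        unit_id=gene.unit_id,
        gene_index=gene_index,
        species=species,
        sequence=seq[f_start:r_end],
        fwd_start=f_start,
        rev_end=r_end,
    )


def amplify_all(
    genes_by_unit: dict[str, list[GeneHit]],
    pairs: list[PrimerPair],
    species_of_unit: dict[str, str],
) -> dict[str, list[AmpliconRecord]]:
    """Amplicons per pair over all units; at most one amplicon per gene per
    pair, so per-unit amplicon counts never exceed gene counts."""
    out: dict[str, list[AmpliconRecord]] = {p.pair_id: [] for p in pairs}
    for unit_id in sorted(genes_by_unit):
        sp = species_of_unit.get(unit_id, "")
        for gi, gene in enumerate(genes_by_unit[unit_id]):
            for pair in pairs:
                amp = amplify_gene(gene, pair, gene_index=gi, species=sp)
                if amp is not None:
                    out[pair.pair_id].append(amp)
    return out


class AmbiguousReferenceMatch(ValueError):
    """A primer matched a reference gene at more than one position."""


def locate_on_reference(
    primer: str, reference_gene: str, *, is_reverse: bool = False
) -> tuple[int, int] | str:
    """Positions (1-based, inclusive) of the unique exact degenerate match of
    a primer on a reference gene; ``"U"`` if it does not match. Reverse
    primers are located via their reverse complement, reported on the
    reference's forward coordinates. Multiple matches raise
    :class:`AmbiguousReferenceMatch`."""
    query = reverse_complement(primer) if is_reverse else primer.upper()
    hits = find_matches(query, reference_gene.upper())
    if not hits:
        return "U"
    if len(hits) > 1:
        raise AmbiguousReferenceMatch(
            f"{primer} matches the reference at {len(hits)} positions"
        )
    s, e = hits[0]
    return (s + 1, e)


def paper_span_length(f_first: int, r_last: int) -> int:
    """Span-length convention of the published primer table: reverse-primer
    last position minus forward-primer first position. Note this is one less
    than the inclusive base count of the amplicon."""
    if r_last < f_first:
        raise ValueError("reverse end precedes forward start")
    return r_last - f_first


def inclusive_span_length(f_first: int, r_last: int) -> int:
    """True amplicon length (inclusive base count) from 1-based positions."""
    return paper_span_length(f_first, r_last) + 1


def classify_length_category(mean_len: float) -> str:
    """S for [100, 300], M for (300, 600], L for >600, undersized below 100."""
    if mean_len < 100.0:
        return "undersized"
    for label, lo, hi in LENGTH_BANDS:
        if lo <= mean_len <= hi:
            return label
    return "L"


def write_amplicons(
    amplicons_by_pair: dict[str, list[AmpliconRecord]],
    tsv_path: str | Path,
    fasta_path: str | Path | None = None,
) -> None:
    with Path(tsv_path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["pair_id", "unit_id", "gene_index", "species", "fwd_start", "rev_end",
             "length_bp"]
        )
        for pid in sorted(amplicons_by_pair):
            for a in amplicons_by_pair[pid]:
                w.writerow(
                    [a.pair_id, a.unit_id, a.gene_index, a.species, a.fwd_start,
                     a.rev_end, a.length_bp]
                )
    if fasta_path is not None:
        with Path(fasta_path).open("w") as fh:
            for pid in sorted(amplicons_by_pair):
                for a in amplicons_by_pair[pid]:
                    fh.write(
                        f">{a.pair_id}|{a.unit_id}|gene{a.gene_index}\n{a.sequence}\n"
                    )


__all__ = [
    "PrimerPair",
    "AmpliconRecord",
    "AmbiguousReferenceMatch",
    "read_primer_table",
    "bundled_primer_pairs",
    "iupac_pattern",
    "amplify_gene",
    "amplify_all",
    "locate_on_reference",
    "paper_span_length",
    "inclusive_span_length",
    "classify_length_category",
    "write_amplicons",
]
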