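"""Detection and extraction of 16S rRNA genes from genome units.

The finder follows the classic k-mer-density strategy: windows of the genome
with a high fraction of 13-mers drawn from known 16S genes are flagged as
candidate segments, then each candidate is anchored by conserved motifs near
the expected start and end of the gene. A motif pair spanning a plausible
gene length confirms the gene and gives homologous endpoints. A bypass path
accepts a pre-extracted gene FASTA so downstream metrics never depend on the
finder's heuristics.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .io import GenomeRecord
from .iupac import find_matches, reverse_complement

DEFAULT_K = 13
DEFAULT_WINDOW = 100
DEFAULT_DENSITY = 0.30
DEFAULT_MIN_LEN = 1200
DEFAULT_MAX_LEN = 1900
MOTIF_LEN = 15


@dataclass(frozen=True)
class GeneHit:
    """One detected gene. Coordinates are 0-based half-open on the unit;
    ``sequence`` is always the sense (5'->3' gene orientation) strand."""

    unit_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    sequence: str

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass
class ReferencePanel:
    """k-mer set (strand-closed) plus terminal anchor motifs from known genes."""

    kmer_set: frozenset[str]        # sense-strand k-mers only (for orientation)
    kmer_set_both: frozenset[str]   # closed under reverse complement
    start_motifs: list[str]
    end_motifs: list[str]
    k: int = DEFAULT_K
    median_length: int = 1550


@dataclass
class Candidate:
    start: int
    end: int
    strand: str
    density: float


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def build_reference_panel(
    known_gene_fasta: str | Path | None = None,
    k: int = DEFAULT_K,
    *,
    sequences: list[str] | None = None,
    motif_len: int = MOTIF_LEN,
) -> ReferencePanel:
    """Build the k-mer/motif panel from known full-length gene sequences.

    The k-mer set contains every k-mer of every input gene and of its reverse
    complement. Anchor motifs default to the first and last ``motif_len``
    nucleotides of each gene (terminal regions of the 16S gene are strongly
    conserved, which is what makes motif anchoring work).
    """
    if sequences is None:
        if known_gene_fasta is None:
            raise ValueError("provide a FASTA path or sequences")
        sequences = [
            str(r.seq).upper() for r in SeqIO.parse(str(known_gene_fasta), "fasta")
        ]
    if not sequences:
        raise ValueError("reference panel needs at least one known gene")

    fwd: set[str] = set()
    both: set[str] = set()
    starts: list[str] = []
    ends: list[str] = []
    for seq in sequences:
        km = _kmers(seq, k)
        fwd |= km
        both |= km
        both |= _kmers(reverse_complement(seq), k)
        if seq[:motif_len] not in starts:
            starts.append(seq[:motif_len])
        if seq[-motif_len:] not in ends:
            ends.append(seq[-motif_len:])
    med = int(statistics.median(len(s) for s in sequences))
    return ReferencePanel(
        kmer_set=frozenset(fwd),
        kmer_set_both=frozenset(both),
        start_motifs=starts,
        end_motifs=ends,
        k=k,
        median_length=med,
    )


def scan_candidates(
    unit: GenomeRecord,
    panel: ReferencePanel,
    window: int = DEFAULT_WINDOW,
    density_threshold: float = DEFAULT_DENSITY,
) -> list[Candidate]:
    """Find maximal runs of windows whose panel k-mer density reaches the
    threshold; adjacent runs separated by less than one window are merged.
    Candidate strand is the majority orientation of the matched k-mers."""
    if window < panel.k:
        raise ValueError("window must be at least k")
    seq = unit.sequence
    k = panel.k
    n = len(seq)
    if n < k:
        return []

    hits_fwd: list[int] = []
    hits_rev: list[int] = []
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        f = kmer in panel.kmer_set
        r = reverse_complement(kmer) in panel.kmer_set
        if f:
            hits_fwd.append(i)
        if r and not f:
            hits_rev.append(i)

    # mark dense windows
    marked: list[tuple[int, int]] = []
    all_hits = sorted(hits_fwd + hits_rev)
    if not all_hits:
        return []
    import bisect

    step = max(window // 2, k)
    for w0 in range(0, max(n - window, 0) + 1, step):
        w1 = w0 + window
        n_kmer_positions = min(w1, n - k + 1) - w0
        if n_kmer_positions <= 0:
            continue
        lo = bisect.bisect_left(all_hits, w0)
        hi = bisect.bisect_left(all_hits, min(w1, n - k + 1))
        if (hi - lo) / n_kmer_positions >= density_threshold:
            marked.append((w0, w1))
    if not marked:
        return []

    # merge marked windows into candidate segments (gap < window merges)
    segments: list[list[int]] = [[marked[0][0], marked[0][1]]]
    for w0, w1 in marked[1:]:
        if w0 - segments[-1][1] < window:
            segments[-1][1] = max(segments[-1][1], w1)
        else:
            segments.append([w0, w1])

    out: list[Candidate] = []
    for s0, s1 in segments:
        lo_f = bisect.bisect_left(hits_fwd, s0)
        hi_f = bisect.bisect_left(hits_fwd, s1)
        lo_r = bisect.bisect_left(hits_rev, s0)
        hi_r = bisect.bisect_left(hits_rev, s1)
        nf, nr = hi_f - lo_f, hi_r - lo_r
        if nf + nr == 0:
            continue
        strand = "+" if nf >= nr else "-"
        density = (nf + nr) / max(s1 - s0 - k + 1, 1)
        out.append(Candidate(start=s0, end=min(s1, n), strand=strand, density=density))
    return out


def _anchor_all(
    candidate: Candidate,
    unit: GenomeRecord,
    panel: ReferencePanel,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    pad: int | None = None,
) -> list[GeneHit]:
    """All non-overlapping motif-anchored genes inside one candidate, in
    oriented order. Ties between admissible end motifs are broken toward the
    panel's median gene length.

    The candidate is padded by one maximum gene length on each side so that a
    dense k-mer run covering only part of a gene (density dips can split one
    gene into several candidate segments) still reaches both terminal
    motifs; duplicate anchors from split candidates collapse in the caller's
    overlap deduplication."""
    if pad is None:
        pad = max_len
    s0 = max(candidate.start - pad, 0)
    s1 = min(candidate.end + pad, len(unit.sequence))
    region = unit.sequence[s0:s1]
    if candidate.strand == "-":
        region = reverse_complement(region)

    starts: list[int] = sorted(
        {m[0] for motif in panel.start_motifs for m in find_matches(motif, region)}
    )
    ends: list[int] = sorted(
        {m[1] for motif in panel.end_motifs for m in find_matches(motif, region)}
    )
    hits: list[GeneHit] = []
    cursor = 0
    for st in starts:
        if st < cursor:
            continue
        admissible = [e for e in ends if min_len <= e - st <= max_len]
        if not admissible:
            continue
        en = min(admissible, key=lambda e: abs((e - st) - panel.median_length))
        gene_seq = region[st:en]
        if candidate.strand == "+":
            g0, g1 = s0 + st, s0 + en
        else:
            g0, g1 = s1 - en, s1 - st
        hits.append(
            GeneHit(
                unit_id=unit.unit_id,
                start=g0,
                end=g1,
                strand=candidate.strand,
                sequence=gene_seq,
            )
        )
        cursor = en
    return hits


def anchor_and_extract(
    candidate: Candidate,
    unit: GenomeRecord,
    panel: ReferencePanel,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> GeneHit | None:
    """First motif-anchored gene in the candidate, or None if no admissible
    start/end motif pair exists within the length range."""
    hits = _anchor_all(candidate, unit, panel, min_len=min_len, max_len=max_len)
    return hits[0] if hits else None


def extract_genes(
    unit: GenomeRecord,
    panel: ReferencePanel,
    *,
    window: int = DEFAULT_WINDOW,
    density_threshold: float = DEFAULT_DENSITY,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[GeneHit]:
    """Scan + anchor composition. Hits are sorted by start coordinate and
    overlapping hits are deduplicated keeping the first (higher-density
    candidate order)."""
    hits: list[GeneHit] = []
    candidates = scan_candidates(unit, panel, window=window, density_threshold=density_threshold)
    for cand in sorted(candidates, key=lambda c: -c.density):
        hits.extend(_anchor_all(cand, unit, panel, min_len=min_len, max_len=max_len))
    hits.sort(key=lambda h: (h.start, h.end))
    kept: list[GeneHit] = []
    for h in hits:
        if kept and h.start < kept[-1].end and h.end > kept[-1].start:
            continue  # overlap: keep the earlier (from the denser candidate)
        kept.append(h)
    return kept


def read_genes_fasta(path: str | Path, *, delimiter: str = "|") -> dict[str, list[GeneHit]]:
    """Bypass path: read a pre-extracted gene FASTA (record IDs
    ``<unit_id><delimiter>gene<i>``, sense-oriented sequences) into hits per
    unit. Coordinates are unknown on this path and set to a zero-based run of
    placeholders; strand is '+' by convention (sequences are already sense)."""
    out: dict[str, list[GeneHit]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        unit_id = rec.id.rsplit(delimiter, 1)[0]
        seq = str(rec.seq).upper()
        idx = len(out.setdefault(unit_id, []))
        out[unit_id].append(
            GeneHit(unit_id=unit_id, start=idx, end=idx + len(seq), strand="+", sequence=seq)
        )
    return out


def write_genes(
    hits_by_unit: dict[str, list[GeneHit]],
    fasta_path: str | Path,
    bed_path: str | Path | None = None,
    *,
    delimiter: str = "|",
) -> None:
    """Write sense-oriented gene FASTA plus a BED-like TSV (0-based half-open)."""
    with Path(fasta_path).open("w") as fh:
        for unit_id in sorted(hits_by_unit):
            for i, h in enumerate(hits_by_unit[unit_id], start=1):
                fh.write(f">{unit_id}{delimiter}gene{i}\n{h.sequence}\n")
    if bed_path is not None:
        with Path(bed_path).open("w") as fh:
            fh.write("unit_id\tstart\tend\tstrand\n")
            for unit_id in sorted(hits_by_unit):
                for h in hits_by_unit[unit_id]:
                    fh.write(f"{unit_id}\t{h.start}\t{h.end}\t{h.strand}\n")


__all__ = [
    "GeneHit",
    "ReferencePanel",
    "Candidate",
    "build_reference_panel",
    "scan_candidates",
    "anchor_and_extract",
    "extract_genes",
    "read_genes_fasta",
    "write_genes",
]
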