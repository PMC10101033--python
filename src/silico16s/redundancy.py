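"""Per-genome 16S gene counts, variant counts and taxonomic aggregation.

A gene *variant* is a distinct exact gene sequence within one genome unit
(two copies differing by a single nucleotide, or in length, are distinct
variants). Species-level means average over the species' genome units;
each higher rank averages the means of its immediate child taxa
(mean-of-means), matching the nested per-rank presentation used in
copy-number surveys. At the strain level raw (max, min) counts are reported
instead of means.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genefinder import GeneHit
from .io import RANKS, GenomeRecord


@dataclass
class GenomeGeneStats:
    unit_id: str
    genome_id: str
    n_genes: int
    n_variants: int
    n_plus_strand: int
    n_minus_strand: int
    gene_lengths: list[int]
    genome_length: int


@dataclass
class TaxonSummary:
    rank: str
    taxon: str
    mean_genes: float
    mean_variants: float
    n_genomes: int
    strain_range: tuple[int, int] | None = None  # (max, min), strain rank only


def count_variants(gene_seqs: list[str]) -> int:
    """Number of distinct gene sequences (0 for an empty list).

    Equivalent to 1 + the number of distinct sequences differing from the
    first one, but order-invariant.
    """
    return len(set(gene_seqs))


def summarize_genome(hits: list[GeneHit], unit: GenomeRecord) -> GenomeGeneStats:
    for h in hits:
        if h.unit_id != unit.unit_id:
            raise ValueError(
                f"gene hit for {h.unit_id!r} passed with unit {unit.unit_id!r}"
            )
    return GenomeGeneStats(
        unit_id=unit.unit_id,
        genome_id=unit.genome_id,
        n_genes=len(hits),
        n_variants=count_variants([h.sequence for h in hits]),
        n_plus_strand=sum(1 for h in hits if h.strand == "+"),
        n_minus_strand=sum(1 for h in hits if h.strand == "-"),
        gene_lengths=[h.length_bp for h in hits],
        genome_length=unit.length_bp,
    )


def _stats_frame(
    stats: list[GenomeGeneStats], taxonomy: dict[str, dict[str, str]]
) -> pd.DataFrame:
    rows = []
    for s in stats:
        if s.genome_id not in taxonomy:
            raise KeyError(f"no taxonomy for genome {s.genome_id!r}")
        tax = taxonomy[s.genome_id]
        rows.append(
            {
                "unit_id": s.unit_id,
                "genome_id": s.genome_id,
                **{r: tax[r] for r in RANKS},
                "n_genes": s.n_genes,
                "n_variants": s.n_variants,
            }
        )
    return pd.DataFrame(rows)


def _mean_of_means(df: pd.DataFrame, value: str, rank: str) -> pd.Series:
    """Hierarchical mean: average per-unit values at species level, then
    average child-taxon means up the rank ladder to ``rank``."""
    ladder = list(RANKS[: RANKS.index(rank) + 1])
    # species-level means first (units -> species), keyed by the full lineage
    lineage = list(RANKS[: RANKS.index("species") + 1])
    sp = df.groupby(lineage, dropna=False)[value].mean()
    levels = sp
    cur_ranks = lineage
    while len(cur_ranks) > len(ladder):
        cur_ranks = cur_ranks[:-1]
        levels = levels.groupby(level=list(range(len(cur_ranks)))).mean()
    return levels


def aggregate(
    stats: list[GenomeGeneStats],
    taxonomy: dict[str, dict[str, str]],
    rank: str,
    *,
    pooled: bool = False,
) -> list[TaxonSummary]:
    """Summaries for every taxon at ``rank``.

    Default is the hierarchical mean-of-means; ``pooled=True`` averages raw
    per-unit values across all units of the taxon instead. Strain rank
    reports raw (max, min) gene counts.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    df = _stats_frame(stats, taxonomy)
    ladder = list(RANKS[: RANKS.index(rank) + 1])
    n_units = df.groupby(ladder, dropna=False)["unit_id"].count()

    out: list[TaxonSummary] = []
    if rank == "strain":
        grouped = df.groupby(ladder, dropna=False)
        for key, sub in grouped:
            out.append(
                TaxonSummary(
                    rank=rank,
                    taxon=key[-1] if isinstance(key, tuple) else key,
                    mean_genes=float(sub["n_genes"].mean()),
                    mean_variants=float(sub["n_variants"].mean()),
                    n_genomes=len(sub),
                    strain_range=(int(sub["n_genes"].max()), int(sub["n_genes"].min())),
                )
            )
        return out

    if pooled:
        genes = df.groupby(ladder, dropna=False)["n_genes"].mean()
        variants = df.groupby(ladder, dropna=False)["n_variants"].mean()
    else:
        genes = _mean_of_means(df, "n_genes", rank)
        variants = _mean_of_means(df, "n_variants", rank)

    for key in genes.index:
        taxon = key[-1] if isinstance(key, tuple) else key
        out.append(
            TaxonSummary(
                rank=rank,
                taxon=taxon,
                mean_genes=float(genes.loc[key]),
                mean_variants=float(variants.loc[key]),
                n_genomes=int(n_units.loc[key]),
            )
        )
    return out


#: Default copy-number bands: (label, lower, upper) with mean m in band iff
#: lower < m <= upper. Band edges are configuration, not claims.
BACTERIAL_BANDS = (("1", 0.0, 1.0), ("2-6", 1.0, 6.999), (">=7", 6.999, float("inf")))
ARCHAEAL_BANDS = (("1", 0.0, 1.0), ("2-3", 1.0, 3.0), (">3", 3.0, float("inf")))


def copy_number_spectrum(
    stats: list[GenomeGeneStats],
    taxonomy: dict[str, dict[str, str]],
    *,
    value: str = "n_genes",
    bands: tuple[tuple[str, float, float], ...] = BACTERIAL_BANDS,
) -> dict:
    """Species mean copy numbers plus banded tallies and percentages.

    Returns species means, per-band (count, percent), and the headline
    "more than one copy" percentage. Percentages use the total species count
    as denominator; ``value`` selects genes vs variants.
    """
    df = _stats_frame(stats, taxonomy)
    species_means = df.groupby("species")[value].mean()
    n_species = len(species_means)
    banded = {}
    for label, lo, hi in bands:
        cnt = int(((species_means > lo) & (species_means <= hi)).sum())
        banded[label] = (cnt, round(100.0 * cnt / n_species, 2) if n_species else 0.0)
    multi = int((species_means > 1.0).sum())
    return {
        "species_means": species_means.to_dict(),
        "n_species": n_species,
        "bands": banded,
        "percent_multi_copy": round(100.0 * multi / n_species, 2) if n_species else 0.0,
    }


def write_rank_table(
    stats: list[GenomeGeneStats],
    taxonomy: dict[str, dict[str, str]],
    path: str | Path,
) -> pd.DataFrame:
    """Rank-nested summary TSV: one row per (rank, taxon) with mean genes,
    mean variants, unit count, and strain-level (max, min) ranges."""
    rows = []
    for rank in RANKS[1:]:  # superkingdom split is handled by the caller
        for ts in aggregate(stats, taxonomy, rank):
            rows.append(
                {
                    "rank": rank,
                    "taxon": ts.taxon,
                    "mean_genes": round(ts.mean_genes, 2),
                    "mean_variants": round(ts.mean_variants, 2),
                    "n_genomes": ts.n_genomes,
                    "max_genes": ts.strain_range[0] if ts.strain_range else "",
                    "min_genes": ts.strain_range[1] if ts.strain_range else "",
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_genome_table(
    stats: list[GenomeGeneStats],
    taxonomy: dict[str, dict[str, str]],
    path: str | Path,
) -> pd.DataFrame:
    """Per-genome-unit stats TSV (genome size, gene count, variants, strands)."""
    rows = []
    for s in stats:
        tax = taxonomy[s.genome_id]
        rows.append(
            {
                "unit_id": s.unit_id,
                "genome_id": s.genome_id,
                **{r: tax[r] for r in RANKS},
                "genome_length": s.genome_length,
                "n_genes": s.n_genes,
                "n_variants": s.n_variants,
                "n_plus_strand": s.n_plus_strand,
                "n_minus_strand": s.n_minus_strand,
                "mean_gene_length": round(
                    sum(s.gene_lengths) / len(s.gene_lengths), 2
                )
                if s.gene_lengths
                else 0.0,
            }
        )
    df = pd.DataFrame(rows).sort_values("unit_id")
    df.to_csv(path, sep="\t", index=False)
    return df


__all__ = [
    "GenomeGeneStats",
    "TaxonSummary",
    "count_variants",
    "summarize_genome",
    "aggregate",
    "copy_number_spectrum",
    "write_rank_table",
    "write_genome_table",
    "BACTERIAL_BANDS",
    "ARCHAEAL_BANDS",
]
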