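"""End-to-end orchestration: genomes -> units -> genes -> amplicons ->
redundancy and primer-evaluation reports.

The pipeline mirrors a published survey design: every chromosome is an
independent analysis unit, units are split into bacterial and archaeal
evaluation sets by the superkingdom rank, and each primer pair is evaluated
against the domains its scope declares ("both"-scope pairs get one row per
domain plus a combined overall SC-NMA row).

Also hosts the worked-examples report: SC-NMA, copy-number-band and
span-length values recomputed at runtime from the bundled survey-count
tables (counts transcribed from a published oral-microbiome survey).
"""

from __future__ import annotations

import csv
import json
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from . import genefinder, io, metrics, pcr, redundancy
from .metrics import round_half_up
from .simulate import build_template

SURVEY_COUNTS_RESOURCE = "oral_survey_counts.tsv"
SURVEY_SUMMARY_RESOURCE = "oral_survey_summary.tsv"


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """An error in a named pipeline stage, with the offending record id."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    genomes_fasta: Path
    taxonomy_tsv: Path
    out_dir: Path
    seed: int
    primer_table: Path | None = None  # default: bundled panel
    genes_fasta: Path | None = None  # bypass the gene finder
    reference_genes_fasta: Path | None = None  # finder panel source
    run_threshold: int = 10
    kmer_window: int = genefinder.DEFAULT_WINDOW
    kmer_density: float = genefinder.DEFAULT_DENSITY
    min_gene_len: int = genefinder.DEFAULT_MIN_LEN
    max_gene_len: int = genefinder.DEFAULT_MAX_LEN

    def __post_init__(self) -> None:
        for name in ("genomes_fasta", "taxonomy_tsv", "out_dir",
                     "primer_table", "genes_fasta", "reference_genes_fasta"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        self.seed = int(self.seed)

    def validate(self) -> None:
        for name in ("genomes_fasta", "taxonomy_tsv", "primer_table",
                     "genes_fasta", "reference_genes_fasta"):
            p = getattr(self, name)
            if p is not None and not Path(p).is_file():
                raise ConfigError(f"{name}: no such file: {p}")
        if not self.min_gene_len <= self.max_gene_len:
            raise ConfigError("min_gene_len must not exceed max_gene_len")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class RunResult:
    config: RunConfig
    units: list[io.GenomeRecord]
    sanitization: list[io.SanitizationReport]
    genes_by_unit: dict[str, list[genefinder.GeneHit]]
    stats: list[redundancy.GenomeGeneStats]
    amplicons_by_pair: dict[str, list[pcr.AmpliconRecord]]
    evaluations: list[metrics.PrimerEvaluation]
    overall_rows: list[dict]
    domain_of_unit: dict[str, str]
    paths: dict[str, Path] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def unit_domain(unit: io.GenomeRecord) -> str:
    """bacteria/archaea split by the superkingdom rank."""
    return (
        "archaea"
        if unit.taxonomy["superkingdom"].strip().lower() == "archaea"
        else "bacteria"
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage and write the full report bundle to
    ``config.out_dir``. Deterministic: identical config + seed give
    byte-identical output TSVs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)

    from . import __version__

    note(f"silico16s {__version__} seed={config.seed}")

    # stage: input
    try:
        taxonomy = io.read_taxonomy(config.taxonomy_tsv)
        genomes = io.read_genomes_fasta(config.genomes_fasta)
    except Exception as exc:
        raise StageError("input", str(exc)) from exc
    n_chroms = sum(len(chroms) for _, chroms in genomes)
    note(f"input: {len(genomes)} genomes, {n_chroms} chromosomes")

    # stage: sanitize/split
    try:
        units, reports = io.split_units(
            genomes, taxonomy, seed=config.seed, run_threshold=config.run_threshold
        )
    except Exception as exc:
        raise StageError("sanitize", str(exc)) from exc
    n_excluded = sum(1 for r in reports if r.excluded)
    if len(reports) != n_chroms or len(units) + n_excluded != n_chroms:
        raise StageError("sanitize", "conservation of records violated")
    note(f"sanitize: {len(units)} units kept, {n_excluded} excluded")

    # stage: genes
    unit_by_id = {u.unit_id: u for u in units}
    if config.genes_fasta is not None:
        genes_by_unit = genefinder.read_genes_fasta(config.genes_fasta)
        unknown = set(genes_by_unit) - set(unit_by_id)
        if unknown:
            raise StageError(
                "genes", f"gene FASTA names unknown unit {sorted(unknown)[0]!r}"
            )
        for u in units:
            genes_by_unit.setdefault(u.unit_id, [])
        note(f"genes: bypass FASTA {config.genes_fasta}")
    else:
        if config.reference_genes_fasta is not None:
            panel = genefinder.build_reference_panel(config.reference_genes_fasta)
        else:
            # default panel: the package's synthetic 16S-like template
            panel = genefinder.build_reference_panel(sequences=[build_template()])
        genes_by_unit = {}
        for u in units:
            try:
                genes_by_unit[u.unit_id] = genefinder.extract_genes(
                    u,
                    panel,
                    window=config.kmer_window,
                    density_threshold=config.kmer_density,
                    min_len=config.min_gene_len,
                    max_len=config.max_gene_len,
                )
            except Exception as exc:
                raise StageError("genes", f"{u.unit_id}: {exc}") from exc
    n_genes = sum(len(v) for v in genes_by_unit.values())
    note(f"genes: {n_genes} genes over {len(units)} units")

    # stage: redundancy
    stats = [
        redundancy.summarize_genome(genes_by_unit[u.unit_id], u) for u in units
    ]
    domain_of_unit = {u.unit_id: unit_domain(u) for u in units}
    species_of_unit = {u.unit_id: u.taxonomy["species"] for u in units}
    units_by_domain: dict[str, list[io.GenomeRecord]] = defaultdict(list)
    for u in units:
        units_by_domain[domain_of_unit[u.unit_id]].append(u)
    totals = {
        d: (len(us), len({u.taxonomy["species"] for u in us}))
        for d, us in units_by_domain.items()
    }
    for d, (nu, ns) in sorted(totals.items()):
        note(f"domain {d}: {nu} units, {ns} species")

    # stage: pcr
    if config.primer_table is not None:
        pairs = pcr.read_primer_table(config.primer_table)
    else:
        pairs = pcr.bundled_primer_pairs()
    try:
        amplicons_by_pair = pcr.amplify_all(genes_by_unit, pairs, species_of_unit)
    except Exception as exc:
        raise StageError("pcr", str(exc)) from exc
    note(
        "pcr: "
        + f"{sum(len(v) for v in amplicons_by_pair.values())} amplicons over "
        + f"{len(pairs)} pairs"
    )

    # stage: evaluate
    evaluations: list[metrics.PrimerEvaluation] = []
    overall_rows: list[dict] = []
    for pair in pairs:
        domains = (
            ["bacteria", "archaea"] if pair.scope == "both" else [pair.scope]
        )
        per_domain: dict[str, metrics.PrimerEvaluation] = {}
        for d in domains:
            if d not in totals:
                continue
            amps = [
                a
                for a in amplicons_by_pair[pair.pair_id]
                if domain_of_unit[a.unit_id] == d
            ]
            ev = metrics.evaluate_pair(
                pair.pair_id,
                amps,
                domain=d,
                n_total_genomes=totals[d][0],
                n_total_species=totals[d][1],
            )
            per_domain[d] = ev
            evaluations.append(ev)
        if pair.scope == "both" and len(per_domain) == 2:
            counts = [
                (e.n_species_detected, e.n_species_with_ma, e.n_total_species)
                for e in per_domain.values()
            ]
            overall_rows.append(
                {
                    "pair_id": pair.pair_id,
                    "sc_nma_count": sum(d - m for d, m, _ in counts),
                    "n_total_species": sum(t for _, _, t in counts),
                    "overall_sc_nma_pct": metrics.overall_sc_nma(counts),
                }
            )

    # stage: report
    paths: dict[str, Path] = {}

    def p(name: str, fname: str) -> Path:
        paths[name] = out / fname
        return paths[name]

    io.write_sanitization_report(reports, p("sanitization", "sanitization.tsv"))
    genefinder.write_genes(
        genes_by_unit, p("genes_fasta", "genes.fasta"), p("genes_bed", "genes.tsv")
    )
    for d, us in sorted(units_by_domain.items()):
        ids = {u.unit_id for u in us}
        dstats = [s for s in stats if s.unit_id in ids]
        redundancy.write_rank_table(dstats, taxonomy, p(f"rank_{d}", f"redundancy_{d}.tsv"))
        redundancy.write_genome_table(dstats, taxonomy, p(f"units_{d}", f"units_{d}.tsv"))
        bands = (
            redundancy.ARCHAEAL_BANDS if d == "archaea" else redundancy.BACTERIAL_BANDS
        )
        spectrum = redundancy.copy_number_spectrum(dstats, taxonomy, bands=bands)
        with p(f"spectrum_{d}", f"copy_number_{d}.tsv").open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["band", "n_species", "pct_species"])
            for label, (cnt, pct) in spectrum["bands"].items():
                w.writerow([label, cnt, f"{pct:.2f}"])
            w.writerow(
                ["multi_copy", "", f"{spectrum['percent_multi_copy']:.2f}"]
            )
        note(
            f"spectrum {d}: {spectrum['percent_multi_copy']:.2f}% multi-copy "
            f"species of {spectrum['n_species']}"
        )
    pcr.write_amplicons(amplicons_by_pair, p("amplicons", "amplicons.tsv"))
    # amplicon-size table (per pair x domain): n, mean/min/max length, category
    with p("amplicon_sizes", "amplicon_sizes.tsv").open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["pair_id", "domain", "n_amplicons", "mean_length",
                    "min_length", "max_length", "length_category"])
        for pair in pairs:
            for d in sorted(totals):
                lens = [
                    a.length_bp
                    for a in amplicons_by_pair[pair.pair_id]
                    if domain_of_unit[a.unit_id] == d
                ]
                if not lens:
                    continue
                mean_len = sum(lens) / len(lens)
                w.writerow(
                    [pair.pair_id, d, len(lens), f"{round_half_up(mean_len):.2f}",
                     min(lens), max(lens), pcr.classify_length_category(mean_len)]
                )
    metrics.write_evaluation_table(evaluations, p("evaluation", "evaluation.tsv"))
    with p("overall", "evaluation_overall.tsv").open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["pair_id", "sc_nma_count", "n_total_species", "overall_sc_nma_pct"])
        for row in overall_rows:
            w.writerow([row["pair_id"], row["sc_nma_count"], row["n_total_species"],
                        f"{row['overall_sc_nma_pct']:.2f}"])
    all_groups: list[metrics.MAGroup] = []
    ma_flags_by_domain: dict[str, dict[str, dict[str, bool]]] = defaultdict(dict)
    for pair in pairs:
        groups = metrics.find_ma_groups(amplicons_by_pair[pair.pair_id], pair.pair_id)
        all_groups.extend(groups)
        for d in sorted(totals):
            det = {
                a.species
                for a in amplicons_by_pair[pair.pair_id]
                if domain_of_unit[a.unit_id] == d
            }
            mas = {
                sp
                for g in groups
                for sp, uid, _ in g.members
                if domain_of_unit[uid] == d
            }
            ma_flags_by_domain[d][pair.pair_id] = {
                sp: (sp in mas) for sp in det
            }
    metrics.write_ma_groups(all_groups, p("ma_groups", "ma_groups.tsv"))
    for d in sorted(totals):
        metrics.write_flag_matrix(
            ma_flags_by_domain[d], p(f"flags_{d}", f"ma_flags_{d}.tsv")
        )
    note(f"evaluate: {len(evaluations)} pair-domain rows, {len(all_groups)} MA groups")

    with p("log", "run_log.txt").open("w") as fh:
        fh.write("\n".join(log) + "\n")
    with p("config", "run_config.json").open("w") as fh:
        json.dump(
            {k: str(v) if isinstance(v, Path) else v
             for k, v in vars(config).items()},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")

    return RunResult(
        config=config,
        units=units,
        sanitization=reports,
        genes_by_unit=genes_by_unit,
        stats=stats,
        amplicons_by_pair=amplicons_by_pair,
        evaluations=evaluations,
        overall_rows=overall_rows,
        domain_of_unit=domain_of_unit,
        paths=paths,
        log=log,
    )


# --------------------------------------------------------------------------
# worked examples from the bundled survey-count tables


def _read_resource(name: str) -> list[dict]:
    ref = resources.files("silico16s.data").joinpath(name)
    with resources.as_file(ref) as p, Path(p).open(newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def load_survey_counts() -> list[dict]:
    """Published per-pair detection counts (detected genomes/species, species
    with MAs, domain totals), transcribed from the survey's result tables."""
    rows = _read_resource(SURVEY_COUNTS_RESOURCE)
    for r in rows:
        for k in ("detected_genomes", "detected_species", "ma_species",
                  "total_genomes", "total_species"):
            r[k] = int(r[k])
    return rows


def load_survey_summary() -> list[dict]:
    rows = _read_resource(SURVEY_SUMMARY_RESOURCE)
    for r in rows:
        r["total_species"] = int(r["total_species"])
        r["single_copy_species"] = int(r["single_copy_species"])
    return rows


def survey_row(pair_id: str, domain: str) -> dict:
    for r in load_survey_counts():
        if r["pair_id"] == pair_id and r["domain"] == domain:
            return r
    raise KeyError(f"no survey counts for {pair_id} ({domain})")


def survey_sc_nma(pair_id: str, domain: str) -> tuple[float, int]:
    """(SC-NMA %, total species) for one pair on one domain from the bundled
    survey counts."""
    r = survey_row(pair_id, domain)
    return (
        metrics.sc_nma(r["detected_species"], r["ma_species"], r["total_species"]),
        r["total_species"],
    )


def survey_overall_sc_nma(pair_id: str) -> tuple[float, int]:
    """(overall SC-NMA %, combined species total) for a pair evaluated on
    both domains."""
    rows = [r for r in load_survey_counts() if r["pair_id"] == pair_id]
    if len(rows) != 2:
        raise KeyError(f"{pair_id} does not have counts for both domains")
    counts = [
        (r["detected_species"], r["ma_species"], r["total_species"]) for r in rows
    ]
    return metrics.overall_sc_nma(counts), sum(r["total_species"] for r in rows)


def survey_multi_copy_pct(domain: str) -> tuple[float, int]:
    """(% species with more than one gene copy, total species)."""
    for r in load_survey_summary():
        if r["domain"] == domain:
            total = r["total_species"]
            multi = total - r["single_copy_species"]
            return round_half_up(100.0 * multi / total), total
    raise KeyError(domain)


def panel_span(pair_id: str) -> tuple[int, int]:
    """(span length under the survey's printed convention, inclusive amplicon
    length) from a pair's printed reference positions."""
    for pair in pcr.bundled_primer_pairs():
        if pair.pair_id == pair_id:
            if pair.f_first is None or pair.r_last is None:
                raise ValueError(f"{pair_id} has no printed reference positions")
            return (
                pcr.paper_span_length(pair.f_first, pair.r_last),
                pcr.inclusive_span_length(pair.f_first, pair.r_last),
            )
    raise KeyError(pair_id)


def worked_examples_report() -> list[dict]:
    """Recompute every formula-level survey value from the bundled count
    tables: per-pair SC-NMA for both domains, overall SC-NMA for dual-scope
    pairs, copy-number-band percentages, and span lengths from printed
    primer positions."""
    rows: list[dict] = []
    for r in load_survey_counts():
        value, total = survey_sc_nma(r["pair_id"], r["domain"])
        rows.append(
            {
                "kind": "sc_nma",
                "pair_id": r["pair_id"],
                "domain": r["domain"],
                "inputs": f"({r['detected_species']}, {r['ma_species']}, {total})",
                "value": value,
            }
        )
    by_pair: dict[str, int] = defaultdict(int)
    for r in load_survey_counts():
        by_pair[r["pair_id"]] += 1
    for pair_id in sorted(p for p, n in by_pair.items() if n == 2):
        value, total = survey_overall_sc_nma(pair_id)
        rows.append(
            {"kind": "overall_sc_nma", "pair_id": pair_id, "domain": "both",
             "inputs": f"(n={total})", "value": value}
        )
    for r in load_survey_summary():
        value, total = survey_multi_copy_pct(r["domain"])
        rows.append(
            {"kind": "multi_copy_pct", "pair_id": "", "domain": r["domain"],
             "inputs": f"({total}, {r['single_copy_species']})", "value": value}
        )
    for pair in pcr.bundled_primer_pairs():
        if pair.f_first is None or pair.r_last is None:
            continue
        span, _ = panel_span(pair.pair_id)
        rows.append(
            {"kind": "span_length", "pair_id": pair.pair_id, "domain": "",
             "inputs": f"({pair.f_first}, {pair.r_last})", "value": span}
        )
    return rows


def write_worked_examples(path: str | Path) -> list[dict]:
    rows = worked_examples_report()
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["kind", "pair_id", "domain", "inputs", "value"])
        for r in rows:
            value = f"{r['value']:.2f}" if r["kind"] != "span_length" else r["value"]
            w.writerow([r["kind"], r["pair_id"], r["domain"], r["inputs"], value])
    return rows


__all__ = [
    "ConfigError",
    "StageError",
    "RunConfig",
    "RunResult",
    "unit_domain",
    "run_pipeline",
    "load_survey_counts",
    "load_survey_summary",
    "survey_row",
    "survey_sc_nma",
    "survey_overall_sc_nma",
    "survey_multi_copy_pct",
    "panel_span",
    "worked_examples_report",
    "write_worked_examples",
]
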