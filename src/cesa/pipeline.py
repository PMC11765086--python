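"""End-to-end orchestration of the five pipeline stages.

parse catalog → anchor sites on the source proteome → resolve gene ids →
map orthologs (confidence-filtered) → align and score every target isoform
→ report.  The pipeline is fully deterministic: identical inputs and
configuration produce byte-identical output files (rows are ordered by
source gene id, target gene id, isoform accession, site).

Every catalog row is traceable: it ends up either as one or more report
rows, as a parse reject, or as an anchoring-report row whose disposition
records why it produced no report rows (anchor_failed, unmapped_gene,
unmapped_ortholog).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import catalog_io
from .alignment import AlignmentParams, align_and_transfer
from .conservation import load_matrix, score_site
from .reference_store import (
    UNMAPPED,
    GeneIdMap,
    OrthologTable,
    load_proteome,
)
from .site_anchor import anchor_site

log = logging.getLogger("cesa")

DISP_SCORED = "scored"
DISP_ANCHOR_FAILED = "anchor_failed"
DISP_UNMAPPED_GENE = "unmapped_gene"
DISP_UNMAPPED_ORTHOLOG = "unmapped_ortholog"


@dataclass
class PipelineConfig:
    catalog: Path
    source_fasta: Path
    target_fasta: Path
    gene_map: Path
    ortholog_table: Path
    id_map: Path | None = None
    species_filter: frozenset[str] | None = None
    require_antibody: bool = True
    min_rank: str = "moderate"
    min_window: int = 6
    max_window: int = 11
    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    allow_substitution: bool = True
    source_species: str = "source"
    target_species: str = "target"
    out_dir: Path | None = None
    column_map: dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(range(self.min_window, self.max_window + 1))

    @property
    def alignment_params(self) -> AlignmentParams:
        return AlignmentParams(self.matrix, self.gap_open, self.gap_extend)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        base = Path(path).parent
        for key in ("catalog", "source_fasta", "target_fasta", "gene_map",
                    "ortholog_table", "id_map", "out_dir"):
            if raw.get(key) is not None:
                raw[key] = base / raw[key] if not Path(raw[key]).is_absolute() else Path(raw[key])
        if raw.get("species_filter") is not None:
            raw["species_filter"] = frozenset(raw["species_filter"])
        return cls(**raw)


@dataclass
class PipelineResult:
    report: pd.DataFrame
    summary: pd.DataFrame
    anchoring: pd.DataFrame
    rejects: pd.DataFrame


def _qualified_cols(lengths) -> list[str]:
    return [f"qualified_{L}" for L in lengths]


REPORT_COLUMNS_FIXED = [
    "site_id",
    "source_species",
    "source_gene_symbol",
    "source_gene_id",
    "source_accession",
    "residue",
    "catalog_position",
    "site_position",
    "antibody_ids",
    "anchor_status",
    "ambiguous_gene",
    "ortholog_rank",
    "target_gene_id",
    "target_isoform_accession",
    "target_isoform_length",
    "aligned_site_position",
    "aligned_site_residue",
    "alignment_score",
    "site_identical",
    "longest_identical_run",
    "max_qualified_length",
    "substitution_note",
]

ANCHORING_COLUMNS = [
    "site_id",
    "gene_symbol",
    "catalog_accession",
    "accession_used",
    "status",
    "site_position",
    "failure_reason",
    "disposition",
]


def _site_id(record) -> str:
    return (
        f"{record.source_species}|{record.gene_symbol}|"
        f"{record.residue}{record.position}|{record.protein_accession}"
    )


def _resolve_gene_ids(anchored, id_map: GeneIdMap | None) -> set[int]:
    gids: set[int] = set()
    if anchored.protein is not None and anchored.protein.gene_id != UNMAPPED:
        gids.add(anchored.protein.gene_id)
    if not gids and id_map is not None:
        rec = anchored.record
        gids |= id_map.lookup(rec.gene_symbol, "symbol")
        for ns in ("refseq", "uniprot"):
            gids |= id_map.lookup(rec.protein_accession, ns)
    return gids


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline; optionally write the four output TSVs."""
    for name in ("catalog", "source_fasta", "target_fasta", "gene_map", "ortholog_table"):
        path = getattr(config, name)
        if not Path(path).is_file():
            raise FileNotFoundError(f"{name} input not found: {path}")
    if config.id_map is not None and not Path(config.id_map).is_file():
        raise FileNotFoundError(f"id_map input not found: {config.id_map}")

    records, rejects = catalog_io.parse_catalog(
        config.catalog,
        species_filter=config.species_filter,
        require_antibody=config.require_antibody,
        column_map=config.column_map or None,
    )
    log.info("catalog: %d records retained, %d rejected", len(records), len(rejects))

    source_store = load_proteome(config.source_fasta, config.gene_map, config.source_species)
    target_store = load_proteome(config.target_fasta, config.gene_map, config.target_species)
    id_map = GeneIdMap.load(config.id_map) if config.id_map is not None else None
    orthologs = OrthologTable.load(config.ortholog_table)
    log.info(
        "stores: %d source proteins, %d target proteins", len(source_store), len(target_store)
    )

    matrix = load_matrix(config.matrix)
    lengths = config.lengths
    params = config.alignment_params

    anchoring_rows: list[dict] = []
    report_rows: list[dict] = []
    for record in records:
        anchored = anchor_site(record, source_store, id_map)
        arow = {
            "site_id": _site_id(record),
            "gene_symbol": record.gene_symbol,
            "catalog_accession": record.protein_accession,
            "accession_used": anchored.protein.accession if anchored.protein else "",
            "status": anchored.status,
            "site_position": anchored.site_position if anchored.site_position else "",
            "failure_reason": anchored.failure_reason or "",
        }
        if not anchored.ok:
            arow["disposition"] = DISP_ANCHOR_FAILED
            anchoring_rows.append(arow)
            continue

        gene_ids = _resolve_gene_ids(anchored, id_map)
        if not gene_ids:
            arow["disposition"] = DISP_UNMAPPED_GENE
            anchoring_rows.append(arow)
            continue
        ambiguous_gene = len(gene_ids) > 1

        produced = 0
        for gid in sorted(gene_ids):
            for pair in orthologs.get_orthologs(gid, config.min_rank):
                for isoform in target_store.isoforms(pair.target_gene_id):
                    ctx = align_and_transfer(
                        anchored.protein.sequence,
                        isoform.sequence,
                        anchored.site_position,
                        params,
                    )
                    res = score_site(
                        ctx, lengths, matrix, allow_substitution=config.allow_substitution
                    )
                    note = res.substitution_note
                    row = {
                        "site_id": _site_id(record),
                        "source_species": record.source_species,
                        "source_gene_symbol": record.gene_symbol,
                        "source_gene_id": gid,
                        "source_accession": anchored.protein.accession,
                        "residue": record.residue,
                        "catalog_position": record.position,
                        "site_position": anchored.site_position,
                        "antibody_ids": ";".join(record.antibody_ids),
                        "anchor_status": anchored.status,
                        "ambiguous_gene": ambiguous_gene,
                        "ortholog_rank": pair.rank,
                        "target_gene_id": pair.target_gene_id,
                        "target_isoform_accession": isoform.accession,
                        "target_isoform_length": len(isoform.sequence),
                        "aligned_site_position": ctx.subject_site_position
                        if ctx.subject_site_position is not None
                        else "",
                        "aligned_site_residue": ctx.subject_site_residue,
                        "alignment_score": ctx.alignment_score,
                        "site_identical": res.site_identical,
                        "longest_identical_run": res.longest_identical_run,
                        "max_qualified_length": res.max_qualified_length,
                        "substitution_note": f"{note[0]}:{note[1]}>{note[2]}" if note else "",
                    }
                    for L in lengths:
                        row[f"qualified_{L}"] = res.qualified_lengths[L]
                    report_rows.append(row)
                    produced += 1
        arow["disposition"] = DISP_SCORED if produced else DISP_UNMAPPED_ORTHOLOG
        anchoring_rows.append(arow)

    report_cols = REPORT_COLUMNS_FIXED + _qualified_cols(lengths)
    report = pd.DataFrame(report_rows, columns=report_cols)
    if len(report):
        report = report.sort_values(
            ["source_gene_id", "target_gene_id", "target_isoform_accession", "site_id"],
            kind="mergesort",
        ).reset_index(drop=True)
    summary = aggregate_counts(report, lengths)
    anchoring = pd.DataFrame(anchoring_rows, columns=ANCHORING_COLUMNS)
    rejects_df = pd.DataFrame(
        [(r.row_number, r.reason, r.raw_line) for r in rejects],
        columns=["row_number", "reason_code", "raw_line"],
    )
    log.info(
        "pipeline: %d report rows, dispositions %s",
        len(report),
        anchoring["disposition"].value_counts().to_dict() if len(anchoring) else {},
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "report.tsv", sep="\t", index=False, float_format="%.1f")
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        anchoring.to_csv(out / "anchoring.tsv", sep="\t", index=False)
        rejects_df.to_csv(out / "rejects.tsv", sep="\t", index=False)
    return PipelineResult(report, summary, anchoring, rejects_df)


def _best_isoform_rows(report: pd.DataFrame) -> pd.DataFrame:
    """One row per (site, target gene): the longest isoform, ties broken by
    lexicographically smallest accession."""
    ordered = report.sort_values(
        ["target_isoform_length", "target_isoform_accession"],
        ascending=[False, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates(subset=["site_id", "target_gene_id"], keep="first")


def aggregate_counts(
    report: pd.DataFrame, lengths: tuple[int, ...] = (6, 7, 8, 9, 10, 11)
) -> pd.DataFrame:
    """Per-cutoff summary: target genes and (site, gene) pairs qualifying.

    Gene-level counting follows the longest-isoform convention: a (site,
    gene) pair counts at cutoff L when the site qualifies at L on the gene's
    longest scored isoform.  Counts are reported overall and per source
    species; they are non-increasing in L by construction.
    """
    rows = []
    if len(report):
        best = _best_isoform_rows(report)
        groups = [("all", best)] + [
            (species, sub) for species, sub in best.groupby("source_species", sort=True)
        ]
    else:
        groups = [("all", report)]
    for species, sub in groups:
        for L in lengths:
            if len(sub):
                hits = sub[sub[f"qualified_{L}"]]
                n_genes = hits["target_gene_id"].nunique()
                n_pairs = len(hits.drop_duplicates(subset=["site_id", "target_gene_id"]))
            else:
                n_genes = n_pairs = 0
            rows.append(
                {
                    "source_species": species,
                    "cutoff": L,
                    "n_target_genes": n_genes,
                    "n_site_gene_pairs": n_pairs,
                }
            )
    return pd.DataFrame(
        rows, columns=["source_species", "cutoff", "n_target_genes", "n_site_gene_pairs"]
    )


def config_for_fixture(fixture_dir: str | Path, **overrides) -> PipelineConfig:
    """Convenience: a PipelineConfig wired to a fixture bundle directory."""
    d = Path(fixture_dir)
    cfg = PipelineConfig(
        catalog=d / "catalog.tsv",
        source_fasta=d / "source.fasta",
        target_fasta=d / "target.fasta",
        gene_map=d / "gene_map.tsv",
        ortholog_table=d / "orthologs.tsv",
        id_map=d / "id_map.tsv",
    )
    return replace(cfg, **overrides) if overrides else cfg
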