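"""Antibody/phosphosite catalog parsing.

Reads the tab-separated phosphorylation-site catalog dialect used by large
commercial phospho-antibody collections: one row per annotated site with a
gene symbol, protein accession, species, a modified-residue token such as
``Y1150-p``, a 15-mer flank peptide with the phosphosite lowercased at
position 8 and underscore padding at protein termini, and zero or more
antibody catalog numbers.

Every input row is accounted for: it becomes either a
:class:`PhosphoSiteRecord` or a :class:`RowReject` carrying a reason code
(including rows excluded by the species filter or the antibody requirement,
so that retained + rejected always equals rows read).
"""

from __future__ import annotations

import csv
import gzip
import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

RESIDUES = frozenset("STY")

#: Default column-name map for the catalog dialect.
DEFAULT_COLUMNS = {
    "gene": "GENE",
    "accession": "ACC_ID",
    "species": "ORGANISM",
    "mod_rsd": "MOD_RSD",
    "flank": "SITE_+/-7_AA",
    "antibody": "CST_CAT#",
}

_MOD_RSD_RE = re.compile(r"^([A-Za-z])(\d+)(?:-(\w+))?$")
FLANK_LEN = 15
SITE_POS = 8  # 1-based


class CatalogError(Exception):
    """Fatal catalog configuration problem (e.g. a missing column)."""


class RowRejectError(Exception):
    """A single malformed or excluded row; carries a machine reason code."""

    def __init__(self, reason: str, detail: str = ""):
        super().__init__(f"{reason}: {detail}" if detail else reason)
        self.reason = reason


@dataclass(frozen=True)
class PhosphoSiteRecord:
    """One catalog row, normalized."""

    source_species: str
    gene_symbol: str
    protein_accession: str
    residue: str  # one of S/T/Y
    position: int  # 1-based on the source protein
    flank_peptide: str  # 15 uppercase chars, site at index 8 (1-based)
    antibody_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class RowReject:
    row_number: int  # 1-based data-row number
    reason: str
    raw_line: str


def parse_mod_rsd(token: str) -> tuple[str, int]:
    """Parse a modified-residue token like ``Y1150-p`` into (residue, position).

    Only phosphorylatable residues (S/T/Y) are accepted; other modification
    types (e.g. ``K48-ub``) are rejected.
    """
    m = _MOD_RSD_RE.match(token.strip())
    if not m:
        raise RowRejectError("bad_mod_rsd", token)
    residue, pos, mod = m.group(1).upper(), int(m.group(2)), m.group(3)
    if residue not in RESIDUES:
        raise RowRejectError("non_STY_residue", token)
    if mod is not None and mod.lower() != "p":
        raise RowRejectError("non_STY_residue", token)
    if pos < 1:
        raise RowRejectError("bad_mod_rsd", token)
    return residue, pos


def normalize_flank(peptide: str) -> str:
    """Validate and uppercase a 15-mer flank peptide.

    Requirements: length 15; letters and underscores only; exactly one
    lowercase letter (the phosphosite) at position 8; underscores only as a
    contiguous N- and/or C-terminal pad; no ambiguity code X.
    """
    if len(peptide) != FLANK_LEN:
        raise RowRejectError("bad_flank_length", peptide)
    if not re.fullmatch(r"[A-Za-z_]+", peptide):
        raise RowRejectError("bad_flank_char", peptide)
    lowers = [i for i, c in enumerate(peptide) if c.islower()]
    if lowers != [SITE_POS - 1]:
        raise RowRejectError("site_not_centered", peptide)
    stripped = peptide.strip("_")
    if "_" in stripped:
        raise RowRejectError("bad_padding", peptide)
    upper = peptide.upper()
    if "X" in upper:
        raise RowRejectError("ambiguous_residue", peptide)
    return upper


def _split_antibody_ids(raw: str) -> tuple[str, ...]:
    if not raw:
        return ()
    return tuple(tok.strip() for tok in re.split(r"[;,]", raw) if tok.strip())


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def parse_catalog(
    path: str | Path,
    species_filter: set[str] | None = None,
    require_antibody: bool = True,
    column_map: dict[str, str] | None = None,
) -> tuple[list[PhosphoSiteRecord], list[RowReject]]:
    """Parse a catalog file into records plus a rejects report.

    ``species_filter`` keeps only rows whose species token (case-insensitive)
    is in the set; ``require_antibody`` drops rows without any antibody
    catalog number.  Both exclusions are recorded in the rejects list under
    their own reason codes so every row is accounted for.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    if species_filter is not None:
        species_filter = {s.lower() for s in species_filter}

    records: list[PhosphoSiteRecord] = []
    rejects: list[RowReject] = []
    with _open_text(path) as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise CatalogError(f"empty catalog file: {path}")
        index: dict[str, int] = {}
        for key in ("gene", "accession", "species", "mod_rsd", "flank"):
            name = cols[key]
            if name not in header:
                raise CatalogError(f"missing mandatory column {name!r} in {path}")
            index[key] = header.index(name)
        ab_idx = header.index(cols["antibody"]) if cols["antibody"] in header else None

        for row_number, row in enumerate(reader, start=1):
            raw = "\t".join(row)
            if not any(field.strip() for field in row):
                continue
            try:
                if len(row) <= max(index.values()):
                    raise RowRejectError("short_row", raw)
                species = row[index["species"]].strip()
                if species_filter is not None and species.lower() not in species_filter:
                    raise RowRejectError("species_excluded", species)
                antibody_ids = (
                    _split_antibody_ids(row[ab_idx].strip())
                    if ab_idx is not None and ab_idx < len(row)
                    else ()
                )
                if require_antibody and not antibody_ids:
                    raise RowRejectError("no_antibody_id")
                residue, position = parse_mod_rsd(row[index["mod_rsd"]])
                flank = normalize_flank(row[index["flank"]].strip())
                if flank[SITE_POS - 1] != residue:
                    raise RowRejectError(
                        "site_residue_mismatch",
                        f"{row[index['mod_rsd']]} vs {row[index['flank']]}",
                    )
                records.append(
                    PhosphoSiteRecord(
                        source_species=species,
                        gene_symbol=row[index["gene"]].strip(),
                        protein_accession=row[index["accession"]].strip(),
                        residue=residue,
                        position=position,
                        flank_peptide=flank,
                        antibody_ids=antibody_ids,
                    )
                )
            except RowRejectError as exc:
                rejects.append(RowReject(row_number, exc.reason, raw))
    return records, rejects


def write_catalog(
    records: Iterable[PhosphoSiteRecord],
    path: str | Path,
    column_map: dict[str, str] | None = None,
) -> None:
    """Write records back out in the catalog dialect (site lowercased)."""
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [cols[k] for k in ("gene", "accession", "species", "mod_rsd", "flank", "antibody")]
        )
        for rec in records:
            flank = rec.flank_peptide
            flank = flank[: SITE_POS - 1] + flank[SITE_POS - 1].lower() + flank[SITE_POS:]
            writer.writerow(
                [
                    rec.gene_symbol,
                    rec.protein_accession,
                    rec.source_species,
                    f"{rec.residue}{rec.position}-p",
                    flank,
                    ";".join(rec.antibody_ids),
                ]
            )


def write_rejects(rejects: Iterable[RowReject], path: str | Path) -> None:
    """Write the rejects report TSV (row_number, reason_code, raw_line)."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["row_number", "reason_code", "raw_line"])
        for rej in rejects:
            writer.writerow([rej.row_number, rej.reason, rej.raw_line])
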