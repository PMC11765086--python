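"""Anchoring catalog phosphosites onto current full-length proteins.

Catalog rows describe a site by accession + position + flank peptide, but
accessions go stale and isoform coordinates drift between releases.
Anchoring validates each record against the loaded proteome, in order:

1. accession lookup and positional check (residue and full flank match at
   the stated position) → ``anchored_direct``;
2. accession lookup and a flank-peptide scan of the whole protein, accepting
   a unique hit elsewhere → ``anchored_shifted`` with the corrected
   position;
3. gene-symbol rescue: map the catalog gene symbol to gene id(s), scan every
   protein of those genes for the flank, accepting a single unique hit →
   ``rescued_by_symbol``;
4. otherwise ``failed`` with a reason code.

Matching is exact (mismatch tolerance belongs to the conservation stage,
not to site validation) and ambiguity — the peptide occurring at several
positions, or the rescue finding several candidate genes/proteins — fails
the record rather than guessing: a false anchor would poison every
downstream alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

from .catalog_io import PhosphoSiteRecord, SITE_POS
from .reference_store import GeneIdMap, ProteinRecord, ProteinStore

#: Anchoring status codes.
ANCHORED_DIRECT = "anchored_direct"
ANCHORED_SHIFTED = "anchored_shifted"
RESCUED_BY_SYMBOL = "rescued_by_symbol"
FAILED = "failed"

#: Failure reason codes.
NO_PROTEIN = "no_protein"
PEPTIDE_NOT_FOUND = "peptide_not_found"
AMBIGUOUS_PEPTIDE = "ambiguous_peptide"
AMBIGUOUS_GENE = "ambiguous_gene"


@dataclass(frozen=True)
class AnchoredSite:
    record: PhosphoSiteRecord
    protein: ProteinRecord | None
    site_position: int | None  # 1-based on protein.sequence
    status: str
    failure_reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.status != FAILED


def locate_peptide(flank_peptide: str, sequence: str) -> list[int]:
    """All 1-based site positions where the flank matches the sequence.

    The non-underscore core of the 15-mer must match exactly; underscore
    padding anchors the match to the corresponding sequence terminus.  The
    returned position is where the site character (flank index 8, 1-based)
    lands.
    """
    flank = flank_peptide.upper()
    core = flank.strip("_")
    if not core or "_" in core:
        raise ValueError(f"malformed flank peptide {flank_peptide!r}")
    n_prefix = len(flank) - len(flank.lstrip("_"))
    n_suffix = len(flank) - len(flank.rstrip("_"))
    site_in_core = (SITE_POS - 1) - n_prefix  # 0-based within core
    seq = sequence.upper()
    positions: list[int] = []
    start = 0
    while True:
        idx = seq.find(core, start)
        if idx < 0:
            break
        start = idx + 1
        if n_prefix and idx != 0:
            continue
        if n_suffix and idx + len(core) != len(seq):
            continue
        positions.append(idx + site_in_core + 1)
    return positions


def _matches_at(record: PhosphoSiteRecord, sequence: str) -> bool:
    """Does the flank match the sequence with the site at record.position?"""
    return record.position in locate_peptide(record.flank_peptide, sequence)


def anchor_site(
    record: PhosphoSiteRecord,
    protein_store: ProteinStore,
    gene_map: GeneIdMap | None = None,
) -> AnchoredSite:
    """Resolve one catalog record onto a concrete protein sequence.

    Deterministic and side-effect free; failures are returned as data
    (status + reason), never raised.
    """
    protein = protein_store.get(record.protein_accession)
    if protein is not None:
        pos = record.position
        if (
            1 <= pos <= len(protein.sequence)
            and protein.sequence[pos - 1] == record.residue
            and _matches_at(record, protein.sequence)
        ):
            return AnchoredSite(record, protein, pos, ANCHORED_DIRECT)
        hits = locate_peptide(record.flank_peptide, protein.sequence)
        if len(hits) == 1:
            return AnchoredSite(record, protein, hits[0], ANCHORED_SHIFTED)
        if len(hits) > 1:
            return AnchoredSite(record, protein, None, FAILED, AMBIGUOUS_PEPTIDE)
        # fall through to symbol rescue: peptide absent from this protein

    rescue = _rescue_by_symbol(record, protein_store, gene_map)
    if rescue is not None:
        return rescue
    reason = NO_PROTEIN if protein is None else PEPTIDE_NOT_FOUND
    return AnchoredSite(record, None, None, FAILED, reason)


def _rescue_by_symbol(
    record: PhosphoSiteRecord,
    protein_store: ProteinStore,
    gene_map: GeneIdMap | None,
) -> AnchoredSite | None:
    if gene_map is None:
        return None
    gene_ids = gene_map.lookup(record.gene_symbol, "symbol")
    if not gene_ids:
        return None
    matches: list[tuple[int, ProteinRecord, list[int]]] = []
    for gid in sorted(gene_ids):
        for prot in protein_store.isoforms(gid):
            hits = locate_peptide(record.flank_peptide, prot.sequence)
            if hits:
                matches.append((gid, prot, hits))
    if not matches:
        return None
    genes_hit = {gid for gid, _, _ in matches}
    if len(genes_hit) > 1:
        return AnchoredSite(record, None, None, FAILED, AMBIGUOUS_GENE)
    if len(matches) > 1 or len(matches[0][2]) > 1:
        return AnchoredSite(record, None, None, FAILED, AMBIGUOUS_PEPTIDE)
    _, prot, hits = matches[0]
    return AnchoredSite(record, prot, hits[0], RESCUED_BY_SYMBOL)
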