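"""Reference proteomes, gene-identifier maps and ortholog tables.

The pipeline joins four flat files: a FASTA proteome per species, a
gene-to-protein map (gene_id, protein_accession), an identifier map
(namespace, token, gene_id) for symbol/accession → gene-id resolution, and
an ortholog table with per-pair confidence ranks (high/moderate/low, an
opaque ordered label as produced by integrative ortholog predictors).

Accession versions drift between catalog releases and proteome releases, so
the version-stripped accession is the join key everywhere; both the
versioned and stripped forms resolve in the store.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

#: Sentinel gene id for proteins present in the FASTA but absent from the map.
UNMAPPED = -1

ALLOWED_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXUBZ*")

RANK_ORDER = {"high": 3, "moderate": 2, "low": 1}


def strip_version(accession: str) -> str:
    return accession.rsplit(".", 1)[0] if "." in accession else accession


@dataclass(frozen=True)
class ProteinRecord:
    accession: str  # as given in the FASTA (possibly versioned)
    species: str
    gene_id: int  # UNMAPPED if absent from the gene map
    sequence: str  # uppercase

    @property
    def accession_key(self) -> str:
        return strip_version(self.accession)


@dataclass(frozen=True)
class OrthologPair:
    source_gene_id: int
    target_gene_id: int
    rank: str  # high | moderate | low
    score: float | None = None

    def __post_init__(self):
        if self.rank not in RANK_ORDER:
            raise ValueError(f"unknown ortholog rank {self.rank!r}")


class ProteinStore:
    """Proteome for one species, keyed by accession and grouped by gene."""

    def __init__(self, species: str):
        self.species = species
        self._by_accession: dict[str, ProteinRecord] = {}
        self._by_gene: dict[int, list[ProteinRecord]] = defaultdict(list)

    def add(self, record: ProteinRecord) -> None:
        key = record.accession_key
        existing = self._by_accession.get(key)
        if existing is not None:
            if existing.sequence != record.sequence:
                raise ValueError(
                    f"duplicate accession {record.accession} with differing sequence"
                )
            return
        self._by_accession[key] = record
        if record.gene_id != UNMAPPED:
            self._by_gene[record.gene_id].append(record)

    def get(self, accession: str) -> ProteinRecord | None:
        return self._by_accession.get(strip_version(accession))

    def isoforms(self, gene_id: int) -> list[ProteinRecord]:
        """All proteins mapped to a gene, sorted by accession."""
        return sorted(self._by_gene.get(gene_id, []), key=lambda r: r.accession)

    def genes(self) -> list[int]:
        return sorted(self._by_gene)

    def __len__(self) -> int:
        return len(self._by_accession)

    def __iter__(self):
        return iter(self._by_accession.values())


def load_gene_map(path: str | Path) -> dict[str, int]:
    """Read a (gene_id, protein_accession) TSV into accession-key → gene id."""
    mapping: dict[str, int] = {}
    with open(path, encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or not {"gene_id", "protein_accession"} <= set(
            reader.fieldnames
        ):
            raise ValueError(f"gene map {path} needs columns gene_id, protein_accession")
        for row in reader:
            mapping[strip_version(row["protein_accession"].strip())] = int(row["gene_id"])
    return mapping


def load_proteome(
    fasta_path: str | Path,
    mapping_path: str | Path,
    species: str,
) -> ProteinStore:
    """Load a FASTA proteome and attach gene ids from a gene2protein map.

    The accession is the first whitespace-delimited header token.  Proteins
    without a gene mapping are retained with ``gene_id = UNMAPPED`` (they can
    still anchor a site by accession, just not contribute to per-gene isoform
    sets).  An empty FASTA or conflicting duplicate accessions are fatal.
    """
    mapping = load_gene_map(mapping_path)
    store = ProteinStore(species)
    n = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        n += 1
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for {rec.id} in {fasta_path}")
        bad = set(seq) - ALLOWED_ALPHABET
        if bad:
            raise ValueError(f"invalid residue(s) {sorted(bad)} in {rec.id}")
        gene_id = mapping.get(strip_version(rec.id), UNMAPPED)
        store.add(ProteinRecord(rec.id, species, gene_id, seq))
    if n == 0:
        raise ValueError(f"empty FASTA: {fasta_path}")
    return store


class GeneIdMap:
    """Identifier map: (namespace, token) → set of gene ids.

    Namespaces are ``symbol``, ``refseq``, ``uniprot``.  A token may map to
    several gene ids; the caller resolves (or flags) the ambiguity.
    """

    NAMESPACES = ("symbol", "refseq", "uniprot")

    def __init__(self):
        self._entries: dict[tuple[str, str], set[int]] = defaultdict(set)

    @classmethod
    def load(cls, path: str | Path) -> "GeneIdMap":
        obj = cls()
        with open(path, encoding="utf-8") as handle:
            reader = csv.DictReader(handle, delimiter="\t")
            if reader.fieldnames is None or not {"namespace", "token", "gene_id"} <= set(
                reader.fieldnames
            ):
                raise ValueError(f"id map {path} needs columns namespace, token, gene_id")
            for row in reader:
                obj.add(row["namespace"].strip(), row["token"].strip(), int(row["gene_id"]))
        return obj

    def add(self, namespace: str, token: str, gene_id: int) -> None:
        if namespace not in self.NAMESPACES:
            raise ValueError(f"unknown namespace {namespace!r}")
        self._entries[(namespace, token.upper())].add(gene_id)

    def lookup(self, token: str, namespace: str) -> frozenset[int]:
        """Possibly-empty set of gene ids for a token (case-insensitive)."""
        key = (namespace, strip_version(token).upper())
        return frozenset(self._entries.get(key, ()))


class OrthologTable:
    """Flat ortholog mapping with confidence ranks."""

    def __init__(self):
        self._pairs: dict[int, list[OrthologPair]] = defaultdict(list)

    @classmethod
    def load(cls, path: str | Path) -> "OrthologTable":
        obj = cls()
        with open(path, encoding="utf-8") as handle:
            reader = csv.DictReader(handle, delimiter="\t")
            needed = {"source_gene_id", "target_gene_id", "rank"}
            if reader.fieldnames is None or not needed <= set(reader.fieldnames):
                raise ValueError(f"ortholog table {path} needs columns {sorted(needed)}")
            for row in reader:
                score = row.get("score", "")
                obj.add(
                    OrthologPair(
                        source_gene_id=int(row["source_gene_id"]),
                        target_gene_id=int(row["target_gene_id"]),
                        rank=row["rank"].strip().lower(),
                        score=float(score) if score not in ("", None) else None,
                    )
                )
        return obj

    def add(self, pair: OrthologPair) -> None:
        self._pairs[pair.source_gene_id].append(pair)

    def get_orthologs(
        self, source_gene_id: int, min_rank: str = "moderate"
    ) -> list[OrthologPair]:
        """Pairs with rank ≥ ``min_rank`` under high > moderate > low.

        Unknown gene ids yield an empty list.  Results are ordered by
        descending rank then target gene id, deterministically.
        """
        threshold = RANK_ORDER[min_rank]
        pairs = [
            p for p in self._pairs.get(source_gene_id, []) if RANK_ORDER[p.rank] >= threshold
        ]
        return sorted(pairs, key=lambda p: (-RANK_ORDER[p.rank], p.target_gene_id))
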