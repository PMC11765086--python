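"""Deterministic synthetic fixture bundles with planted conservation structure.

Generates a self-consistent set of pipeline inputs — catalog, source and
target proteomes, gene map, identifier map, ortholog table — plus a truth
table stating, per planted phosphosite, the expected anchoring status and
conservation result.  Each gene carries one planted site drawn from a
conservation class:

``identical_15``
    target window identical to the source window.
``run_6`` .. ``run_14``
    an identical block of exactly k residues through the site, terminated
    by non-conservative substitutions.
``conservative_sub_pass``
    one conservative replacement three residues from the site; every
    window length still qualifies.
``adjacent_sub_fail``
    conservative replacements immediately flanking the site; no window
    qualifies (adjacency exclusion).
``site_mismatch_fail``
    the site residue itself substituted; run 0, nothing qualifies.
``gap_fail``
    a 3-residue deletion just C-terminal of the site plus two
    non-conservative substitutions N-terminal; no window qualifies.
``low_rank_fail``
    conserved window but the ortholog pair has rank "low", so the default
    confidence filter removes it.
``bad_accession_rescue``
    the catalog carries a stale accession; anchoring must fall back to the
    gene-symbol rescue path.
``shifted_position``
    the catalog position is wrong (isoform drift); the flank-peptide scan
    relocates the site.
``ambiguous_peptide_fail``
    the flank occurs twice on the protein and the stated position is wrong;
    anchoring must fail rather than guess.
``multi_isoform_mixed``
    two target isoforms, conserved only on the longer one.

Edits are rule-targeted, not evolutionary: windows are drawn without
replacement from the 20 amino acids (so flanks are locally unique and gap
placement in the aligner is strictly optimal), and expected conservation
values are derived by an internal literal-rule enumerator that is
independent of :mod:`cesa.conservation`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from . import catalog_io
from .catalog_io import PhosphoSiteRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
SITE0 = 7  # 0-based index of the site within a 15-mer window
_CANONICAL = frozenset(AA)

DEFAULT_ROSTER: tuple[str, ...] = (
    "identical_15",
    "run_6",
    "run_7",
    "run_8",
    "run_9",
    "run_10",
    "run_11",
    "run_12",
    "run_13",
    "run_14",
    "conservative_sub_pass",
    "adjacent_sub_fail",
    "site_mismatch_fail",
    "gap_fail",
    "low_rank_fail",
    "bad_accession_rescue",
    "shifted_position",
    "ambiguous_peptide_fail",
    "multi_isoform_mixed",
)

TRUTH_COLUMNS = [
    "site_id",
    "conservation_class",
    "gene_symbol",
    "source_gene_id",
    "target_gene_id",
    "isoform_accession",
    "expected_status",
    "expected_failure_reason",
    "expected_disposition",
    "expected_site_position",
    "expected_run",
    "expected_qualified_lengths",
    "expected_max_qualified",
]


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 20240
    n_genes: int = len(DEFAULT_ROSTER)
    protein_length: tuple[int, int] = (120, 200)
    classes: tuple[str, ...] | None = None
    lengths: tuple[int, ...] = (6, 7, 8, 9, 10, 11)

    def resolved_classes(self) -> list[str]:
        roster = self.classes if self.classes is not None else DEFAULT_ROSTER
        for cls in roster:
            _validate_class(cls)
        return [roster[i % len(roster)] for i in range(self.n_genes)]


def _validate_class(cls: str) -> None:
    if cls.startswith("run_"):
        k = int(cls.split("_", 1)[1])
        if not 6 <= k <= 14:
            raise ValueError(f"run_k class needs 6 <= k <= 14, got {cls}")
    elif cls not in DEFAULT_ROSTER:
        raise ValueError(f"unknown conservation class {cls!r}")


# ---------------------------------------------------------------------------
# literal-rule truth enumerator (independent of cesa.conservation)

_blosum = substitution_matrices.load("BLOSUM62")


def _truth_run(q: str, s: str) -> int:
    def same(i):
        return q[i] == s[i] and q[i] in _CANONICAL

    if not same(SITE0):
        return 0
    lo = hi = SITE0
    while lo > 0 and same(lo - 1):
        lo -= 1
    while hi < 14 and same(hi + 1):
        hi += 1
    return hi - lo + 1


def _truth_qualified(q: str, s: str, lengths) -> dict[int, bool]:
    out = {}
    for L in lengths:
        ok = False
        for st in range(0, 15 - L + 1):
            if not st <= SITE0 <= st + L - 1:
                continue
            mismatches = []
            valid = True
            for p in range(st, st + L):
                if q[p] not in _CANONICAL or s[p] not in _CANONICAL:
                    valid = False
                    break
                if q[p] != s[p]:
                    mismatches.append(p)
            if not valid or len(mismatches) > 1:
                continue
            if not mismatches:
                ok = True
                break
            p = mismatches[0]
            if abs(p - SITE0) > 1 and _blosum[q[p], s[p]] > 0:
                ok = True
                break
        out[L] = ok
    return out


# ---------------------------------------------------------------------------
# window construction helpers

def _conservative_partner(a: str, prefer_not: set[str]) -> str:
    # prefer a letter not already in the window (keeps residues distinct,
    # which pins gap placement), but fall back to any positive partner
    for forbid in (prefer_not, set()):
        for b in AA:
            if b != a and b not in forbid and _blosum[a, b] > 0:
                return b
    raise ValueError(f"no conservative partner for {a!r}")


def _nonconservative_partner(a: str, prefer_not: set[str]) -> str:
    for forbid in (prefer_not, set()):
        for b in AA:
            if b != a and b not in forbid and _blosum[a, b] <= 0:
                return b
    raise ValueError(f"no non-conservative partner for {a!r}")


def _sample_window(rng: np.random.Generator, site_residue: str) -> str:
    others = [a for a in AA if a != site_residue]
    order = rng.permutation(len(others))
    pick = [others[j] for j in order[:14]]
    return "".join(pick[:SITE0] + [site_residue] + pick[SITE0:])


def _set_residue(window: str, idx: int, residue: str) -> str:
    """Place ``residue`` at ``idx``, swapping out a duplicate to keep the
    window's residues distinct."""
    chars = list(window)
    if residue in chars:
        j = chars.index(residue)
        chars[j] = chars[idx]
    chars[idx] = residue
    return "".join(chars)


def plant_window(
    base_window: str, plan: list[tuple[int, str]], allow_site_edits: bool = False
) -> str:
    """Apply an edit plan to a 15-mer and return the mutated window.

    ``plan`` is a list of ``(offset_from_site, kind)`` with kind one of
    ``identical``, ``conservative``, ``non_conservative``, ``delete``.
    Edits at the site or site ± 1 are refused unless ``allow_site_edits``
    (they are only legitimate for fail-class constructions).  Deletions are
    applied after substitutions; with deletions the result is shorter than
    15 characters.
    """
    if len(base_window) != 15:
        raise ValueError("base window must be 15 characters")
    chars = list(base_window)
    present = set(chars)
    deletions = []
    for offset, kind in plan:
        idx = SITE0 + offset
        if not 0 <= idx <= 14:
            raise ValueError(f"edit offset {offset} outside the window")
        if kind == "identical":
            continue
        if abs(offset) <= 1 and not allow_site_edits:
            raise ValueError(f"edit at site offset {offset} requires allow_site_edits")
        if kind == "conservative":
            chars[idx] = _conservative_partner(chars[idx], present)
        elif kind == "non_conservative":
            chars[idx] = _nonconservative_partner(chars[idx], present)
        elif kind == "delete":
            deletions.append(idx)
        else:
            raise ValueError(f"unknown edit kind {kind!r}")
        if kind in ("conservative", "non_conservative"):
            present.add(chars[idx])
    for idx in sorted(deletions, reverse=True):
        del chars[idx]
    return "".join(chars)


# ---------------------------------------------------------------------------
# per-gene assembly

@dataclass
class _GeneBundle:
    catalog_record: PhosphoSiteRecord | None = None
    source_fasta: list[tuple[str, str]] = field(default_factory=list)
    target_fasta: list[tuple[str, str]] = field(default_factory=list)
    gene_map: list[tuple[int, str]] = field(default_factory=list)
    id_map: list[tuple[str, str, int]] = field(default_factory=list)
    orthologs: list[tuple[int, int, str, float]] = field(default_factory=list)
    truth: list[dict] = field(default_factory=list)


def _background(rng: np.random.Generator, length: int) -> str:
    return "".join(AA[j] for j in rng.integers(0, len(AA), size=length))


def _embed_once(rng, length, window, extra_window_at=None):
    """Background sequence with ``window`` planted at a random internal spot.

    Returns (sequence, 1-based site position[, second site position]).
    Regenerates until each planted 15-mer occurs exactly the intended number
    of times (collisions with random background are vanishingly rare but
    would corrupt the truth table)."""
    while True:
        p0 = int(rng.integers(30, length - 45))
        seq = _background(rng, length)
        seq = seq[:p0] + window + seq[p0 + 15:]
        positions = [p0]
        if extra_window_at is not None:
            p1 = p0
            while abs(p1 - p0) < 20:
                p1 = int(rng.integers(30, length - 45))
            seq = seq[:p1] + window + seq[p1 + 15:]
            positions.append(p1)
        if seq.count(window) == len(positions):
            return seq, sorted(pp + SITE0 + 1 for pp in positions)


def _truth_row(
    site_id, cls, symbol, src_gid, tgt_gid, acc, status, reason, disposition,
    site_pos, qwin=None, swin=None, lengths=(6, 7, 8, 9, 10, 11),
):
    if qwin is not None:
        run = _truth_run(qwin, swin)
        qualified = _truth_qualified(qwin, swin, lengths)
        qualified_str = ",".join(str(L) for L in lengths if qualified[L])
        max_q = max((L for L in lengths if qualified[L]), default=0)
    else:
        run, qualified_str, max_q = "", "", ""
    return {
        "site_id": site_id,
        "conservation_class": cls,
        "gene_symbol": symbol,
        "source_gene_id": src_gid,
        "target_gene_id": tgt_gid,
        "isoform_accession": acc,
        "expected_status": status,
        "expected_failure_reason": reason or "",
        "expected_disposition": disposition,
        "expected_site_position": site_pos if site_pos is not None else "",
        "expected_run": run,
        "expected_qualified_lengths": qualified_str,
        "expected_max_qualified": max_q,
    }


def _run_block_edits(k: int) -> list[tuple[int, str]]:
    """Non-conservative substitutions bounding an identical block of length k
    containing the site, never adjacent to the site itself."""
    start = min(max(8 - k // 2, max(1, 8 - k + 1)), min(8, 16 - k))  # 1-based
    edits = []
    for pos in (start - 1, start + k):
        if 1 <= pos <= 15:
            if abs(pos - 8) <= 1:
                raise ValueError("run block boundary landed next to the site")
            edits.append((pos - 8, "non_conservative"))
    return edits


def _build_gene(rng, i, cls, spec) -> _GeneBundle:
    b = _GeneBundle()
    symbol = f"GENE{i:03d}"
    src_gid, tgt_gid = 1000 + i, 5000 + i
    src_acc = f"NP_{100000 + i}.1"
    tgt_acc = f"XP_{200000 + i}.1"
    site_id = symbol
    length = int(rng.integers(*spec.protein_length))
    site_res = "STY"[int(rng.integers(3))]
    lengths = spec.lengths

    w = _sample_window(rng, site_res)
    rank = "high" if i % 2 == 0 else "moderate"
    score = round(5.0 + (i % 10) * 0.7, 1)
    stated_offset = 0  # catalog position error, 0 = correct
    catalog_acc = src_acc
    status, reason, disposition = "anchored_direct", "", "scored"

    # --- class-specific target window / topology -------------------------
    tgt_window = w
    tgt_region = None  # defaults to tgt_window
    expected_slice = None  # defaults to tgt_window
    extra_plant = False
    if cls == "identical_15":
        pass
    elif cls.startswith("run_"):
        k = int(cls.split("_", 1)[1])
        tgt_window = plant_window(w, _run_block_edits(k))
    elif cls == "conservative_sub_pass":
        w = _set_residue(w, SITE0 - 3, "K")
        tgt_window = plant_window(w, [(-3, "conservative")])
    elif cls == "adjacent_sub_fail":
        w = _set_residue(w, SITE0 - 1, "K")
        w = _set_residue(w, SITE0 + 1, "D")
        tgt_window = plant_window(
            w, [(-1, "conservative"), (1, "conservative")], allow_site_edits=True
        )
    elif cls == "site_mismatch_fail":
        tgt_window = plant_window(w, [(0, "non_conservative")], allow_site_edits=True)
    elif cls == "gap_fail":
        subbed = plant_window(w, [(-4, "non_conservative"), (-2, "non_conservative")])
        tgt_region = plant_window(
            subbed, [(1, "delete"), (2, "delete"), (3, "delete")], allow_site_edits=True
        )
        expected_slice = subbed[:8] + "---" + subbed[11:]
    elif cls == "low_rank_fail":
        rank = "low"
        status, disposition = "anchored_direct", "unmapped_ortholog"
    elif cls == "bad_accession_rescue":
        catalog_acc = f"NP_{900000 + i}.1"  # stale, absent from the proteome
        status = "rescued_by_symbol"
    elif cls == "shifted_position":
        status = "anchored_shifted"
    elif cls == "ambiguous_peptide_fail":
        extra_plant = True
        status, reason, disposition = "failed", "ambiguous_peptide", "anchor_failed"
    elif cls == "multi_isoform_mixed":
        pass
    else:  # pragma: no cover - guarded by _validate_class
        raise ValueError(cls)

    # --- source protein ---------------------------------------------------
    if extra_plant:
        source_seq, positions = _embed_once(rng, length, w, extra_window_at=True)
        site_pos = positions[0]
    else:
        source_seq, positions = _embed_once(rng, length, w)
        site_pos = positions[0]

    stated_pos = site_pos
    if cls in ("shifted_position", "ambiguous_peptide_fail"):
        # stated position must be wrong and must not coincidentally carry the
        # site residue, so that the positional check fails and the scan runs
        stated_pos = next(
            p
            for p in range(site_pos + 5, len(source_seq) + 1)
            if source_seq[p - 1] != site_res and p not in positions
        )

    # --- target protein(s) ------------------------------------------------
    p0 = site_pos - 8  # 0-based window start on the source protein
    region = tgt_region if tgt_region is not None else tgt_window
    target_seq = source_seq[:p0] + region + source_seq[p0 + 15:]
    qslice = w
    sslice = expected_slice if expected_slice is not None else tgt_window

    b.source_fasta.append((src_acc, source_seq))
    b.gene_map.append((src_gid, src_acc))
    b.id_map.append(("symbol", symbol, src_gid))
    b.orthologs.append((src_gid, tgt_gid, rank, score))
    b.catalog_record = PhosphoSiteRecord(
        source_species="human",
        gene_symbol=symbol,
        protein_accession=catalog_acc,
        residue=site_res,
        position=stated_pos,
        flank_peptide=w,
        antibody_ids=(f"CST{10000 + i}",),
    )

    if cls == "multi_isoform_mixed":
        tail = _background(rng, 30)
        long_acc = f"XP_{200000 + i}.1"
        short_acc = f"XP_{250000 + i}.1"
        short_window = plant_window(w, [(0, "non_conservative")], allow_site_edits=True)
        short_seq = source_seq[:p0] + short_window + source_seq[p0 + 15:]
        b.target_fasta.append((long_acc, target_seq + tail))
        b.target_fasta.append((short_acc, short_seq))
        b.gene_map.append((tgt_gid, long_acc))
        b.gene_map.append((tgt_gid, short_acc))
        b.truth.append(
            _truth_row(site_id, cls, symbol, src_gid, tgt_gid, long_acc,
                       status, reason, disposition, site_pos, w, w, lengths)
        )
        b.truth.append(
            _truth_row(site_id, cls, symbol, src_gid, tgt_gid, short_acc,
                       status, reason, disposition, site_pos, w, short_window, lengths)
        )
        return b

    b.target_fasta.append((tgt_acc, target_seq))
    b.gene_map.append((tgt_gid, tgt_acc))
    if disposition == "scored":
        b.truth.append(
            _truth_row(site_id, cls, symbol, src_gid, tgt_gid, tgt_acc,
                       status, reason, disposition, site_pos, qslice, sslice, lengths)
        )
    else:
        site_for_truth = None if disposition == "anchor_failed" else site_pos
        b.truth.append(
            _truth_row(site_id, cls, symbol, src_gid, tgt_gid if disposition != "anchor_failed" else "",
                       "" if disposition == "anchor_failed" else tgt_acc,
                       status, reason, disposition, site_for_truth, None, None, lengths)
        )
    return b


# ---------------------------------------------------------------------------
# bundle assembly

def _write_fasta(path: Path, entries: list[tuple[str, str]]) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for acc, seq in entries:
            handle.write(f">{acc}\n")
            for j in range(0, len(seq), 60):
                handle.write(seq[j:j + 60] + "\n")


def _write_tsv(path: Path, header: list[str], rows) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow(row)


def make_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate the full fixture bundle under ``out_dir``.

    Same spec (same seed) → byte-identical files.  Returns the paths of the
    seven files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    bundles = [
        _build_gene(rng, i, cls, spec)
        for i, cls in enumerate(spec.resolved_classes())
    ]

    paths = {
        "catalog": out / "catalog.tsv",
        "source_fasta": out / "source.fasta",
        "target_fasta": out / "target.fasta",
        "gene_map": out / "gene_map.tsv",
        "id_map": out / "id_map.tsv",
        "orthologs": out / "orthologs.tsv",
        "truth": out / "truth.tsv",
    }
    catalog_io.write_catalog([b.catalog_record for b in bundles], paths["catalog"])
    _write_fasta(paths["source_fasta"], [e for b in bundles for e in b.source_fasta])
    _write_fasta(paths["target_fasta"], [e for b in bundles for e in b.target_fasta])
    _write_tsv(
        paths["gene_map"],
        ["gene_id", "protein_accession"],
        [row for b in bundles for row in b.gene_map],
    )
    _write_tsv(
        paths["id_map"],
        ["namespace", "token", "gene_id"],
        [row for b in bundles for row in b.id_map],
    )
    _write_tsv(
        paths["orthologs"],
        ["source_taxon", "source_gene_id", "target_taxon", "target_gene_id", "rank", "score"],
        [("9606", sg, "7227", tg, rank, score) for b in bundles for sg, tg, rank, score in b.orthologs],
    )
    _write_tsv(
        paths["truth"],
        TRUTH_COLUMNS,
        [[row[c] for c in TRUTH_COLUMNS] for b in bundles for row in b.truth],
    )
    return paths
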