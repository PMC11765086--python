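"""Global pairwise protein alignment and phosphosite transfer.

Each anchored source protein is aligned against every isoform of every
ortholog gene with the Needleman–Wunsch global algorithm under an affine
gap model (BLOSUM62, gap open 11, gap extend 1 by default, following the
common BLAST convention where a gap of length k costs open + k·extend).
The phosphosite is then carried through the alignment column holding it to
find the aligned residue — or gap — on the subject.

Residues outside the substitution matrix alphabet (e.g. selenocysteine U)
are scored as X during alignment but the original letters are restored in
the gapped output, so downstream identity checks still see them (and treat
them as never identical).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

GAP = "-"


@dataclass(frozen=True)
class AlignmentParams:
    """Substitution matrix and affine gap costs (configurable)."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11  # cost of the first gapped position
    gap_extend: int = 1  # cost of each gapped position, including the first


DEFAULT_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class SiteAlignmentContext:
    """A pairwise alignment together with the located phosphosite column."""

    aligned_query: str
    aligned_subject: str
    site_column: int  # 0-based alignment column of the query phosphosite
    subject_site_position: int | None  # 1-based on ungapped subject; None if gap
    subject_site_residue: str  # residue, or the gap sentinel
    alignment_score: float


@lru_cache(maxsize=8)
def _make_aligner(params: AlignmentParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    # Biopython charges open_gap_score for the first gapped position and
    # extend_gap_score for each further one; -(open+extend) at the first
    # position reproduces the open + k*extend convention.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _sanitize(sequence: str, alphabet: str) -> str:
    allowed = set(alphabet)
    return "".join(c if c in allowed else "X" for c in sequence)


def _restore(gapped: str, original: str) -> str:
    # Re-insert the original letters behind the gap structure.
    it = iter(original)
    return "".join(c if c == GAP else next(it) for c in gapped)


def global_align(
    query_sequence: str,
    subject_sequence: str,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> tuple[str, str, float]:
    """Needleman–Wunsch global alignment with affine gaps.

    Returns ``(aligned_query, aligned_subject, score)``.  Among co-optimal
    alignments the first one enumerated by the aligner is taken, which is
    deterministic for fixed inputs and parameters.
    """
    if not query_sequence or not subject_sequence:
        raise ValueError("cannot align an empty sequence")
    query = query_sequence.upper()
    subject = subject_sequence.upper()
    aligner = _make_aligner(params)
    alphabet = str(aligner.substitution_matrix.alphabet)
    alignments = aligner.align(_sanitize(query, alphabet), _sanitize(subject, alphabet))
    best = alignments[0]
    aligned_q = _restore(best[0], query)
    aligned_s = _restore(best[1], subject)
    return aligned_q, aligned_s, float(best.score)


def transfer_site(
    aligned_query: str,
    aligned_subject: str,
    query_site_position: int,
    alignment_score: float = 0.0,
) -> SiteAlignmentContext:
    """Locate the alignment column of a query position and read the subject.

    ``query_site_position`` is 1-based on the ungapped query.  When the
    subject carries a gap at that column the residue is the gap sentinel and
    the subject position is None (the site cannot be conserved).
    """
    if len(aligned_query) != len(aligned_subject):
        raise ValueError("aligned sequences must have equal length")
    seen = 0
    site_column = -1
    for col, c in enumerate(aligned_query):
        if c != GAP:
            seen += 1
            if seen == query_site_position:
                site_column = col
                break
    if site_column < 0:
        raise ValueError(
            f"query site position {query_site_position} beyond ungapped length {seen}"
        )
    subject_char = aligned_subject[site_column]
    if subject_char == GAP:
        subject_pos = None
    else:
        subject_pos = sum(1 for c in aligned_subject[: site_column + 1] if c != GAP)
    return SiteAlignmentContext(
        aligned_query=aligned_query,
        aligned_subject=aligned_subject,
        site_column=site_column,
        subject_site_position=subject_pos,
        subject_site_residue=subject_char,
        alignment_score=alignment_score,
    )


def align_and_transfer(
    query_sequence: str,
    subject_sequence: str,
    query_site_position: int,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> SiteAlignmentContext:
    """Convenience composition of :func:`global_align` and :func:`transfer_site`."""
    aligned_q, aligned_s, score = global_align(query_sequence, subject_sequence, params)
    return transfer_site(aligned_q, aligned_s, query_site_position, score)


def write_pair_fasta(context: SiteAlignmentContext, path, query_id="query", subject_id="subject"):
    """Dump one alignment as two-row gapped FASTA (debugging aid)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f">{query_id} site_column={context.site_column}\n")
        handle.write(context.aligned_query + "\n")
        handle.write(f">{subject_id}\n")
        handle.write(context.aligned_subject + "\n")
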