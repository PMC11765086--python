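"""Phosphosite-neighborhood conservation scoring.

An antibody raised against a phosphopeptide recognizes roughly the 15-mer
centered on the phosphorylated residue (±7 amino acids).  Whether it will
cross-react with the orthologous protein in a second species depends on how
well that neighborhood is conserved.  Two statistics are computed on a pair
of aligned 15-residue windows with the phosphosite at position 8:

* ``longest_identical_run`` — the length of the maximal contiguous block of
  identical residues that contains the site (the "conserved region,
  continuous AA" statistic).  Zero when the site residue itself differs.
* window qualification — for each window length L (default 6..11), whether
  some contiguous sub-window of length L containing the site is identical
  everywhere except at most one *conservative* replacement (strictly
  positive substitution-matrix score, BLOSUM62 by default) that is neither
  at the site nor immediately adjacent to it.

Gap characters and underscore terminus padding are never identical to
anything and disqualify any window they fall in: an indel inside the epitope
breaks the recognition surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Align import substitution_matrices

#: Residues that may count as identical or conservatively substituted.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Gap sentinel used in alignment slices.
GAP = "-"

#: Window lengths evaluated by default.
DEFAULT_LENGTHS: tuple[int, ...] = (6, 7, 8, 9, 10, 11)

WINDOW_SIZE = 15
SITE_INDEX = 8  # 1-based position of the phosphosite within the window


@lru_cache(maxsize=8)
def load_matrix(name: str = "BLOSUM62"):
    """Load a named substitution matrix (cached)."""
    return substitution_matrices.load(name)


def _identical(a: str, b: str) -> bool:
    # Gap, underscore padding and ambiguity codes (X/U/B/Z) never match.
    return a == b and a in CANONICAL_AA


@dataclass(frozen=True)
class ConservationResult:
    """Conservation of one phosphosite neighborhood.

    Attributes
    ----------
    longest_identical_run : int
        Maximal contiguous identical stretch through the site; 0 when the
        site residue differs or is gapped.
    qualified_lengths : dict[int, bool]
        For each evaluated window length L, whether some L-window containing
        the site passes the one-conservative-replacement rule.
    max_qualified_length : int
        Largest qualifying L, or 0.
    substitution_note : tuple[int, str, str] | None
        (1-based window position, query residue, subject residue) of the
        allowed replacement in the longest qualifying window, if one was
        used.
    site_identical : bool
        Whether the site residue itself is identical.
    """

    longest_identical_run: int
    qualified_lengths: dict[int, bool] = field(compare=False)
    max_qualified_length: int
    substitution_note: tuple[int, str, str] | None
    site_identical: bool


def longest_identical_run(
    query_window: str, subject_window: str, site_index: int = SITE_INDEX
) -> int:
    """Length of the maximal identical block containing the site.

    Both windows must be exactly 15 characters; comparison is
    case-insensitive; underscores and gaps terminate (and never extend) a
    run.  Returns 0 if the two windows differ at ``site_index``.
    """
    if len(query_window) != WINDOW_SIZE or len(subject_window) != WINDOW_SIZE:
        raise ValueError("windows must be exactly 15 characters")
    if not 1 <= site_index <= WINDOW_SIZE:
        raise ValueError(f"site_index {site_index} out of range 1..{WINDOW_SIZE}")
    q = query_window.upper()
    s = subject_window.upper()
    i = site_index - 1
    if not _identical(q[i], s[i]):
        return 0
    left = i
    while left > 0 and _identical(q[left - 1], s[left - 1]):
        left -= 1
    right = i
    while right < WINDOW_SIZE - 1 and _identical(q[right + 1], s[right + 1]):
        right += 1
    return right - left + 1


def is_conservative_substitution(a: str, b: str, matrix=None) -> bool:
    """True iff ``a`` → ``b`` is a conservative amino-acid replacement.

    Operationalized as a strictly positive entry of the similarity matrix
    (default BLOSUM62) between two *different* canonical residues.
    Symmetric; any non-standard letter is never conservative.
    """
    a = a.upper()
    b = b.upper()
    if a == b or a not in CANONICAL_AA or b not in CANONICAL_AA:
        return False
    if matrix is None:
        matrix = load_matrix()
    return matrix[a, b] > 0


def _window_ok(
    q: str,
    s: str,
    start: int,
    length: int,
    site0: int,
    matrix,
    allow_substitution: bool,
) -> tuple[bool, tuple[int, str, str] | None]:
    note = None
    for p in range(start, start + length):
        a, b = q[p], s[p]
        if a not in CANONICAL_AA or b not in CANONICAL_AA:
            return False, None
        if a == b:
            continue
        # one mismatch allowed: conservative, not at the site, not adjacent
        if not allow_substitution or note is not None:
            return False, None
        if abs(p - site0) <= 1:
            return False, None
        if not is_conservative_substitution(a, b, matrix):
            return False, None
        note = (p + 1, a, b)
    return True, note


def window_qualifies(
    query_window: str,
    subject_window: str,
    site_index: int = SITE_INDEX,
    length: int = 6,
    matrix=None,
    allow_substitution: bool = True,
) -> tuple[bool, tuple[int, str, str] | None]:
    """Does some length-``length`` sub-window containing the site qualify?

    Qualification: every position identical except at most one, which must
    be a conservative substitution located neither at the site nor at
    site ± 1.  Windows touching a gap or underscore never qualify.  Returns
    ``(qualifies, substitution_note)`` where the note records the replacement
    the first qualifying window used, if any, as (1-based window position,
    query residue, subject residue).
    """
    if not 6 <= length <= WINDOW_SIZE:
        raise ValueError(f"window length {length} out of range 6..{WINDOW_SIZE}")
    if len(query_window) != WINDOW_SIZE or len(subject_window) != WINDOW_SIZE:
        raise ValueError("windows must be exactly 15 characters")
    if matrix is None:
        matrix = load_matrix()
    q = query_window.upper()
    s = subject_window.upper()
    site0 = site_index - 1
    for start in range(max(0, site0 - length + 1), min(WINDOW_SIZE - length, site0) + 1):
        ok, note = _window_ok(q, s, start, length, site0, matrix, allow_substitution)
        if ok:
            return True, note
    return False, None


def score_windows(
    query_window: str,
    subject_window: str,
    site_index: int = SITE_INDEX,
    lengths: tuple[int, ...] = DEFAULT_LENGTHS,
    matrix=None,
    allow_substitution: bool = True,
) -> ConservationResult:
    """Score a raw pair of 15-mer windows (no alignment involved).

    This is the direct-comparison code path used for flank-peptide pairs;
    :func:`score_site` applies the same rule to a 15-column alignment slice.
    """
    if matrix is None:
        matrix = load_matrix()
    q = query_window.upper()
    s = subject_window.upper()
    site0 = site_index - 1
    site_ok = _identical(q[site0], s[site0])
    run = longest_identical_run(q, s, site_index)
    qualified: dict[int, bool] = {}
    best_note = None
    max_l = 0
    for length in sorted(lengths):
        ok, note = window_qualifies(
            q, s, site_index, length, matrix, allow_substitution
        )
        qualified[length] = ok
        if ok:
            max_l = length
            best_note = note
    return ConservationResult(
        longest_identical_run=run,
        qualified_lengths=qualified,
        max_qualified_length=max_l,
        substitution_note=best_note,
        site_identical=site_ok,
    )


def score_site(
    context,
    lengths: tuple[int, ...] = DEFAULT_LENGTHS,
    matrix=None,
    allow_substitution: bool = True,
) -> ConservationResult:
    """Score conservation around an aligned phosphosite.

    Takes a :class:`cesa.alignment.SiteAlignmentContext`, extracts the
    15-column slice of the alignment centered on the site column (padding
    with the gap sentinel past the alignment ends) and applies the window
    rule.  Gap columns inside a candidate window disqualify it; a gap at the
    site column yields an all-false result.
    """
    flank = (WINDOW_SIZE - 1) // 2
    col = context.site_column
    n = len(context.aligned_query)
    q_slice = "".join(
        context.aligned_query[c] if 0 <= c < n else GAP
        for c in range(col - flank, col + flank + 1)
    )
    s_slice = "".join(
        context.aligned_subject[c] if 0 <= c < n else GAP
        for c in range(col - flank, col + flank + 1)
    )
    return score_windows(
        q_slice,
        s_slice,
        site_index=SITE_INDEX,
        lengths=lengths,
        matrix=matrix,
        allow_substitution=allow_substitution,
    )
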