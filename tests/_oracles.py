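"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (literal rule
enumeration, naive scanning, small dynamic programs) without importing the
implementation paths they check.
"""

from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")
CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")
NEG = float("-inf")


def brute_locate(flank: str, sequence: str) -> list[int]:
    """All 1-based site positions: naive comparison at every offset."""
    flank = flank.upper()
    seq = sequence.upper()
    hits = []
    # pad the sequence conceptually with underscores so terminal padding in
    # the flank can only match beyond the sequence ends
    for start in range(-14, len(seq)):
        ok = True
        for k, f in enumerate(flank):
            p = start + k
            c = seq[p] if 0 <= p < len(seq) else "_"
            if f == "_":
                if c != "_":
                    ok = False
                    break
            elif f != c:
                ok = False
                break
        if ok:
            site = start + 7  # 0-based
            if 0 <= site < len(seq):
                hits.append(site + 1)
    return hits


def brute_window_qualifies(query: str, subject: str, length: int, site_index: int = 8,
                           allow_substitution: bool = True) -> bool:
    """Literal enumeration of every length-L sub-window containing the site."""
    q, s = query.upper(), subject.upper()
    site0 = site_index - 1
    for start in range(0, 15 - length + 1):
        end = start + length - 1
        if not start <= site0 <= end:
            continue
        diffs = [p for p in range(start, end + 1) if q[p] != s[p]]
        if any(q[p] not in CANONICAL or s[p] not in CANONICAL for p in range(start, end + 1)):
            continue
        if not diffs:
            return True
        if not allow_substitution or len(diffs) > 1:
            continue
        p = diffs[0]
        if p in (site0 - 1, site0, site0 + 1):
            continue
        if BLOSUM62[q[p], s[p]] > 0:
            return True
    return False


def gotoh_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Affine-gap global alignment score (gap of length k costs open + k*extend).

    Three-state Gotoh recursion with end gaps penalized; scores only."""
    first = gap_open + gap_extend  # charge for the first gapped position
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = sub + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
        for j in range(0, m + 1):
            if i >= 1:
                X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend,
                              Y[i - 1][j] - first)
            if j >= 1:
                Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend,
                              X[i][j - 1] - first)
    return max(M[n][m], X[n][m], Y[n][m])
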