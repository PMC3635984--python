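"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package implementations: the
aligner oracle is a top-down memoized recursion over the classic global
alignment DP, the substring oracle is Python's own ``in`` operator, and the
Welch oracle is the textbook formula evaluated term by term.
"""

from __future__ import annotations

import math
from functools import lru_cache

from scipy import stats

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oracle_global_identity(seq_a, seq_b, match=1.0, mismatch=-1.0, gap=-2.0):
    """Global alignment identity by memoized recursion + greedy traceback.

    Ties between predecessors are resolved diagonal > up > left, the same
    documented convention as the package (identity among co-optimal
    alignments is otherwise not unique).  Sequences are canonically ordered
    first, mirroring the package's symmetry guarantee.
    """
    if seq_a > seq_b:
        seq_a, seq_b = seq_b, seq_a
    a, b = seq_a, seq_b

    @lru_cache(maxsize=None)
    def score(i: int, j: int) -> float:
        if i == 0 and j == 0:
            return 0.0
        best = -math.inf
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            best = max(best, score(i - 1, j - 1) + s)
        if i > 0:
            best = max(best, score(i - 1, j) + gap)
        if j > 0:
            best = max(best, score(i, j - 1) + gap)
        return best

    i, j = len(a), len(b)
    ident = cols = 0
    while i > 0 or j > 0:
        cols += 1
        cur = score(i, j)
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            if cur == score(i - 1, j - 1) + s:
                ident += a[i - 1] == b[j - 1]
                i, j = i - 1, j - 1
                continue
        if i > 0 and cur == score(i - 1, j) + gap:
            i -= 1
            continue
        j -= 1
    return ident / cols


def oracle_is_known(query: str, *databases: dict[str, str]) -> bool:
    """Brute-force minus-strand perfect-match screen."""
    rc = revcomp(query.upper())
    return any(rc in ref for db in databases for ref in db.values())


def oracle_welch(x, y):
    """Welch t, Welch–Satterthwaite df and two-sided p, from the raw formula."""
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p
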