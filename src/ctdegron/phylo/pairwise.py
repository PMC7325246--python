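"""Affine-gap global pairwise alignment (Gotoh) and p-distances.

Gap cost convention: a run of L gap characters costs
``gap_open + gap_extend * (L - 1)``, so with open=extend=1 each gap
character costs 1. Tie-breaking during traceback is deterministic:
match/mismatch is preferred over a gap in ``a``, which is preferred over
a gap in ``b``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

from ..errors import InvalidArgumentError

NEG_INF = float("-inf")

#: Poisson-corrected distance assigned when p >= 1 (flagged maximal).
MAX_CORRECTED_DISTANCE = -math.log(1e-12)


@lru_cache(maxsize=1)
def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scores plus affine gap costs (both costs nonnegative)."""

    substitution: dict = field(repr=False)
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend >= 0):
            raise InvalidArgumentError(
                f"need gap_open >= gap_extend >= 0, got {self.gap_open}/{self.gap_extend}"
            )

    def score(self, a: str, b: str) -> float:
        return self.substitution[(a, b)]

    @classmethod
    def blosum62(cls, gap_open: float = 11.0, gap_extend: float = 1.0) -> "ScoringScheme":
        m = _blosum62()
        table = {}
        for x in m.alphabet:
            for y in m.alphabet:
                table[(x, y)] = float(m[x, y])
        return cls(substitution=table, gap_open=gap_open, gap_extend=gap_extend)

    @classmethod
    def simple(cls, match: float = 1.0, mismatch: float = -1.0,
               gap_open: float = 1.0, gap_extend: float = 1.0) -> "ScoringScheme":
        return cls(substitution=_UniformTable(match, mismatch),
                   gap_open=gap_open, gap_extend=gap_extend)


class _UniformTable(dict):
    """Match/mismatch scores over any alphabet."""

    def __init__(self, match: float, mismatch: float):
        super().__init__()
        self.match = match
        self.mismatch = mismatch

    def __missing__(self, key):
        a, b = key
        return self.match if a == b else self.mismatch


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float

    def __iter__(self):
        yield self.aligned_a
        yield self.aligned_b


# traceback states, in preference order on score ties
_M, _GAP_IN_A, _GAP_IN_B = 0, 1, 2


def global_align(a: str, b: str, scheme: ScoringScheme | None = None) -> PairwiseAlignment:
    """Optimal global alignment of two sequences under affine gap costs."""
    if not a or not b:
        raise InvalidArgumentError("sequences must be non-empty")
    if scheme is None:
        scheme = ScoringScheme.blosum62()

    # DP on reversed sequences so the right-to-left traceback preference
    # (match > gap-in-a > gap-in-b) applies to leftmost columns first,
    # placing unavoidable gaps as late as possible.
    ra, rb = a[::-1], b[::-1]

    def sub(i, j):
        return scheme.score(ra[i - 1], rb[j - 1])

    cols_a, cols_b, score = _affine_dp(len(a), len(b), sub,
                                       scheme.gap_open, scheme.gap_extend)
    aligned_a = "".join(ra[i - 1] if i else "-" for i in cols_a)[::-1]
    aligned_b = "".join(rb[j - 1] if j else "-" for j in cols_b)[::-1]
    return PairwiseAlignment(aligned_a, aligned_b, score)


def _affine_dp(n: int, m: int, sub, gap_open: float, gap_extend: float):
    """Gotoh DP over an (n x m) grid with a callable substitution score.

    Returns (cols_a, cols_b, score) where cols_* give, per alignment
    column, the 1-based index consumed from that side (0 = gap). Shared
    between sequence-level and profile-level alignment.
    """
    go, ge = gap_open, gap_extend
    # M: both consumed; A: gap in a (consume b); B: gap in b (consume a)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    A = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    B = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        A[0][j] = -(go + ge * (j - 1))
    for i in range(1, n + 1):
        B[i][0] = -(go + ge * (i - 1))
    for i in range(1, n + 1):
        Mi, Ai, Bi = M[i], A[i], B[i]
        Mp, Ap, Bp = M[i - 1], A[i - 1], B[i - 1]
        for j in range(1, m + 1):
            diag = max(Mp[j - 1], Ap[j - 1], Bp[j - 1])
            if diag > NEG_INF:
                Mi[j] = diag + sub(i, j)
            Ai[j] = max(Mi[j - 1] - go, Bi[j - 1] - go, Ai[j - 1] - ge)
            Bi[j] = max(Mp[j] - go, Ap[j] - go, Bp[j] - ge)

    # pick final state with deterministic preference M > gap-in-a > gap-in-b
    finals = (M[n][m], A[n][m], B[n][m])
    score = max(finals)
    state = finals.index(score)  # index order matches preference order

    cols_a: list[int] = []
    cols_b: list[int] = []
    i, j = n, m
    tol = 1e-9
    while i > 0 or j > 0:
        if state == _M:
            cols_a.append(i)
            cols_b.append(j)
            target = M[i][j] - sub(i, j)
            i, j = i - 1, j - 1
            for cand, mat in ((_M, M), (_GAP_IN_A, A), (_GAP_IN_B, B)):
                if abs(mat[i][j] - target) <= tol:
                    state = cand
                    break
        elif state == _GAP_IN_A:
            cols_a.append(0)
            cols_b.append(j)
            val = A[i][j]
            j -= 1
            if abs(M[i][j] - go - val) <= tol:
                state = _M
            elif abs(B[i][j] - go - val) <= tol:
                state = _GAP_IN_B
            else:
                state = _GAP_IN_A
        else:
            cols_a.append(i)
            cols_b.append(0)
            val = B[i][j]
            i -= 1
            if abs(M[i][j] - go - val) <= tol:
                state = _M
            elif abs(A[i][j] - go - val) <= tol:
                state = _GAP_IN_A
            else:
                state = _GAP_IN_B
    cols_a.reverse()
    cols_b.reverse()
    return cols_a, cols_b, score


def _strip_terminal_gap_columns(aligned_a: str, aligned_b: str) -> tuple[str, str]:
    lo, hi = 0, len(aligned_a)
    while lo < hi and ("-" in (aligned_a[lo], aligned_b[lo])):
        lo += 1
    while hi > lo and ("-" in (aligned_a[hi - 1], aligned_b[hi - 1])):
        hi -= 1
    return aligned_a[lo:hi], aligned_b[lo:hi]


def alignment_identity(aligned_a: str, aligned_b: str) -> float:
    """Fraction of identical columns, excluding terminal-gap columns."""
    a, b = _strip_terminal_gap_columns(aligned_a, aligned_b)
    if not a:
        return 0.0
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(a)


def p_distance(a: str, b: str, scheme: ScoringScheme | None = None,
               poisson: bool = False) -> float:
    """Mismatch fraction over the optimal global alignment of two sequences.

    Terminal-gap columns are excluded from the denominator; internal gap
    columns count as mismatches. With ``poisson=True`` returns the
    Poisson correction ``-ln(1 - p)`` (capped when p >= 1).
    """
    if a == b:
        return 0.0
    aln = global_align(a, b, scheme)
    xa, xb = _strip_terminal_gap_columns(aln.aligned_a, aln.aligned_b)
    if not xa:
        p = 1.0
    else:
        mismatches = sum(1 for x, y in zip(xa, xb) if x != y or x == "-")
        p = mismatches / len(xa)
    if not poisson:
        return p
    if p >= 1.0:
        return MAX_CORRECTED_DISTANCE
    return -math.log(1.0 - p)
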