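"""Pairwise alignment: Needleman-Wunsch, Gotoh, Smith-Waterman, LCS.

These four algorithms back every sequence comparison in the pipeline:
query-to-reference placement, tRNA classification, and the single-reference
fallback to profile mapping.

Conventions
-----------
* Scores are integers whenever the scoring scheme is integral; DP cells never
  hold floats.
* Gap penalties are stored as non-negative magnitudes and applied negatively.
  Needleman-Wunsch and the linear view of Smith-Waterman charge
  ``gap_extend`` per gap column; Gotoh (and Smith-Waterman, which is
  implemented with the same three-state affine recurrence) charge
  ``gap_open + k * gap_extend`` for a gap of length *k*, so
  ``gotoh(gap_open=0)`` scores exactly like ``needleman_wunsch``.
* Traceback ties break deterministically: diagonal > up (gap in ``b``) >
  left (gap in ``a``).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Union

import numpy as np
from numba import njit
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "DNA_SCHEME",
    "PROTEIN_SCHEME",
    "SIMPLE_SCHEME",
    "needleman_wunsch",
    "gotoh",
    "smith_waterman",
    "lcs",
]

GAP = "-"
_NEG = -(1 << 60)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution scores plus gap penalties (magnitudes).

    ``substitution`` is either a ``(match, mismatch)`` pair applied uniformly,
    or the name of a substitution matrix shipped with Biopython (for proteins
    the conventional choice is ``"BLOSUM62"``).
    """

    substitution: Union[tuple[int, int], str] = (1, -1)
    gap_open: int = 0
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are magnitudes and must be >= 0")


#: Nucleotide default: +5/-4 with affine 10/1 gaps.
DNA_SCHEME = ScoringScheme((5, -4), 10, 1)
#: Protein default: BLOSUM62 with affine 10/1 gaps.
PROTEIN_SCHEME = ScoringScheme("BLOSUM62", 10, 1)
#: Unit match/mismatch with linear unit gaps; handy for didactic examples.
SIMPLE_SCHEME = ScoringScheme((1, -1), 0, 1)


@dataclass(frozen=True)
class AlignmentResult:
    """A scored pairwise alignment.

    ``aligned_a``/``aligned_b`` are equal-length gapped strings; removing the
    gaps recovers ``a[a_start:a_end]`` and ``b[b_start:b_end]`` (half-open
    coordinates).  Global algorithms cover the full inputs; local ones may
    cover proper sub-intervals.
    """

    score: int
    aligned_a: str
    aligned_b: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    algorithm: str

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    mat = substitution_matrices.load(name)
    alphabet = str(mat.alphabet)
    arr = np.asarray(mat).astype(np.int64)
    index = {ch: i for i, ch in enumerate(alphabet)}
    return alphabet, index, arr


def _encode(a: str, b: str, scheme: ScoringScheme):
    """Encode both sequences as integer arrays plus a substitution matrix."""
    if isinstance(scheme.substitution, str):
        alphabet, index, submat = _load_matrix(scheme.substitution)
        fallback = index.get("X")
        def code_of(ch: str) -> int:
            i = index.get(ch)
            if i is None:
                if fallback is None:
                    raise ValueError(f"character {ch!r} not in matrix alphabet")
                return fallback
            return i
        ca = np.fromiter((code_of(ch) for ch in a), np.int64, len(a))
        cb = np.fromiter((code_of(ch) for ch in b), np.int64, len(b))
    else:
        match, mismatch = scheme.substitution
        alphabet = sorted(set(a) | set(b))
        index = {ch: i for i, ch in enumerate(alphabet)}
        k = max(len(alphabet), 1)
        submat = np.full((k, k), int(mismatch), np.int64)
        np.fill_diagonal(submat, int(match))
        ca = np.fromiter((index[ch] for ch in a), np.int64, len(a))
        cb = np.fromiter((index[ch] for ch in b), np.int64, len(b))
    return ca, cb, submat


# --------------------------------------------------------------------------
# DP kernels (integer cells, int8 traceback pointers)
# --------------------------------------------------------------------------

@njit(cache=True)
def _nw_fill(a, b, S, gap):
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), np.int64)
    P = np.zeros((n + 1, m + 1), np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, n + 1):
        H[i, 0] = -gap * i
        P[i, 0] = 1
    for j in range(1, m + 1):
        H[0, j] = -gap * j
        P[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = H[i - 1, j - 1] + S[a[i - 1], b[j - 1]]
            p = 0
            u = H[i - 1, j] - gap
            if u > best:
                best = u
                p = 1
            l = H[i, j - 1] - gap
            if l > best:
                best = l
                p = 2
            H[i, j] = best
            P[i, j] = p
    return H[n, m], P


@njit(cache=True)
def _gotoh_fill(a, b, S, open_, ext):
    n, m = len(a), len(b)
    NEG = -(1 << 60)
    M = np.full((n + 1, m + 1), NEG, np.int64)
    X = np.full((n + 1, m + 1), NEG, np.int64)  # gap in b (consumes a, "up")
    Y = np.full((n + 1, m + 1), NEG, np.int64)  # gap in a (consumes b, "left")
    PM = np.zeros((n + 1, m + 1), np.int8)  # predecessor state: 0=M 1=X 2=Y
    PX = np.zeros((n + 1, m + 1), np.int8)
    PY = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = -(open_ + ext * i)
        PX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -(open_ + ext * j)
        PY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # match state: diagonal from best predecessor state
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            M[i, j] = best + S[a[i - 1], b[j - 1]]
            PM[i, j] = p
            # gap in b: consume a[i-1]
            best = M[i - 1, j] - open_ - ext
            p = 0
            if X[i - 1, j] - ext > best:
                best = X[i - 1, j] - ext
                p = 1
            if Y[i - 1, j] - open_ - ext > best:
                best = Y[i - 1, j] - open_ - ext
                p = 2
            X[i, j] = best
            PX[i, j] = p
            # gap in a: consume b[j-1]
            best = M[i, j - 1] - open_ - ext
            p = 0
            if X[i, j - 1] - open_ - ext > best:
                best = X[i, j - 1] - open_ - ext
                p = 1
            if Y[i, j - 1] - ext > best:
                best = Y[i, j - 1] - ext
                p = 2
            Y[i, j] = best
            PY[i, j] = p
    return M, X, Y, PM, PX, PY


@njit(cache=True)
def _sw_fill(a, b, S, open_, ext):
    """Local affine alignment; returns best M cell and pointer matrices.

    PM == 3 marks a fresh local start at that match column.
    """
    n, m = len(a), len(b)
    NEG = -(1 << 60)
    M = np.full((n + 1, m + 1), NEG, np.int64)
    X = np.full((n + 1, m + 1), NEG, np.int64)
    Y = np.full((n + 1, m + 1), NEG, np.int64)
    PM = np.zeros((n + 1, m + 1), np.int8)
    PX = np.zeros((n + 1, m + 1), np.int8)
    PY = np.zeros((n + 1, m + 1), np.int8)
    best_score = 0
    best_i = 0
    best_j = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            pred = 0  # start fresh
            p = 3
            if M[i - 1, j - 1] > pred:
                pred = M[i - 1, j - 1]
                p = 0
            if X[i - 1, j - 1] > pred:
                pred = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > pred:
                pred = Y[i - 1, j - 1]
                p = 2
            M[i, j] = pred + S[a[i - 1], b[j - 1]]
            PM[i, j] = p
            bx = M[i - 1, j] - open_ - ext
            p = 0
            if X[i - 1, j] - ext > bx:
                bx = X[i - 1, j] - ext
                p = 1
            if Y[i - 1, j] - open_ - ext > bx:
                bx = Y[i - 1, j] - open_ - ext
                p = 2
            X[i, j] = bx
            PX[i, j] = p
            by = M[i, j - 1] - open_ - ext
            p = 0
            if X[i, j - 1] - open_ - ext > by:
                by = X[i, j - 1] - open_ - ext
                p = 1
            if Y[i, j - 1] - ext > by:
                by = Y[i, j - 1] - ext
                p = 2
            Y[i, j] = by
            PY[i, j] = p
            if M[i, j] > best_score:
                best_score = M[i, j]
                best_i = i
                best_j = j
    return best_score, best_i, best_j, PM, PX, PY


@njit(cache=True)
def _lcs_fill(a, b):
    n, m = len(a), len(b)
    L = np.zeros((n + 1, m + 1), np.int64)
    P = np.zeros((n + 1, m + 1), np.int8)  # 0 diag-match, 1 up, 2 left
    for i in range(1, n + 1):
        P[i, 0] = 1
    for j in range(1, m + 1):
        P[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                best = L[i - 1, j - 1] + 1
                p = 0
            else:
                best = -1
                p = 1
            if L[i - 1, j] > best:
                best = L[i - 1, j]
                p = 1
            if L[i, j - 1] > best:
                best = L[i, j - 1]
                p = 2
            L[i, j] = best
            P[i, j] = p
    return L[n, m], P


# --------------------------------------------------------------------------
# Tracebacks and public entry points
# --------------------------------------------------------------------------

def _global_edge_case(a: str, b: str, score: int, algorithm: str) -> AlignmentResult:
    """Alignment where at least one sequence is empty: pure gaps."""
    if a:
        return AlignmentResult(score, a, GAP * len(a), 0, len(a), 0, 0, algorithm)
    return AlignmentResult(score, GAP * len(b), b, 0, 0, 0, len(b), algorithm)


def needleman_wunsch(a: str, b: str, scheme: ScoringScheme = SIMPLE_SCHEME) -> AlignmentResult:
    """Optimal global alignment with linear gap cost ``gap_extend`` per column."""
    gap = scheme.gap_extend
    if not a or not b:
        return _global_edge_case(a, b, -gap * (len(a) + len(b)), "nw")
    ca, cb, S = _encode(a, b, scheme)
    score, P = _nw_fill(ca, cb, S, gap)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = len(a), len(b)
    while i > 0 or j > 0:
        p = P[i, j]
        if p == 0:
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif p == 1:
            out_a.append(a[i - 1]); out_b.append(GAP); i -= 1
        else:
            out_a.append(GAP); out_b.append(b[j - 1]); j -= 1
    return AlignmentResult(
        int(score), "".join(reversed(out_a)), "".join(reversed(out_b)),
        0, len(a), 0, len(b), "nw",
    )


def _affine_traceback(a, b, PM, PX, PY, i, j, state, stop_at_start=False):
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            p = PM[i, j]
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
            if stop_at_start and p == 3:
                break
            state = p
        elif state == 1:
            p = PX[i, j]
            out_a.append(a[i - 1]); out_b.append(GAP); i -= 1
            state = p
        else:
            p = PY[i, j]
            out_a.append(GAP); out_b.append(b[j - 1]); j -= 1
            state = p
    return "".join(reversed(out_a)), "".join(reversed(out_b)), i, j


def gotoh(a: str, b: str, scheme: ScoringScheme = DNA_SCHEME) -> AlignmentResult:
    """Optimal global alignment with affine gaps: cost ``open + k*extend``."""
    open_, ext = scheme.gap_open, scheme.gap_extend
    if not a or not b:
        k = len(a) + len(b)
        return _global_edge_case(a, b, -(open_ + ext * k) if k else 0, "gotoh")
    ca, cb, S = _encode(a, b, scheme)
    M, X, Y, PM, PX, PY = _gotoh_fill(ca, cb, S, open_, ext)
    n, m = len(a), len(b)
    score = M[n, m]
    state = 0
    if X[n, m] > score:
        score, state = X[n, m], 1
    if Y[n, m] > score:
        score, state = Y[n, m], 2
    out_a, out_b, _, _ = _affine_traceback(a, b, PM, PX, PY, n, m, state)
    return AlignmentResult(int(score), out_a, out_b, 0, n, 0, m, "gotoh")


def smith_waterman(a: str, b: str, scheme: ScoringScheme = DNA_SCHEME) -> AlignmentResult:
    """Optimal local alignment (affine gaps); score >= 0, may be empty."""
    if not a or not b:
        return AlignmentResult(0, "", "", 0, 0, 0, 0, "sw")
    ca, cb, S = _encode(a, b, scheme)
    score, bi, bj, PM, PX, PY = _sw_fill(ca, cb, S, scheme.gap_open, scheme.gap_extend)
    if score <= 0:
        return AlignmentResult(0, "", "", 0, 0, 0, 0, "sw")
    out_a, out_b, i, j = _affine_traceback(a, b, PM, PX, PY, bi, bj, 0, stop_at_start=True)
    return AlignmentResult(int(score), out_a, out_b, i, bi, j, bj, "sw")


def lcs(a: str, b: str) -> AlignmentResult:
    """Longest common subsequence as an alignment (match=1, no mismatches)."""
    if not a or not b:
        return _global_edge_case(a, b, 0, "lcs")
    ca, cb, _ = _encode(a, b, ScoringScheme((1, 0), 0, 0))
    score, P = _lcs_fill(ca, cb)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = len(a), len(b)
    while i > 0 or j > 0:
        p = P[i, j]
        if p == 0:
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif p == 1:
            out_a.append(a[i - 1]); out_b.append(GAP); i -= 1
        else:
            out_a.append(GAP); out_b.append(b[j - 1]); j -= 1
    return AlignmentResult(
        int(score), "".join(reversed(out_a)), "".join(reversed(out_b)),
        0, len(a), 0, len(b), "lcs",
    )


ALGORITHMS = {
    "nw": needleman_wunsch,
    "gotoh": gotoh,
    "sw": smith_waterman,
    "lcs": lambda a, b, scheme=None: lcs(a, b),
}
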