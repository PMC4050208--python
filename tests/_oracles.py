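"""Independent brute-force alignment oracles.

Everything here works by enumerating alignments (or subsequences) outright
and scoring each one; no dynamic programming is shared with the library code
these oracles check.  Feasible for sequences up to length ~6.
"""

from __future__ import annotations

from functools import lru_cache

D, U, L = 0, 1, 2  # diagonal / consume-a / consume-b


@lru_cache(maxsize=None)
def _move_lists(n: int, m: int) -> tuple[tuple[int, ...], ...]:
    """All gapped-alignment move sequences for sequences of lengths n, m."""
    if n == 0 and m == 0:
        return ((),)
    out = []
    if n > 0 and m > 0:
        out.extend((D,) + rest for rest in _move_lists(n - 1, m - 1))
    if n > 0:
        out.extend((U,) + rest for rest in _move_lists(n - 1, m))
    if m > 0:
        out.extend((L,) + rest for rest in _move_lists(n, m - 1))
    return tuple(out)


def _score_moves(a, b, moves, sub, gap_open, gap_extend):
    """Affine score of one alignment: each gap run costs open + len*extend."""
    score = 0
    i = j = 0
    prev = None
    for mv in moves:
        if mv == D:
            score += sub(a[i], b[j])
            i += 1
            j += 1
        else:
            if mv != prev:
                score -= gap_open
            score -= gap_extend
            if mv == U:
                i += 1
            else:
                j += 1
        prev = mv
    return score


def oracle_global(a: str, b: str, sub, gap_open: int, gap_extend: int) -> int:
    """Optimal global alignment score by full enumeration."""
    return max(
        _score_moves(a, b, moves, sub, gap_open, gap_extend)
        for moves in _move_lists(len(a), len(b))
    )


def oracle_local(a: str, b: str, sub, gap_open: int, gap_extend: int) -> int:
    """Optimal local alignment score by anchored enumeration.

    With negative mismatch scores and positive gap penalties an optimal
    non-empty local alignment starts and ends with a match column, so it is
    enough to enumerate matching anchor pairs and all alignments of the
    interiors between them.  The empty alignment scores 0.
    """
    best = 0
    starts = [(i, k) for i in range(len(a)) for k in range(len(b)) if a[i] == b[k]]
    for i, k in starts:
        best = max(best, sub(a[i], b[k]))  # single-column alignment
        for j in range(i + 1, len(a)):
            for l in range(k + 1, len(b)):
                if a[j] != b[l]:
                    continue
                interior = oracle_global(
                    a[i + 1 : j], b[k + 1 : l], sub, gap_open, gap_extend
                )
                best = max(best, sub(a[i], b[k]) + sub(a[j], b[l]) + interior)
    return best


def _is_subsequence(s: str, t: str) -> bool:
    it = iter(t)
    return all(ch in it for ch in s)


def oracle_lcs(a: str, b: str) -> int:
    """Longest common subsequence length by enumerating subsequences of a."""
    best = 0
    for mask in range(1 << len(a)):
        s = "".join(a[i] for i in range(len(a)) if mask >> i & 1)
        if len(s) > best and _is_subsequence(s, b):
            best = len(s)
    return best


def oracle_profile(query_scores, occ_frac, gap_open: float, gap_extend: float) -> float:
    """Optimal query-vs-profile score by recursive enumeration.

    ``query_scores[i][c]`` is the match score of query residue *i* against
    column *c*; deletions cost affine penalties scaled by ``occ_frac[c]``
    except before the first and after the last query residue (free);
    insertions cost plain affine penalties.  Mirrors the library's scoring
    model but shares no code with it.
    """
    n = len(query_scores)
    m = len(occ_frac)
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        # best score of aligning query[:i] with columns[:j], ending in state
        # 0=match, 1=insertion, 2=deletion, 3=initial
        if i == 0 and j == 0:
            return 0.0 if state == 3 else NEG
        best = NEG
        if state == 0 and i > 0 and j > 0:
            prev = max(rec(i - 1, j - 1, s) for s in (0, 1, 2, 3))
            if prev > NEG:
                best = prev + query_scores[i - 1][j - 1]
        elif state == 1 and i > 0:
            for s in (0, 1, 2, 3):
                p = rec(i - 1, j, s)
                if p == NEG:
                    continue
                cost = gap_extend if s == 1 else gap_open + gap_extend
                best = max(best, p - cost)
        elif state == 2 and j > 0:
            oc = occ_frac[j - 1]
            for s in (0, 1, 2, 3):
                p = rec(i, j - 1, s)
                if p == NEG:
                    continue
                if i == 0:  # every deletion before the first residue is free
                    best = max(best, p)
                    continue
                cost = gap_extend * oc if s == 2 else (gap_open + gap_extend) * oc
                best = max(best, p - cost)
        elif state == 3:
            return NEG
        return best

    # trailing deletions free: end at any column count in state 0/1 (or 2/3
    # if the query is empty)
    states = (0, 1) if n else (2, 3)
    result = max(rec(n, j, s) for j in range(m + 1) for s in states)
    rec.cache_clear()
    return result


def make_sub(match: int, mismatch: int):
    return lambda x, y: match if x == y else mismatch
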