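"""Place a predicted protein into a reference family alignment.

All CUG analysis rests on knowing which alignment column each query residue
occupies.  The reference alignment is summarised as a per-column amino-acid
frequency profile, and the query is aligned against the columns with an
affine-gap DP: the match score of residue *r* to column *c* is the
occupancy-weighted mean substitution score, and skipping a column costs gap
penalties scaled by the column's occupancy fraction (an all-gap column is
free to skip).  Columns skipped before the first or after the last query
residue carry no penalty, because predicted genes are locally trimmed
fragments of full-length families; the query itself is aligned end to end.
The reference alignment is never modified.

A pairwise fallback maps the query through a single reference row instead,
using any of the four pairwise algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .genetic_codes import AMINO_ACIDS
from .pairwise_align import (
    ALGORITHMS,
    GAP,
    PROTEIN_SCHEME,
    ScoringScheme,
    _load_matrix,
)

__all__ = ["Profile", "ColumnMap", "build_profile", "align_to_profile", "align_to_single"]

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class Profile:
    """Per-column amino-acid frequencies of a reference family alignment.

    ``counts`` is (n_columns, 20) over the canonical amino acids; gaps and
    non-canonical letters are excluded, so ``occupancy`` (canonical residues
    per column) can be below ``n_rows``.  Frequencies at a column sum to 1
    whenever its occupancy is positive.
    """

    family_id: str
    counts: np.ndarray
    occupancy: np.ndarray
    n_rows: int

    @property
    def n_columns(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        occ = np.maximum(self.occupancy, 1)[:, None]
        return self.counts / occ

    @property
    def occupancy_fraction(self) -> np.ndarray:
        return self.occupancy / max(self.n_rows, 1)


def build_profile(msa_rows: Sequence[str], family_id: str = "") -> Profile:
    """Column frequency profile of an aligned family (rows of equal length)."""
    rows = list(msa_rows)
    if not rows:
        raise ValueError("cannot build a profile from an empty alignment")
    ncols = len(rows[0])
    for r in rows:
        if len(r) != ncols:
            raise ValueError("alignment rows have unequal lengths")
    counts = np.zeros((ncols, 20), np.float64)
    for row in rows:
        for c, ch in enumerate(row):
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[c, idx] += 1.0
    occupancy = counts.sum(axis=1)
    return Profile(family_id, counts, occupancy, len(rows))


@dataclass(frozen=True)
class ColumnMap:
    """Alignment column occupied by each query residue.

    ``columns[i]`` is the 0-based column of residue *i*, or ``None`` for an
    insertion relative to the reference alignment.  Mapped columns increase
    strictly with residue index.
    """

    columns: tuple[Optional[int], ...]
    n_columns: int

    def __len__(self) -> int:
        return len(self.columns)

    def __getitem__(self, i: int) -> Optional[int]:
        return self.columns[i]

    def mapped(self) -> list[tuple[int, int]]:
        """(residue index, column) pairs, both 0-based, insertions skipped."""
        return [(i, c) for i, c in enumerate(self.columns) if c is not None]

    def one_based(self) -> list[tuple[int, Optional[int]]]:
        return [(i + 1, None if c is None else c + 1) for i, c in enumerate(self.columns)]


@njit(cache=True)
def _profile_fill(q, colscore, occ_frac, open_, ext):
    """Three-state affine DP of a query against profile columns.

    States: M (residue in column), X (insertion: residue, no column),
    Y (deletion: column skipped, cost scaled by occupancy fraction).
    Leading column deletions are free via Y[0, j] = 0; trailing ones are
    handled by taking the best cell in the last row.
    """
    n = len(q)
    m = colscore.shape[0]
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    PM = np.zeros((n + 1, m + 1), np.int8)
    PX = np.zeros((n + 1, m + 1), np.int8)
    PY = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        Y[0, j] = 0.0  # free leading deletions
        PY[0, j] = 2
    for i in range(1, n + 1):
        x = M[i - 1, 0] - open_ - ext
        p = 0
        if X[i - 1, 0] - ext > x:
            x = X[i - 1, 0] - ext
            p = 1
        X[i, 0] = x
        PX[i, 0] = p
        for j in range(1, m + 1):
            s = colscore[j - 1, q[i - 1]]
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
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
            oc = occ_frac[j - 1]
            by = M[i, j - 1] - (open_ + ext) * oc
            p = 0
            if X[i, j - 1] - (open_ + ext) * oc > by:
                by = X[i, j - 1] - (open_ + ext) * oc
                p = 1
            if Y[i, j - 1] - ext * oc > by:
                by = Y[i, j - 1] - ext * oc
                p = 2
            Y[i, j] = by
            PY[i, j] = p
    # best end: last query row, any column, trailing deletions free
    best = NEG
    bj = 0
    bstate = 0
    for j in range(m + 1):
        if M[n, j] > best:
            best = M[n, j]
            bj = j
            bstate = 0
        if X[n, j] > best:
            best = X[n, j]
            bj = j
            bstate = 1
    return best, bj, bstate, PM, PX, PY


def _profile_column_scores(profile: Profile, scheme: ScoringScheme) -> np.ndarray:
    """(n_columns, 20) occupancy-weighted mean substitution scores.

    Columns with a higher gap fraction score proportionally weaker (their
    deletion is cheaper by the same factor), so sparse columns neither
    attract nor repel the query strongly.
    """
    if isinstance(scheme.substitution, str):
        alphabet, index, mat = _load_matrix(scheme.substitution)
        sub = np.zeros((20, 20), np.float64)
        for i, x in enumerate(AMINO_ACIDS):
            for j, y in enumerate(AMINO_ACIDS):
                sub[i, j] = mat[index[x], index[y]]
    else:
        match, mismatch = scheme.substitution
        sub = np.full((20, 20), float(mismatch))
        np.fill_diagonal(sub, float(match))
    return (profile.frequencies @ sub) * profile.occupancy_fraction[:, None]


def align_to_profile(
    protein: str,
    profile: Profile,
    scheme: ScoringScheme = PROTEIN_SCHEME,
    *,
    leu_ser_ambiguous: frozenset = frozenset(),
) -> ColumnMap:
    """Align a query protein to a family profile; return its column map.

    Residue indices (0-based) listed in *leu_ser_ambiguous* are scored
    against each column as the better of leucine and serine — the natural
    treatment for CUG-encoded residues, whose identity is exactly one of the
    two.  Other unknown residues ('X', '*') score as the column average.
    """
    if profile.occupancy.sum() == 0:
        raise ValueError("profile has zero total occupancy")
    if not protein:
        return ColumnMap((), profile.n_columns)
    colscore = _profile_column_scores(profile, scheme)
    q = np.fromiter(
        (_AA_INDEX.get(ch, -1) for ch in protein), np.int64, len(protein)
    )
    leu_or_ser = np.maximum(
        colscore[:, _AA_INDEX["L"]], colscore[:, _AA_INDEX["S"]]
    )
    colscore = np.hstack(
        [colscore, colscore.mean(axis=1, keepdims=True), leu_or_ser[:, None]]
    )
    q[q < 0] = 20
    for i in leu_ser_ambiguous:
        q[i] = 21
    _, bj, bstate, PM, PX, PY = _profile_fill(
        q, colscore, profile.occupancy_fraction, float(scheme.gap_open), float(scheme.gap_extend)
    )
    columns: list[Optional[int]] = [None] * len(protein)
    i, j, state = len(protein), int(bj), int(bstate)
    while i > 0:
        if state == 0:
            columns[i - 1] = j - 1
            state = PM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = PX[i, j]
            i -= 1
        else:
            state = PY[i, j]
            j -= 1
    return ColumnMap(tuple(columns), profile.n_columns)


def residue_columns(aligned_row: str) -> list[int]:
    """0-based alignment column of each residue of a gapped row."""
    return [c for c, ch in enumerate(aligned_row) if ch != GAP]


def align_to_single(
    protein: str,
    reference_row: str,
    algorithm: str = "nw",
    scheme: ScoringScheme = PROTEIN_SCHEME,
) -> ColumnMap:
    """Map query residues to alignment columns through one reference row.

    *reference_row* is the reference sequence as it appears in the family
    alignment (with gaps); the query is aligned pairwise to the ungapped
    sequence and columns are transferred through the row's own gap pattern.
    Query residues aligned to gaps — or outside a local alignment's span —
    become insertion markers.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    cols = residue_columns(reference_row)
    ref = "".join(ch for ch in reference_row if ch != GAP)
    columns: list[Optional[int]] = [None] * len(protein)
    if not protein or not ref:
        return ColumnMap(tuple(columns), len(reference_row))
    aln = ALGORITHMS[algorithm](protein, ref, scheme)
    qi = aln.a_start
    ri = aln.b_start
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != GAP and cb != GAP:
            columns[qi] = cols[ri]
        if ca != GAP:
            qi += 1
        if cb != GAP:
            ri += 1
    return ColumnMap(tuple(columns), len(reference_row))
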