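"""Optimal pairwise alignment with affine gap penalties (Gotoh algorithm).

Both the global (Needleman-Wunsch style, end gaps fully penalized) and local
(Smith-Waterman style) variants are provided.  A gap of length ``g`` costs
``GOP + GEP * g`` — note the open penalty is charged *in addition to* the
per-position extension penalty, so the first gapped position costs
``GOP + GEP``.  Tools differ on this convention; it is fixed here because the
density model in :mod:`alnbench.slope_zone` books console overhangs as
``2*GEP*Lcon*c + 2*GOP``.

Tie-breaking is deterministic: where alternatives score equally, a match
column is preferred over a gap in sequence 2 (column consuming s1), which is
preferred over a gap in sequence 1.  The local variant returns, among
co-optimal fragments, the one with lexicographically smallest end
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from numba import njit

from .substitution import ScoringMatrix, encode

GAP = -1
_NEG = -1e30

Mode = Literal["global", "local"]


@dataclass(frozen=True)
class GapPenalty:
    """Affine gap cost: ``cost(g) = gop + gep * g`` for a gap of length g."""

    gop: float
    gep: float

    def __post_init__(self) -> None:
        if self.gop < 0 or self.gep < 0:
            raise ValueError("penalties must be non-negative")

    def cost(self, length: int) -> float:
        if length < 1:
            raise ValueError("gap length must be >= 1")
        return self.gop + self.gep * length


@dataclass
class PairwiseAlignment:
    """Ordered alignment columns plus the optimal score.

    ``columns`` is an (n, 2) int array; entry -1 (:data:`GAP`) marks a gap.
    Non-gap indices are strictly increasing in each column and no column is
    (GAP, GAP).  Global alignments cover both sequences completely; local
    alignments cover one contiguous fragment of each (possibly empty).
    """

    columns: np.ndarray
    score: float
    mode: Mode

    def __len__(self) -> int:
        return len(self.columns)

    def match_columns(self) -> np.ndarray:
        """Columns with a residue from both sequences."""
        both = (self.columns[:, 0] != GAP) & (self.columns[:, 1] != GAP)
        return self.columns[both]


# DP states: 0 = match (column i,j), 1 = gap in s2 (column i,-),
# 2 = gap in s1 (column -,j).  State preference for ties: 0 > 1 > 2.

@njit(cache=True)
def _gotoh_global(a, b, S, gop, gep):  # pragma: no cover - exercised via wrapper
    n, m = len(a), len(b)
    open_ = gop + gep
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in s2: consumes a[i]
    Y = np.full((n + 1, m + 1), _NEG)  # gap in s1: consumes b[j]
    ptrM = np.zeros((n + 1, m + 1), np.uint8)
    ptrX = np.zeros((n + 1, m + 1), np.uint8)
    ptrY = np.zeros((n + 1, m + 1), np.uint8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gop + gep * i)
        ptrX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -(gop + gep * j)
        ptrY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            # match state: best predecessor with preference M > X > Y
            best = M[i - 1, j - 1]; p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]; p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]; p = 2
            M[i, j] = best + S[ai, b[j - 1]]
            ptrM[i, j] = p
            # gap in s2 (vertical)
            best = M[i - 1, j] - open_; p = 0
            if X[i - 1, j] - gep > best:
                best = X[i - 1, j] - gep; p = 1
            if Y[i - 1, j] - open_ > best:
                best = Y[i - 1, j] - open_; p = 2
            X[i, j] = best; ptrX[i, j] = p
            # gap in s1 (horizontal)
            best = M[i, j - 1] - open_; p = 0
            if X[i, j - 1] - open_ > best:
                best = X[i, j - 1] - open_; p = 1
            if Y[i, j - 1] - gep > best:
                best = Y[i, j - 1] - gep; p = 2
            Y[i, j] = best; ptrY[i, j] = p
    # final state with the same preference
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]; state = 1
    if Y[n, m] > score:
        score = Y[n, m]; state = 2
    # traceback
    cols = np.empty((n + m, 2), np.int64)
    k = n + m
    i, j = n, m
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            cols[k, 0] = i - 1; cols[k, 1] = j - 1
            state = ptrM[i, j]; i -= 1; j -= 1
        elif state == 1:
            cols[k, 0] = i - 1; cols[k, 1] = GAP
            state = ptrX[i, j]; i -= 1
        else:
            cols[k, 0] = GAP; cols[k, 1] = j - 1
            state = ptrY[i, j]; j -= 1
    return score, cols[k:]


@njit(cache=True)
def _gotoh_local(a, b, S, gop, gep):  # pragma: no cover - exercised via wrapper
    n, m = len(a), len(b)
    open_ = gop + gep
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    ptrM = np.zeros((n + 1, m + 1), np.uint8)  # 3 = fresh start
    ptrX = np.zeros((n + 1, m + 1), np.uint8)
    ptrY = np.zeros((n + 1, m + 1), np.uint8)
    best_score = 0.0
    best_i = 0
    best_j = 0
    best_state = 3
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            best = 0.0; p = 3
            if M[i - 1, j - 1] > best:
                best = M[i - 1, j - 1]; p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]; p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]; p = 2
            M[i, j] = best + S[ai, b[j - 1]]
            ptrM[i, j] = p
            best = M[i - 1, j] - open_; p = 0
            if X[i - 1, j] - gep > best:
                best = X[i - 1, j] - gep; p = 1
            if Y[i - 1, j] - open_ > best:
                best = Y[i - 1, j] - open_; p = 2
            X[i, j] = best; ptrX[i, j] = p
            best = M[i, j - 1] - open_; p = 0
            if X[i, j - 1] - open_ > best:
                best = X[i, j - 1] - open_; p = 1
            if Y[i, j - 1] - gep > best:
                best = Y[i, j - 1] - gep; p = 2
            Y[i, j] = best; ptrY[i, j] = p
            if M[i, j] > best_score:
                best_score = M[i, j]; best_i = i; best_j = j; best_state = 0
    cols = np.empty((n + m, 2), np.int64)
    k = n + m
    i, j = best_i, best_j
    state = best_state
    while state != 3:
        k -= 1
        if state == 0:
            cols[k, 0] = i - 1; cols[k, 1] = j - 1
            state = ptrM[i, j]; i -= 1; j -= 1
        elif state == 1:
            cols[k, 0] = i - 1; cols[k, 1] = GAP
            state = ptrX[i, j]; i -= 1
        else:
            cols[k, 0] = GAP; cols[k, 1] = j - 1
            state = ptrY[i, j]; j -= 1
    return best_score, cols[k:]


def _as_codes(s: str | np.ndarray, which: str) -> np.ndarray:
    if isinstance(s, np.ndarray):
        codes = s
    else:
        codes = encode(s)
    if len(codes) == 0:
        raise ValueError(f"{which} must be non-empty")
    return codes


def align_global(s1: str | np.ndarray, s2: str | np.ndarray,
                 matrix: ScoringMatrix, gap: GapPenalty) -> PairwiseAlignment:
    """Optimal global alignment; end gaps are fully penalized."""
    a = _as_codes(s1, "s1")
    b = _as_codes(s2, "s2")
    score, cols = _gotoh_global(a, b, matrix.scores, float(gap.gop), float(gap.gep))
    return PairwiseAlignment(columns=cols, score=float(score), mode="global")


def align_local(s1: str | np.ndarray, s2: str | np.ndarray,
                matrix: ScoringMatrix, gap: GapPenalty) -> PairwiseAlignment:
    """Optimal local alignment; the empty alignment (score 0) is allowed."""
    a = _as_codes(s1, "s1")
    b = _as_codes(s2, "s2")
    score, cols = _gotoh_local(a, b, matrix.scores, float(gap.gop), float(gap.gep))
    return PairwiseAlignment(columns=cols, score=float(score), mode="local")


def score_alignment(alignment: PairwiseAlignment | Sequence[tuple[int, int]],
                    s1: str | np.ndarray, s2: str | np.ndarray,
                    matrix: ScoringMatrix, gap: GapPenalty) -> float:
    """Re-score an alignment from its columns (substitutions minus gap costs).

    Gap runs are maximal stretches of consecutive gap columns on the same
    side; adjacent gaps on opposite sides count as separate runs.
    """
    cols = alignment.columns if isinstance(alignment, PairwiseAlignment) \
        else np.asarray(list(alignment), dtype=np.int64).reshape(-1, 2)
    a = encode(s1) if isinstance(s1, str) else s1
    b = encode(s2) if isinstance(s2, str) else s2
    total = 0.0
    prev_gap_side = 0  # 0 none, 1 gap in s2, 2 gap in s1
    last_i = last_j = -1
    for i, j in cols:
        if i == GAP and j == GAP:
            raise ValueError("column (GAP, GAP) is not allowed")
        if i != GAP:
            if i <= last_i:
                raise ValueError("s1 indices must be strictly increasing")
            last_i = i
        if j != GAP:
            if j <= last_j:
                raise ValueError("s2 indices must be strictly increasing")
            last_j = j
        if i != GAP and j != GAP:
            total += matrix.scores[a[i], b[j]]
            prev_gap_side = 0
        elif j == GAP:
            total -= gap.gep + (gap.gop if prev_gap_side != 1 else 0.0)
            prev_gap_side = 1
        else:
            total -= gap.gep + (gap.gop if prev_gap_side != 2 else 0.0)
            prev_gap_side = 2
    return total
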