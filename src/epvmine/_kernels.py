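"""Numba kernels for local protein alignment.

The translated screen needs many Smith--Waterman alignments of peptide
probes against translated genome frames.  The fill/traceback is written
as a numba kernel; everything above it (seeding, X-drop triggering,
masking, bitscores) lives in :mod:`epvmine.screening`.
"""
from __future__ import annotations

import numpy as np
from numba import njit

from Bio.Align import substitution_matrices

#: protein alphabet used throughout; index 24 is a hard mask symbol that
#: scores strongly negative against everything (used to excise reported
#: hits before re-running the DP on the remainder of a frame).
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
MASK_INDEX = len(AA_ALPHABET)

_AA_TO_INT = {c: i for i, c in enumerate(AA_ALPHABET)}


def _build_blosum62() -> np.ndarray:
    b62 = substitution_matrices.load("BLOSUM62")
    n = len(AA_ALPHABET) + 1
    mat = np.full((n, n), -4, dtype=np.int32)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            mat[i, j] = int(b62[a, b])
    mat[MASK_INDEX, :] = -100
    mat[:, MASK_INDEX] = -100
    return mat


BLOSUM62 = _build_blosum62()


def encode_peptide(seq: str) -> np.ndarray:
    """Encode a peptide as int8 indices into :data:`AA_ALPHABET`.

    Unknown characters map to 'X'.
    """
    x = _AA_TO_INT["X"]
    return np.fromiter(
        (_AA_TO_INT.get(c, x) for c in seq.upper()), dtype=np.int8, count=len(seq)
    )


@njit(cache=True)
def sw_fill(q, t, sub, gap_open, gap_extend):  # pragma: no cover - numba
    """Affine-gap Smith-Waterman fill.

    Gap of length L costs gap_open + L*gap_extend.  Returns the H matrix
    (for traceback) plus best score and its end cell.
    """
    m = q.shape[0]
    n = t.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), -10**7, dtype=np.int32)  # gap in query (along t)
    F = np.full((m + 1, n + 1), -10**7, dtype=np.int32)  # gap in target (along q)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - gap_open - gap_extend,
                          E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open - gap_extend,
                          F[i - 1, j] - gap_extend)
            diag = H[i - 1, j - 1] + sub[q[i - 1], t[j - 1]]
            h = diag
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def sw_traceback(q, t, sub, gap_open, gap_extend, H, E, F, bi, bj):  # pragma: no cover
    """Recover one optimal local alignment ending at (bi, bj).

    Returns (qstart, tstart, ops) where ops is an int8 array over the
    alignment columns: 0 = match/mismatch, 1 = gap in target (consumes
    query), 2 = gap in query (consumes target), ordered start->end.
    """
    ops = np.empty(bi + bj, dtype=np.int8)
    k = ops.shape[0]
    i = bi
    j = bj
    state = 0  # in H
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            if h == H[i - 1, j - 1] + sub[q[i - 1], t[j - 1]]:
                k -= 1
                ops[k] = 0
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 2
            else:
                state = 1
        elif state == 2:  # gap in query: consume target
            k -= 1
            ops[k] = 2
            if E[i, j] == H[i, j - 1] - gap_open - gap_extend:
                state = 0
            j -= 1
        else:  # gap in target: consume query
            k -= 1
            ops[k] = 1
            if F[i, j] == H[i - 1, j] - gap_open - gap_extend:
                state = 0
            i -= 1
    return i, j, ops[k:]


@njit(cache=True)
def ungapped_xdrop(q, t, sub, qpos, tpos, klen, xdrop):  # pragma: no cover - numba
    """Extend an exact k-mer seed without gaps in both directions.

    Returns the best ungapped segment score achievable through the seed
    under an X-drop of ``xdrop``.
    """
    score = 0
    for k in range(klen):
        score += sub[q[qpos + k], t[tpos + k]]
    # extend right
    best = score
    cur = score
    i = qpos + klen
    j = tpos + klen
    while i < q.shape[0] and j < t.shape[0]:
        cur += sub[q[i], t[j]]
        if cur > best:
            best = cur
        if best - cur > xdrop:
            break
        i += 1
        j += 1
    # extend left
    right_gain = best - score
    cur = score
    best_l = score
    i = qpos - 1
    j = tpos - 1
    while i >= 0 and j >= 0:
        cur += sub[q[i], t[j]]
        if cur > best_l:
            best_l = cur
        if best_l - cur > xdrop:
            break
        i -= 1
        j -= 1
    return best_l + right_gain
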