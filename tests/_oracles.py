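"""Independent oracles used by the test suite.

These deliberately avoid the package's own alignment/cluster code
paths: the Needleman-Wunsch oracle is a plain three-matrix dynamic
program, the Smith-Waterman oracle is Biopython's PairwiseAligner in
local mode, and the clustering oracle is a brute-force transitive
closure.
"""
from __future__ import annotations

from typing import Dict, List, Sequence, Set, Tuple

NEG = float("-inf")


def nw_affine_score(
    a: str, b: str, match: int, mismatch: int, gap_open: int, gap_extend: int
) -> float:
    """Global alignment score; gap of length L costs gap_open + L*gap_extend."""
    n, m = len(a), len(b)
    first = gap_open + gap_extend
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
            s = match if a[i - 1] == b[j - 1] else mismatch
            best_prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = best_prev + s
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


def sw_protein_oracle_score(probe: str, frames: Sequence[str]) -> int:
    """Best local BLOSUM62 score of a probe over translated frames."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    best = 0
    for f in frames:
        if f:
            best = max(best, int(aligner.score(probe, f)))
    return best


def transitive_closure_partition(
    n: int, matches: Set[Tuple[int, int]]
) -> List[frozenset]:
    """Brute-force single-linkage closure of a pairwise match relation."""
    groups: List[Set[int]] = [{i} for i in range(n)]
    changed = True
    while changed:
        changed = False
        for (i, j) in matches:
            gi = next(g for g in groups if i in g)
            gj = next(g for g in groups if j in g)
            if gi is not gj:
                gi |= gj
                groups.remove(gj)
                changed = True
    return sorted((frozenset(g) for g in groups), key=lambda s: min(s))
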