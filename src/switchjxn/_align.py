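"""Low-level alignment kernels (numba).

Two kernels back the junction caller:

* a semi-global (glocal) affine-gap DP of a read against a reference with
  a free reference start, filled for *every* read prefix at once -- row
  ``x`` of the score matrix holds the best alignments of ``read[:x]``
  ending at each reference position;
* a Smith-Waterman local DP used for sequential-switching footprints.

Scoring convention: a gap of length k costs ``gap_open + (k-1) *
gap_extend`` (the first gapped base pays ``gap_open``).  N never matches
anything, including another N.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(10**9) // 2)

_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3 and N (or anything else) as 4."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def semiglobal_prefix(read, ref, match, mismatch, gap_open, gap_extend):
    """Affine-gap DP of every read prefix against ``ref``, free ref start.

    Returns the three state matrices (M: aligned pair, X: gap consuming a
    reference base, Y: gap consuming a read base), each of shape
    ``(len(read)+1, len(ref)+1)``.  ``max(M,X,Y)[x, y]`` is the best score
    of an alignment that consumes exactly ``read[:x]`` and ends at
    reference position ``y`` (reference start free).
    """
    L = read.shape[0]
    D = ref.shape[0]
    M = np.full((L + 1, D + 1), NEG, dtype=np.int32)
    X = np.full((L + 1, D + 1), NEG, dtype=np.int32)
    Y = np.full((L + 1, D + 1), NEG, dtype=np.int32)
    for y in range(D + 1):
        M[0, y] = 0  # free leading reference gap
    for x in range(1, L + 1):
        # column 0: read bases aligned left of the whole reference
        Y[x, 0] = gap_open + (x - 1) * gap_extend
        for y in range(1, D + 1):
            a = read[x - 1]
            b = ref[y - 1]
            s = match if (a == b and a < 4) else mismatch
            best_diag = M[x - 1, y - 1]
            if X[x - 1, y - 1] > best_diag:
                best_diag = X[x - 1, y - 1]
            if Y[x - 1, y - 1] > best_diag:
                best_diag = Y[x - 1, y - 1]
            M[x, y] = best_diag + s
            # gap consuming ref base (deletion in the read)
            vx = M[x, y - 1] + gap_open
            if X[x, y - 1] + gap_extend > vx:
                vx = X[x, y - 1] + gap_extend
            if Y[x, y - 1] + gap_open > vx:
                vx = Y[x, y - 1] + gap_open
            X[x, y] = vx
            # gap consuming read base (insertion in the read)
            vy = M[x - 1, y] + gap_open
            if Y[x - 1, y] + gap_extend > vy:
                vy = Y[x - 1, y] + gap_extend
            if X[x - 1, y] + gap_open > vy:
                vy = X[x - 1, y] + gap_open
            Y[x, y] = vy
    return M, X, Y


@njit(cache=True)
def count_traceback_mismatches(M, X, Y, read, ref, x, y,
                               match, mismatch, gap_open, gap_extend):
    """Walk back from cell ``(x, y)`` and count mismatched aligned pairs.

    Tie-breaking prefers M over X over Y, making the count deterministic.
    Gap columns are not counted as mismatches.
    """
    # pick starting state
    state = 0
    best = M[x, y]
    if X[x, y] > best:
        best, state = X[x, y], 1
    if Y[x, y] > best:
        best, state = Y[x, y], 2
    n_mm = 0
    while x > 0:
        if state == 0:
            if x == 0:
                break
            a = read[x - 1]
            b = ref[y - 1]
            if not (a == b and a < 4):
                n_mm += 1
            target = M[x, y] - (match if (a == b and a < 4) else mismatch)
            x -= 1
            y -= 1
            if x == 0:
                break
            if M[x, y] == target:
                state = 0
            elif X[x, y] == target:
                state = 1
            else:
                state = 2
        elif state == 1:
            v = X[x, y]
            y -= 1
            if M[x, y] == v - gap_open:
                state = 0
            elif X[x, y] == v - gap_extend:
                state = 1
            else:
                state = 2
        else:
            v = Y[x, y]
            x -= 1
            if x == 0:
                break
            if M[x, y] == v - gap_open:
                state = 0
            elif Y[x, y] == v - gap_extend:
                state = 2
            else:
                state = 1
    return n_mm


@njit(cache=True)
def local_align(read, ref, match, mismatch, gap_open, gap_extend):
    """Smith-Waterman local alignment of ``read`` vs ``ref``.

    Returns ``(score, x0, x1, y0, y1, n_match, n_cols)`` for the single
    best local alignment (earliest end cell on ties; traceback prefers
    M over X over Y).  ``x0:x1``/``y0:y1`` are half-open spans on the
    read/reference; identity is ``n_match / n_cols``.
    """
    L = read.shape[0]
    D = ref.shape[0]
    M = np.zeros((L + 1, D + 1), dtype=np.int32)
    X = np.full((L + 1, D + 1), NEG, dtype=np.int32)
    Y = np.full((L + 1, D + 1), NEG, dtype=np.int32)
    best = np.int32(0)
    bx = 0
    by = 0
    for x in range(1, L + 1):
        for y in range(1, D + 1):
            a = read[x - 1]
            b = ref[y - 1]
            s = match if (a == b and a < 4) else mismatch
            diag = M[x - 1, y - 1]
            if X[x - 1, y - 1] > diag:
                diag = X[x - 1, y - 1]
            if Y[x - 1, y - 1] > diag:
                diag = Y[x - 1, y - 1]
            v = diag + s
            if v < 0:
                v = 0
            M[x, y] = v
            vx = M[x, y - 1] + gap_open
            if X[x, y - 1] + gap_extend > vx:
                vx = X[x, y - 1] + gap_extend
            X[x, y] = vx
            vy = M[x - 1, y] + gap_open
            if Y[x - 1, y] + gap_extend > vy:
                vy = Y[x - 1, y] + gap_extend
            Y[x, y] = vy
            if M[x, y] > best:
                best = M[x, y]
                bx = x
                by = y
    # traceback from (bx, by) while score > 0
    x = bx
    y = by
    state = 0
    n_match = 0
    n_cols = 0
    while x > 0 and y > 0:
        if state == 0:
            if M[x, y] == 0:
                break
            a = read[x - 1]
            b = ref[y - 1]
            s = match if (a == b and a < 4) else mismatch
            if a == b and a < 4:
                n_match += 1
            n_cols += 1
            target = M[x, y] - s
            x -= 1
            y -= 1
            if M[x, y] == target:
                state = 0
            elif X[x, y] == target:
                state = 1
            elif Y[x, y] == target:
                state = 2
            else:
                break  # target == 0 fresh start
        elif state == 1:
            v = X[x, y]
            n_cols += 1
            y -= 1
            if X[x, y] == v - gap_extend:
                state = 1
            else:
                state = 0
        else:
            v = Y[x, y]
            n_cols += 1
            x -= 1
            if Y[x, y] == v - gap_extend:
                state = 2
            else:
                state = 0
    return best, x, bx, y, by, n_match, n_cols
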