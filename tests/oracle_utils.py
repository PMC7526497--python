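"""Independent brute-force oracle for the junction caller.

Enumerates every (prefix length, insertion length, donor_end,
acceptor_start) split of a read and scores the two flanks with
Biopython's PairwiseAligner -- an alignment engine independent of the
package's own DP.  Only practical for small instances (reads <= ~60 nt,
references <= ~80 nt).
"""

from __future__ import annotations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from switchjxn.caller import CallerParams, compute_microhomology


def _matrix(match: int, mismatch: int):
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            m[a, b] = match if (a == b and a != "N") else mismatch
    return m


def _infix_aligner(p: CallerParams) -> Align.PairwiseAligner:
    """Query (read fragment) fully aligned; target (reference) ends free."""
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = _matrix(p.match, p.mismatch)
    al.open_gap_score = p.gap_open
    al.extend_gap_score = p.gap_extend
    # unaligned reference overhang appears as query-side end gaps: free
    al.open_left_deletion_score = 0
    al.extend_left_deletion_score = 0
    al.open_right_deletion_score = 0
    al.extend_right_deletion_score = 0
    return al


def _left_free_aligner(p: CallerParams) -> Align.PairwiseAligner:
    """As above but the reference right end is pinned (ends exactly there)."""
    al = _infix_aligner(p)
    al.open_right_deletion_score = -10_000
    al.extend_right_deletion_score = -10_000
    return al


def oracle_call(read: str, donor: str, acceptor: str,
                p: CallerParams):
    """Best total score and the maximal mh_len among optimal splits.

    Returns ``None`` when no split satisfies the min_flank /
    positive-flank-score preconditions, else ``(score, mh_len)``.
    """
    L = len(read)
    infix = _infix_aligner(p)
    P = np.full(L + 1, -(10 ** 9))
    S = np.full(L + 1, -(10 ** 9))
    for i in range(1, L + 1):
        P[i] = infix.score(donor, read[:i])
        S[L - i] = infix.score(acceptor[::-1], read[L - i:][::-1])
    best = None
    for i in range(p.min_flank, L - p.min_flank + 1):
        if P[i] <= 0:
            continue
        for j in range(i, L - p.min_flank + 1):
            if S[j] <= 0:
                continue
            tot = P[i] + S[j]
            if best is None or tot > best:
                best = tot
    if best is None:
        return None
    # maximal microhomology over every optimal configuration
    pin = _left_free_aligner(p)
    best_mh = 0
    for i in range(p.min_flank, L - p.min_flank + 1):
        if P[i] <= 0:
            continue
        for j in range(i, L - p.min_flank + 1):
            if S[j] <= 0 or P[i] + S[j] != best:
                continue
            if read[i:j]:      # insertion present: mh is 0 by definition
                continue
            d_set = [d for d in range(len(donor) + 1)
                     if d >= 1 and pin.score(donor[:d], read[:i]) == P[i]]
            a_set = [len(acceptor) - y for y in range(len(acceptor) + 1)
                     if y >= 1 and pin.score(acceptor[::-1][:y],
                                             read[j:][::-1]) == S[j]]
            for d in d_set:
                for a in a_set:
                    mh = compute_microhomology(donor, d, acceptor, a)
                    best_mh = max(best_mh, mh)
    return int(best), int(best_mh)


def random_instance(rng: np.random.Generator,
                    max_read: int = 60, max_ref: int = 80):
    """A random (read, donor, acceptor) triple: half purely random reads,
    half genuine chimeras of the two references (with occasional noise)."""
    bases = np.array(list("ACGT"))
    dlen = int(rng.integers(20, max_ref + 1))
    alen = int(rng.integers(20, max_ref + 1))
    donor = "".join(rng.choice(bases, size=dlen))
    acceptor = "".join(rng.choice(bases, size=alen))
    if rng.random() < 0.5:
        rlen = int(rng.integers(10, max_read + 1))
        read = "".join(rng.choice(bases, size=rlen))
    else:
        f1 = int(rng.integers(5, min(25, dlen) + 1))
        f2 = int(rng.integers(5, min(25, alen) + 1))
        d = int(rng.integers(f1, dlen + 1))
        a = int(rng.integers(0, alen - f2 + 1))
        mid = "".join(rng.choice(bases, size=int(rng.integers(0, 4))))
        read = donor[d - f1:d] + mid + acceptor[a:a + f2]
        if rng.random() < 0.3:  # sprinkle substitutions
            arr = list(read)
            for k in rng.integers(0, len(arr), size=2):
                arr[int(k)] = str(rng.choice(bases))
            read = "".join(arr)
    return read, donor, acceptor
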