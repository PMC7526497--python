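"""Breakpoint calling for class-switch recombination junction reads.

A junction read is modelled as a donor-region prefix, an optional
untemplated insertion, and an acceptor-region suffix::

    read = donor[.. donor_end) flank | insertion | acceptor[acceptor_start ..) flank

Both flanks are aligned semi-globally (the end away from the junction is
free on the reference) with affine gaps; the insertion is unaligned read
sequence between the two flank alignments and contributes zero score.
The caller maximizes ``prefix_score + suffix_score`` over every split of
the read, which is exactly the exhaustive enumeration over (prefix
length, insertion length, donor_end, acceptor_start) -- a property the
test suite checks against an independent oracle.

Microhomology is a property of the *references* at the called
coordinates: the longest stretch of bases around the breakpoint that
matches donor and acceptor perfectly, so the exact junction position
inside that stretch is ambiguous.  Its length is the junction's key
repair-pathway signature (long microhomology marks alternative
end-joining).  Ties between equal-scoring splits are resolved by a total
order -- larger microhomology first, then smaller insertion, then
smaller coordinates -- and the junction is reported at the donor-maximal
placement inside the homology window, so calls are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._align import encode, semiglobal_prefix, count_traceback_mismatches, local_align
from .refio import Reference, JunctionRead, reverse_complement

# cap on enumerated equal-scoring placements; generous relative to the
# tie multiplicity seen even in repeat-rich references
_MAX_TIES = 4096


@dataclass(frozen=True)
class CallerParams:
    """Alignment scores and calling thresholds.

    ``min_flank`` guards against spurious splits in repeat-rich switch
    regions: a read whose donor- or acceptor-aligned flank is shorter is
    reported uncallable.  The footprint thresholds gate the detection of
    sequential-switching remnants (an intermediate switch-region segment
    between donor and acceptor).
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1
    min_flank: int = 15
    footprint_min_len: int = 15
    footprint_min_ident: float = 0.90

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("penalties must be negative")
        if self.min_flank < 1:
            raise ValueError("min_flank must be >= 1")
        if not (0 < self.footprint_min_ident <= 1):
            raise ValueError("footprint_min_ident must be in (0, 1]")


@dataclass(frozen=True)
class BreakpointCall:
    """The called structure of one junction read.

    ``donor_end`` is the index of the first donor base NOT used;
    ``acceptor_start`` the first acceptor base used (0-based, half-open).
    ``mh_len`` is perfectly matched reference-reference homology spanning
    the junction; it is 0 by definition whenever ``insertion_seq`` is
    non-empty.  ``callable`` is False when no split achieved positive
    flank scores on both sides; such reads are excluded downstream.
    """

    read_id: str
    donor_end: int
    acceptor_start: int
    mh_len: int
    insertion_seq: str
    n_mismatch_flank: int
    score: int
    donor_name: str = ""
    acceptor_name: str = ""
    cohort: str = ""
    footprint_ref: Optional[str] = None
    class_label: Optional[str] = None
    callable: bool = True

    def __post_init__(self) -> None:
        if self.callable and self.insertion_seq and self.mh_len != 0:
            raise ValueError("mh_len must be 0 when insertion_seq is non-empty")


@dataclass(frozen=True)
class ReporterCall:
    """A called repair junction from a cut-reporter read.

    ``deletion_len`` counts reference bases lost relative to perfect
    religation of the two nuclease cut sites (both sides pooled).
    """

    read_id: str
    deletion_len: int
    insertion_seq: str
    mh_len: int
    class_label: str
    score: int = 0
    callable: bool = True


def compute_microhomology(donor: Reference | str, donor_end: int,
                          acceptor: Reference | str, acceptor_start: int) -> int:
    """Perfectly matched homology spanning a junction, in bases.

    Extends left (donor and acceptor bases immediately before the
    junction) and right (immediately after) for as long as the two
    references agree exactly; N never matches.  Returns ``l + r``.
    """
    dseq = donor.seq if isinstance(donor, Reference) else donor
    aseq = acceptor.seq if isinstance(acceptor, Reference) else acceptor
    if not (0 <= donor_end <= len(dseq)) or not (0 <= acceptor_start <= len(aseq)):
        raise ValueError("breakpoint indices out of bounds")
    l = 0
    while (donor_end - l - 1 >= 0 and acceptor_start - l - 1 >= 0
           and dseq[donor_end - l - 1] == aseq[acceptor_start - l - 1]
           and dseq[donor_end - l - 1] != "N"):
        l += 1
    r = 0
    while (donor_end + r < len(dseq) and acceptor_start + r < len(aseq)
           and dseq[donor_end + r] == aseq[acceptor_start + r]
           and dseq[donor_end + r] != "N"):
        r += 1
    return l + r


def _right_extension(dseq: str, d: int, aseq: str, a: int) -> int:
    r = 0
    while (d + r < len(dseq) and a + r < len(aseq)
           and dseq[d + r] == aseq[a + r] and dseq[d + r] != "N"):
        r += 1
    return r


class _Workspace:
    """DP matrices and per-split best flank scores for one read."""

    def __init__(self, read_seq: str, donor_seq: str, acceptor_seq: str,
                 params: CallerParams):
        p = params
        self.read_seq = read_seq
        self.donor_seq = donor_seq
        self.acceptor_seq = acceptor_seq
        self.params = p
        r = encode(read_seq)
        self._r = r
        self.Mp, self.Xp, self.Yp = semiglobal_prefix(
            r, encode(donor_seq), p.match, p.mismatch, p.gap_open, p.gap_extend)
        self._rrev = r[::-1].copy()
        self._arev = encode(acceptor_seq)[::-1].copy()
        self.Ms, self.Xs, self.Ys = semiglobal_prefix(
            self._rrev, self._arev, p.match, p.mismatch, p.gap_open, p.gap_extend)
        self.Hdon = np.maximum(np.maximum(self.Mp, self.Xp), self.Yp)
        self.Hacc = np.maximum(np.maximum(self.Ms, self.Xs), self.Ys)
        self.P = self.Hdon.max(axis=1)            # P[i]: best for read[:i]
        self.Srev = self.Hacc.max(axis=1)         # Srev[k]: best for read[L-k:]
        L = len(read_seq)
        self.S = self.Srev[::-1].copy()           # S[j]: best for read[j:]

    def donor_ends(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.Hdon[i] == self.P[i])

    def acceptor_starts(self, j: int) -> np.ndarray:
        L = len(self.read_seq)
        ys = np.flatnonzero(self.Hacc[L - j] == self.S[j])
        return np.sort(len(self.acceptor_seq) - ys)

    def mismatches(self, i: int, d: int, j: int, a: int) -> int:
        p = self.params
        n = count_traceback_mismatches(
            self.Mp, self.Xp, self.Yp, self._r, encode(self.donor_seq),
            i, d, p.match, p.mismatch, p.gap_open, p.gap_extend)
        L = len(self.read_seq)
        A = len(self.acceptor_seq)
        n += count_traceback_mismatches(
            self.Ms, self.Xs, self.Ys, self._rrev, self._arev,
            L - j, A - a, p.match, p.mismatch, p.gap_open, p.gap_extend)
        return int(n)


def call_breakpoint(read: JunctionRead, donor: Reference, acceptor: Reference,
                    params: CallerParams = CallerParams()) -> BreakpointCall:
    """Call the donor/acceptor breakpoint of a single junction read.

    Returns an uncallable :class:`BreakpointCall` (``callable=False``)
    when no split of the read achieves positive flank scores of at least
    ``min_flank`` read bases on both sides.
    """
    if len(read) < 2 * params.min_flank:
        raise ValueError(
            f"read {read.read_id!r} shorter than 2*min_flank "
            f"({len(read)} < {2 * params.min_flank})")
    ws = _Workspace(read.seq, donor.seq, acceptor.seq, params)
    best = _best_call(ws, params)
    if best is None:
        return BreakpointCall(
            read_id=read.read_id, cohort=read.cohort, donor_name=donor.name,
            acceptor_name=acceptor.name, donor_end=0, acceptor_start=0,
            mh_len=0, insertion_seq="", n_mismatch_flank=0, score=0,
            callable=False)
    i, j, d, a, mh, ins = best
    n_mm = ws.mismatches(i, d, j, a)
    # canonical placement: donor-maximal inside the homology window
    if not ins:
        r = _right_extension(donor.seq, d, acceptor.seq, a)
        d += r
        a += r
    return BreakpointCall(
        read_id=read.read_id, cohort=read.cohort, donor_name=donor.name,
        acceptor_name=acceptor.name, donor_end=int(d), acceptor_start=int(a),
        mh_len=int(mh), insertion_seq=ins, n_mismatch_flank=n_mm,
        score=int(ws.P[i] + ws.S[j]))


def _best_call(ws: _Workspace, params: CallerParams):
    """Maximize total score over splits; break ties by the total order.

    Order among equal scores: larger mh_len, then shorter insertion, then
    smaller donor_end, then smaller acceptor_start.
    """
    L = len(ws.read_seq)
    mf = params.min_flank
    P, S = ws.P, ws.S
    i_idx = np.arange(L + 1)
    ok_i = (i_idx >= mf) & (P > 0)
    ok_j = (i_idx <= L - mf) & (S > 0)
    if not ok_i.any() or not ok_j.any():
        return None
    total = P[:, None] + S[None, :]
    mask = ok_i[:, None] & ok_j[None, :] & (i_idx[:, None] <= i_idx[None, :])
    if not mask.any():
        return None
    total = np.where(mask, total, np.iinfo(np.int32).min)
    best_score = total.max()
    ties = np.argwhere(total == best_score)
    best = None  # (key, payload)
    n_seen = 0
    for i, j in ties:
        i, j = int(i), int(j)
        ins = ws.read_seq[i:j]
        for d in ws.donor_ends(i):
            for a in ws.acceptor_starts(j):
                n_seen += 1
                if n_seen > _MAX_TIES:
                    break
                d, a = int(d), int(a)
                if ins:
                    mh = 0
                else:
                    mh = compute_microhomology(ws.donor_seq, d, ws.acceptor_seq, a)
                # canonical donor_end for ordering purposes
                if ins:
                    dc, ac = d, a
                else:
                    r = _right_extension(ws.donor_seq, d, ws.acceptor_seq, a)
                    dc, ac = d + r, a + r
                key = (-mh, len(ins), dc, ac)
                if best is None or key < best[0]:
                    best = (key, (i, j, d, a, mh, ins))
            if n_seen > _MAX_TIES:
                break
        if n_seen > _MAX_TIES:
            break
    return best[1] if best is not None else None


def call_breakpoint_rc_rescue(read: JunctionRead, donor: Reference,
                              acceptor: Reference,
                              params: CallerParams = CallerParams()) -> BreakpointCall:
    """Call the read as-is and reverse-complemented; keep the better score.

    Amplicons are normally sense-strand relative to the references, but
    external inputs may not be; ties prefer the forward orientation.
    """
    fwd = call_breakpoint(read, donor, acceptor, params)
    rc = JunctionRead(read.read_id, reverse_complement(read.seq), read.cohort)
    rev = call_breakpoint(rc, donor, acceptor, params)
    if not rev.callable:
        return fwd
    if not fwd.callable or rev.score > fwd.score:
        return rev
    return fwd


def detect_sequential_footprint(
        read: JunctionRead, donor: Reference, acceptor: Reference,
        intermediates: Sequence[Reference],
        params: CallerParams = CallerParams(),
        two_part: Optional[BreakpointCall] = None,
) -> Optional[tuple[str, tuple[int, int]]]:
    """Look for a remnant of an intermediate switch region in the read.

    Sequential switching (e.g. Smu->Sgamma3->Sgamma2) leaves a block of a
    third S region between the donor and acceptor segments.  The block is
    located as the best local alignment of the read against each
    intermediate reference; it is reported when the aligned read segment
    is at least ``footprint_min_len`` long with identity at least
    ``footprint_min_ident``, donor/acceptor flanks on both sides still
    score positively, and the three-part total strictly exceeds the
    two-part call's score.  Returns ``(intermediate name, (seg_start,
    seg_end))`` on the read, or None.
    """
    if two_part is None:
        two_part = call_breakpoint(read, donor, acceptor, params)
    if not two_part.callable:
        return None
    p = params
    ws = _Workspace(read.seq, donor.seq, acceptor.seq, p)
    L = len(read)
    best = None
    for inter in sorted(intermediates, key=lambda r: r.name):
        score_loc, x0, x1, y0, y1, n_match, n_cols = local_align(
            encode(read.seq), encode(inter.seq),
            p.match, p.mismatch, p.gap_open, p.gap_extend)
        if x1 - x0 < p.footprint_min_len or n_cols == 0:
            continue
        if n_match / n_cols < p.footprint_min_ident:
            continue
        if x0 < p.min_flank or L - x1 < p.min_flank:
            continue
        if ws.P[x0] <= 0 or ws.S[x1] <= 0:
            continue
        three_part = int(ws.P[x0] + score_loc + ws.S[x1])
        if three_part <= two_part.score:
            continue
        if best is None or three_part > best[0]:
            best = (three_part, inter.name, (int(x0), int(x1)))
    if best is None:
        return None
    return best[1], best[2]


def call_junction(read: JunctionRead, donor: Reference, acceptor: Reference,
                  intermediates: Sequence[Reference] = (),
                  params: CallerParams = CallerParams(),
                  rc_rescue: bool = False) -> BreakpointCall:
    """Two-part call plus optional footprint annotation; pipeline entry."""
    call = (call_breakpoint_rc_rescue if rc_rescue else call_breakpoint)(
        read, donor, acceptor, params)
    if call.callable and intermediates:
        fp = detect_sequential_footprint(
            read, donor, acceptor, intermediates, params, two_part=call)
        if fp is not None:
            call = replace(call, footprint_ref=fp[0])
    return call


def call_reporter_junction(read: JunctionRead, reporter: Reference,
                           cut_left: int, cut_right: int,
                           params: CallerParams = CallerParams()) -> ReporterCall:
    """Call a repair junction of a nuclease-cut reporter read.

    The reporter sequence left of ``cut_left`` acts as donor, the part
    right of ``cut_right`` as acceptor (the cassette in between is
    excised by the two cuts).  ``deletion_len`` is the number of
    additional reference bases resected beyond the cuts:
    ``(cut_left - donor_end) + (acceptor_start_global - cut_right)``.
    """
    if not (0 < cut_left < cut_right < len(reporter)):
        raise ValueError("need 0 < cut_left < cut_right < reporter length")
    donor = Reference(reporter.name + "|L", reporter.seq[:cut_left], "donor")
    acceptor = Reference(reporter.name + "|R", reporter.seq[cut_right:], "acceptor")
    call = call_breakpoint(read, donor, acceptor, params)
    if not call.callable:
        return ReporterCall(read.read_id, 0, "", 0, "uncallable",
                            score=0, callable=False)
    deletion = (cut_left - call.donor_end) + call.acceptor_start
    if call.insertion_seq:
        label = "insertion"
    elif deletion > 0:
        label = "deletion"
    else:
        label = "blunt"
    return ReporterCall(
        read_id=read.read_id, deletion_len=int(deletion),
        insertion_seq=call.insertion_seq, mh_len=call.mh_len,
        class_label=label, score=call.score)
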