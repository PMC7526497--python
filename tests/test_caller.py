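"""Unit and property tests of the breakpoint caller.

The caller's contract is checked against an independent Biopython-based
enumeration oracle (``oracle_utils``) on small random instances; larger
batches run in the acceptance suite.
"""

import numpy as np
import pytest

from oracle_utils import oracle_call, random_instance
from switchjxn.caller import (CallerParams, call_breakpoint,
                              call_breakpoint_rc_rescue,
                              call_reporter_junction, compute_microhomology,
                              detect_sequential_footprint)
from switchjxn.refio import JunctionRead, Reference, reverse_complement


def _call(read, donor, acceptor, params):
    return call_breakpoint(JunctionRead("r", read),
                           Reference("d", donor),
                           Reference("a", acceptor, "acceptor"), params)


class TestCallBreakpoint:
    @pytest.mark.parametrize(
        "read,donor,acceptor,exp",
        [
            # unique exact split, no shared boundary bases
            ("AAAATTTT", "AAAACCCC", "GGGGTTTT",
             dict(donor_end=4, acceptor_start=4, mh_len=0, insertion_seq="")),
            # 4-base overlap GTGT matches both references
            ("AACCGTGTTTAA", "AACCGTGT", "GTGTTTAA",
             dict(mh_len=4, insertion_seq="")),
            # untemplated GC extends neither flank
            ("AAAAGCTTTT", "AAAACCCC", "GGGGTTTT",
             dict(mh_len=0, insertion_seq="GC")),
        ])
    def test_constructed_junctions(self, tiny_params, read, donor, acceptor, exp):
        c = _call(read, donor, acceptor, tiny_params)
        assert c.callable
        for k, v in exp.items():
            assert getattr(c, k) == v, k

    def test_too_short_read_raises(self, tiny_params):
        with pytest.raises(ValueError, match="min_flank"):
            _call("ACT", "AAAACCCC", "GGGGTTTT", tiny_params)

    def test_uncallable_when_no_positive_flanks(self, tiny_params):
        # read unrelated to either reference
        c = _call("TGTGTGTGTGTG", "AAAACCCCAAAA", "CCCCAAAACCCC", tiny_params)
        assert not c.callable

    def test_deterministic(self, tiny_params):
        args = ("AACCGTGTTTAA", "AACCGTGT", "GTGTTTAA")
        assert _call(*args, tiny_params) == _call(*args, tiny_params)

    def test_n_bases_do_not_create_homology(self, tiny_params):
        # junction flanked by N on both references: would be mh 2 if N matched
        c = _call("AACCTTGG", "AACCN", "NTTGG", tiny_params)
        assert c.callable and c.mh_len == 0

    def test_reverse_complement_symmetry(self, oracle_params, rng):
        """Revcomping read and references (and swapping roles) preserves
        the junction signature."""
        for _ in range(25):
            read, donor, acceptor = random_instance(rng)
            fwd = _call(read, donor, acceptor, oracle_params)
            rev = _call(reverse_complement(read), reverse_complement(acceptor),
                        reverse_complement(donor), oracle_params)
            assert fwd.callable == rev.callable
            if fwd.callable:
                assert fwd.score == rev.score
                assert fwd.mh_len == rev.mh_len
                assert len(fwd.insertion_seq) == len(rev.insertion_seq)

    def test_rc_rescue_recovers_flipped_read(self, oracle_params):
        donor = "ATCGGCTAAGCTGCAGGTCAATCGGATC"
        acceptor = "TTGACCATGGTTACGCTACCGGTTACGA"
        read = donor[4:24] + acceptor[2:22]
        flipped = JunctionRead("r", reverse_complement(read))
        d, a = Reference("d", donor), Reference("a", acceptor, "acceptor")
        plain = call_breakpoint(flipped, d, a, oracle_params)
        rescued = call_breakpoint_rc_rescue(flipped, d, a, oracle_params)
        assert rescued.callable
        # junction position is placement-invariant up to homology sliding
        assert rescued.donor_end - rescued.acceptor_start == 24 - 2
        assert rescued.score > (plain.score if plain.callable else 0)

    def test_oracle_equivalence_small_batch(self, oracle_params, rng):
        """Caller score and mh equal exhaustive enumeration (80 instances)."""
        for _ in range(80):
            read, donor, acceptor = random_instance(rng)
            expected = oracle_call(read, donor, acceptor, oracle_params)
            c = _call(read, donor, acceptor, oracle_params)
            if expected is None:
                assert not c.callable
            else:
                assert c.callable
                assert (c.score, c.mh_len) == expected


class TestComputeMicrohomology:
    @pytest.mark.parametrize("donor,d,acceptor,a,exp", [
        ("AACCGTGT", 8, "GTGTTTAA", 4, 4),   # left extension over GTGT
        ("AAAACCCC", 4, "GGGGTTTT", 4, 0),   # both flanking bases differ
        ("ACGTACGT", 0, "ACGTACGT", 0, 8),   # right-only extension
        ("ACGT", 0, "TTTT", 0, 0),           # no bases leftward, no match right
    ])
    def test_extension(self, donor, d, acceptor, a, exp):
        assert compute_microhomology(donor, d, acceptor, a) == exp

    def test_n_never_matches(self):
        assert compute_microhomology("AANAA", 3, "CCNCC", 3, ) == 0

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError):
            compute_microhomology("ACGT", 5, "ACGT", 0)

    def test_placement_invariance_inside_window(self, rng):
        """mh_len is the same at every junction placement within the
        homology window."""
        for _ in range(50):
            bases = list("ACGT")
            core = "".join(rng.choice(bases, size=int(rng.integers(2, 8))))
            left_d = "".join(rng.choice(bases, size=10))
            left_a = "".join(rng.choice(bases, size=10))
            right_d = "".join(rng.choice(bases, size=10))
            right_a = "".join(rng.choice(bases, size=10))
            donor = left_d + core + right_d
            acceptor = left_a + core + right_a
            mhs = {compute_microhomology(donor, 10 + t, acceptor, 10 + t)
                   for t in range(len(core) + 1)}
            assert len(mhs) == 1


class TestFootprint:
    def _refs(self):
        rng = np.random.default_rng(7)
        bases = np.array(list("ACGT"))
        donor = Reference("Smu", "".join(rng.choice(bases, size=120)))
        acceptor = Reference("Sg2", "".join(rng.choice(bases, size=120)),
                             "acceptor")
        inter = Reference("Sg3", "".join(rng.choice(bases, size=120)),
                          "intermediate")
        return donor, acceptor, inter

    def test_detects_intermediate_block(self):
        donor, acceptor, inter = self._refs()
        read = JunctionRead("r", donor.seq[40:80] + inter.seq[50:70]
                            + acceptor.seq[20:60])
        fp = detect_sequential_footprint(read, donor, acceptor, [inter])
        assert fp is not None
        name, (x0, x1) = fp
        assert name == "Sg3"
        assert (x0, x1) == (40, 60)

    def test_none_without_intermediate_block(self):
        donor, acceptor, inter = self._refs()
        read = JunctionRead("r", donor.seq[40:80] + acceptor.seq[20:60])
        assert detect_sequential_footprint(read, donor, acceptor, [inter]) is None

    def test_short_block_below_threshold(self):
        donor, acceptor, inter = self._refs()
        read = JunctionRead("r", donor.seq[40:80] + inter.seq[50:60]
                            + acceptor.seq[20:60])
        # 10 nt < footprint_min_len 15
        assert detect_sequential_footprint(read, donor, acceptor, [inter]) is None


class TestReporterCall:
    def _reporter(self):
        rng = np.random.default_rng(11)
        seq = "".join(np.random.default_rng(11).choice(list("ACGT"), size=300))
        return Reference("rep", seq, "reporter"), 120, 180

    def test_perfect_religation(self, tiny_params):
        rep, cl, cr = self._reporter()
        read = JunctionRead("r", rep.seq[60:cl] + rep.seq[cr:cr + 60])
        c = call_reporter_junction(read, rep, cl, cr)
        assert (c.deletion_len, c.mh_len, c.insertion_seq) == (0, 0, "")
        assert c.class_label == "blunt"

    def test_donor_side_resection(self):
        rep, cl, cr = self._reporter()
        read = JunctionRead("r", rep.seq[60:cl - 6] + rep.seq[cr:cr + 60])
        c = call_reporter_junction(read, rep, cl, cr)
        assert c.deletion_len == 6 and c.class_label == "deletion"

    def test_untemplated_insertion(self):
        rep, cl, cr = self._reporter()
        # pick inserted bases that cannot extend either flank
        ins = "".join(b for b in "ACGT"
                      if b not in (rep.seq[cr],))[:1] * 3
        read = JunctionRead("r", rep.seq[60:cl] + ins + rep.seq[cr:cr + 60])
        c = call_reporter_junction(read, rep, cl, cr)
        assert c.class_label == "insertion"
        assert len(c.insertion_seq) == 3 and c.deletion_len == 0

    def test_bad_cut_coordinates(self):
        rep, cl, cr = self._reporter()
        with pytest.raises(ValueError):
            call_reporter_junction(JunctionRead("r", rep.seq[:100]), rep, 200, 100)
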