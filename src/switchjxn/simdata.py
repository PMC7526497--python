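"""Synthetic switch-region references and junction reads with ground truth.

Switch (S) regions are repeat-rich: tandem arrays of short conserved
motifs (pentamers such as GAGCT/GGGGT in Smu) with substantial per-copy
divergence.  The generator emulates that structure, then forms junction
reads by joining a donor-region flank to an acceptor-region flank with a
configurable spectrum of repair outcomes:

* ``direct``    -- blunt join, no shared bases at the boundary;
* ``insertion`` -- untemplated bases between the flanks;
* ``mh_k``      -- k bases of perfectly matched homology spanning the
                  junction, *planted* by locally editing the acceptor
                  reference so that the ground truth is realizable even
                  in repeat-rich sequence.

Each planted microhomology occupies its own non-overlapping slot along
the acceptor, so every truth record is re-derivable from the emitted
read and the (edited) references.  Substitution noise is applied to the
finished read; Sanger-style indel errors are off by default.

Regime presets carry published cohort spectra: ``control-like`` uses the
healthy-children Smu-Salpha percentages (16/24/36/24 over
direct/insertion/1-6 bp/>=7 bp), ``ICF2-like`` the patient percentages
(5/13/42/40), letting users regenerate a characterization-table-shaped
experiment without the unavailable raw Sanger reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .caller import compute_microhomology, _right_extension
from .classify import LABELS, CohortTable, cohort_table_from_counts
from .refio import Reference, JunctionRead

_BASES = np.array(list("ACGT"))

#: default S-region repeat motifs (Smu-style pentamers)
DEFAULT_MOTIFS = ("GAGCT", "GGGGT")

#: published cohort class spectra (fractions of junctions per category)
PRESETS: dict[str, dict[str, float]] = {
    "control-like": {"direct": 0.16, "insertion": 0.24,
                     "mh_1_6": 0.36, "mh_ge7": 0.24},
    "ICF2-like": {"direct": 0.05, "insertion": 0.13,
                  "mh_1_6": 0.42, "mh_ge7": 0.40},
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the junction-read generator.

    ``mh_law`` maps microhomology lengths (1..20) to probabilities;
    together with ``p_direct`` and ``p_insertion`` the masses must sum
    to 1.  ``insertion_len_law`` is the success probability of the
    geometric law for insertion lengths (support >= 1; mean = 1/p).
    ``flank_len_law`` is a closed uniform range for each flank in nt, so
    reads are Sanger-length.  ``substitution_rate`` is per base.
    """

    n_reads: int = 200
    p_direct: float = 0.16
    p_insertion: float = 0.24
    mh_law: Mapping[int, float] = field(
        default_factory=lambda: {**{k: 0.06 for k in range(1, 7)},
                                 **{k: 0.04 for k in range(7, 13)}})
    insertion_len_law: float = 0.5
    flank_len_law: tuple[int, int] = (100, 250)
    substitution_rate: float = 0.002
    seed: int = 0
    label: str = "sim"

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if any(k < 1 or k > 20 for k in self.mh_law):
            raise ValueError("mh_law lengths must be in 1..20")
        tot = self.p_direct + self.p_insertion + sum(self.mh_law.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"class masses must sum to 1, got {tot}")
        if not (0 < self.insertion_len_law <= 1):
            raise ValueError("insertion_len_law must be in (0, 1]")
        if not (0 <= self.substitution_rate <= 1):
            raise ValueError("substitution_rate must be in [0, 1]")
        lo, hi = self.flank_len_law
        if not (1 <= lo <= hi):
            raise ValueError("flank_len_law must be 1 <= lo <= hi")

    @property
    def class_masses(self) -> dict[str, float]:
        return {
            "direct": self.p_direct,
            "insertion": self.p_insertion,
            "mh_1_6": sum(v for k, v in self.mh_law.items() if k <= 6),
            "mh_ge7": sum(v for k, v in self.mh_law.items() if k >= 7),
        }


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated read (coordinates are canonical:
    donor-maximal placement inside the homology window)."""

    read_id: str
    true_donor_end: int
    true_acceptor_start: int
    true_mh_len: int
    true_insertion_seq: str
    regime: str
    true_deletion_len: int = 0


@dataclass(frozen=True)
class SimResult:
    reads: list[JunctionRead]
    truths: list[SimTruth]
    donor: Reference
    acceptor: Reference


def preset_config(preset: str, n_reads: int = 200, seed: int = 0,
                  substitution_rate: float = 0.002) -> SimConfig:
    """A SimConfig carrying a named cohort spectrum."""
    masses = PRESETS[preset]
    mh_law = {**{k: masses["mh_1_6"] / 6 for k in range(1, 7)},
              **{k: masses["mh_ge7"] / 6 for k in range(7, 13)}}
    return SimConfig(n_reads=n_reads, p_direct=masses["direct"],
                     p_insertion=masses["insertion"], mh_law=mh_law,
                     substitution_rate=substitution_rate, seed=seed,
                     label=preset)


def make_switch_reference(length: int, repeat_units: Sequence[str] = DEFAULT_MOTIFS,
                          divergence: float = 0.08, seed: int = 0,
                          name: str = "S", role: str = "donor") -> Reference:
    """A tandem-repeat switch-region reference with per-base divergence.

    Motifs are concatenated cyclically to ``length`` and substituted at
    the ``divergence`` rate; deterministic per seed.
    """
    if length < 200:
        raise ValueError("reference length must be >= 200")
    if not repeat_units:
        raise ValueError("need at least one repeat motif")
    for m in repeat_units:
        if set(m.upper()) - set("ACGT"):
            raise ValueError(f"motif {m!r}: invalid alphabet")
    rng = np.random.default_rng(seed)
    units = [m.upper() for m in repeat_units]
    chars: list[str] = []
    i = 0
    while len(chars) < length:
        chars.extend(units[i % len(units)])
        i += 1
    arr = np.array(chars[:length])
    if divergence > 0:
        hit = rng.random(length) < divergence
        for idx in np.flatnonzero(hit):
            arr[idx] = rng.choice(_BASES[_BASES != arr[idx]])
    return Reference(name, "".join(arr), role)


def _different_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return choices[int(rng.integers(len(choices)))]


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for idx in np.flatnonzero(hit):
        if arr[idx] in "ACGT":
            arr[idx] = _different_base(rng, str(arr[idx]))
    return "".join(arr)


def required_acceptor_length(cfg: SimConfig) -> int:
    """Minimum acceptor length for slot-based microhomology planting."""
    max_k = max(cfg.mh_law, default=0)
    stride = max_k + 2
    return cfg.n_reads * stride + max_k + 1 + cfg.flank_len_law[1]


def preset_references(cfg: SimConfig, donor_length: int = 2000,
                      seed_offset: int = 1000) -> tuple[Reference, Reference]:
    """Donor/acceptor references sized for ``cfg`` (deterministic per
    cfg.seed)."""
    donor = make_switch_reference(donor_length, seed=cfg.seed + seed_offset,
                                  name="Smu", role="donor")
    acc_len = required_acceptor_length(cfg) + 10
    acceptor = make_switch_reference(acc_len, seed=cfg.seed + seed_offset + 1,
                                     name="Salpha", role="acceptor")
    return donor, acceptor


def simulate_junctions(donor: Reference, acceptor: Reference,
                       cfg: SimConfig) -> SimResult:
    """Simulate junction reads between ``donor`` and ``acceptor``.

    The returned acceptor is a locally edited copy of the input (planted
    homology / boundary fixes); call reads against *that* reference.
    Raises when the acceptor is too short to host the requested planting
    slots or a requested homology exceeds the flanks.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reads
    lo, hi = cfg.flank_len_law
    max_k = max(cfg.mh_law, default=0)
    if max_k >= lo:
        raise ValueError("unrealizable: planted homology exceeds min flank")
    if lo >= len(donor):
        raise ValueError("donor shorter than flank_len_law")
    need = required_acceptor_length(cfg)
    if len(acceptor) < need:
        raise ValueError(
            f"unrealizable: acceptor length {len(acceptor)} < {need} needed "
            f"for {n} planting slots (stride {max_k + 2}) plus max flank")
    stride = max_k + 2

    outcomes = list(cfg.mh_law.items())
    labels = ["direct", "insertion"] + [f"mh_{k}" for k, _ in outcomes]
    probs = [cfg.p_direct, cfg.p_insertion] + [v for _, v in outcomes]
    drawn = rng.choice(len(labels), size=n, p=np.array(probs) / sum(probs))
    slot_of = rng.permutation(n)

    acc = list(acceptor.seq)
    dseq = donor.seq
    plan = []
    for i in range(n):
        lab = labels[int(drawn[i])]
        f1 = int(rng.integers(lo, hi + 1))
        f2 = int(rng.integers(lo, hi + 1))
        d = int(rng.integers(f1, len(dseq)))
        a = max_k + 1 + int(slot_of[i]) * stride
        ins = ""
        k = 0
        if lab == "direct":
            if acc[a - 1] == dseq[d - 1]:
                acc[a - 1] = _different_base(rng, dseq[d - 1])
            if acc[a] == dseq[d]:
                acc[a] = _different_base(rng, dseq[d])
        elif lab == "insertion":
            ilen = int(rng.geometric(cfg.insertion_len_law))
            ins = "".join(rng.choice(_BASES, size=ilen))
            if ilen == 1:
                ins = _different_base(rng, dseq[d], acc[a - 1])
            else:
                if ins[0] == dseq[d]:
                    ins = _different_base(rng, dseq[d]) + ins[1:]
                if ins[-1] == acc[a - 1]:
                    ins = ins[:-1] + _different_base(rng, acc[a - 1])
        else:
            k = int(lab.split("_")[1])
            acc[a - k:a] = list(dseq[d - k:d])
            if acc[a - k - 1] == dseq[d - k - 1]:
                acc[a - k - 1] = _different_base(rng, dseq[d - k - 1])
            if acc[a] == dseq[d]:
                acc[a] = _different_base(rng, dseq[d])
        plan.append((lab, f1, f2, d, a, k, ins))

    acc_seq = "".join(acc)
    acceptor_out = Reference(acceptor.name, acc_seq, acceptor.role)
    reads: list[JunctionRead] = []
    truths: list[SimTruth] = []
    for i, (lab, f1, f2, d, a, k, ins) in enumerate(plan):
        seq = dseq[d - f1:d] + ins + acc_seq[a:a + f2]
        seq = _mutate(rng, seq, cfg.substitution_rate)
        rid = f"{cfg.label}_{i:05d}"
        reads.append(JunctionRead(rid, seq, cohort=cfg.label))
        truths.append(SimTruth(rid, d, a, k, ins, cfg.label))
    return SimResult(reads, truths, donor, acceptor_out)


# ---------------------------------------------------------------------------
# reporter-mode simulation


@dataclass(frozen=True)
class ReporterSimConfig:
    """Parameters of the cut-reporter read generator.

    Outcomes are blunt religation, untemplated insertion, or deletion
    (further resection beyond the cuts).  The total deletion per read is
    geometric with mean ``deletion_mean`` (support >= 1), split
    uniformly between the two sides.  When ``planted_junction`` is set
    (see :func:`make_reporter_reference`), deletion reads instead anneal
    at the engineered direct repeat, modelling microhomology-mediated
    joining.
    """

    n_reads: int = 200
    p_blunt: float = 0.4
    p_insertion: float = 0.3
    deletion_mean: float = 8.0
    insertion_len_law: float = 0.5
    flank_len_law: tuple[int, int] = (100, 250)
    substitution_rate: float = 0.002
    seed: int = 0
    label: str = "reporter"
    planted_junction: Optional[tuple[int, int, int]] = None
    # (donor_end, acceptor_start_local, mh_len)

    def __post_init__(self) -> None:
        if not (0 <= self.p_blunt + self.p_insertion <= 1):
            raise ValueError("p_blunt + p_insertion must be in [0, 1]")
        if self.deletion_mean < 1:
            raise ValueError("deletion_mean must be >= 1")

    @property
    def p_deletion(self) -> float:
        return 1.0 - self.p_blunt - self.p_insertion


def make_reporter_reference(length: int = 1200, cut_left: int = 500,
                            cut_right: int = 700, planted_mh_len: int = 0,
                            planted_offsets: tuple[int, int] = (6, 4),
                            seed: int = 0,
                            name: str = "reporter") -> tuple[Reference, tuple]:
    """A random reporter construct with two cut sites; optionally embeds a
    direct repeat straddling the cuts for microhomology-mediated joining.

    Returns ``(reference, planted_junction)`` where ``planted_junction``
    is ``None`` or ``(donor_end, acceptor_start_local, mh_len)`` suitable
    for :class:`ReporterSimConfig`.
    """
    if not (0 < cut_left < cut_right < length):
        raise ValueError("need 0 < cut_left < cut_right < length")
    rng = np.random.default_rng(seed)
    arr = rng.choice(_BASES, size=length)
    planted = None
    if planted_mh_len > 0:
        k = planted_mh_len
        dl, dr = planted_offsets
        motif = rng.choice(_BASES, size=k)
        d = cut_left - dl               # donor_end of the annealed junction
        a = dr + k                      # acceptor_start in local coordinates
        arr[d - k:d] = motif
        arr[cut_right + dr:cut_right + dr + k] = motif
        # pin the window: one mismatch on each side of the repeat
        if arr[d - k - 1] == arr[cut_right + dr - 1]:
            arr[cut_right + dr - 1] = _different_base(rng, str(arr[d - k - 1]))
        if arr[d] == arr[cut_right + dr + k]:
            arr[cut_right + dr + k] = _different_base(rng, str(arr[d]))
        planted = (d, a, k)
    ref = Reference(name, "".join(arr), "reporter")
    return ref, planted


def simulate_reporter_junctions(reporter: Reference, cut_left: int,
                                cut_right: int,
                                cfg: ReporterSimConfig) -> SimResult:
    """Simulate repair-junction reads from a nuclease-cut reporter.

    Truth records carry ``true_deletion_len``; donor/acceptor in the
    result are the reporter halves, so truth coordinates follow the
    reporter-call convention (acceptor_start local to the right half).
    """
    rng = np.random.default_rng(cfg.seed)
    dseq = reporter.seq[:cut_left]
    aseq = reporter.seq[cut_right:]
    lo, hi = cfg.flank_len_law
    if hi > len(dseq) or hi > len(aseq):
        raise ValueError("unrealizable: flanks exceed reporter arm length")
    probs = [cfg.p_blunt, cfg.p_insertion, cfg.p_deletion]
    drawn = rng.choice(3, size=cfg.n_reads, p=np.array(probs) / sum(probs))
    reads: list[JunctionRead] = []
    truths: list[SimTruth] = []
    for i in range(cfg.n_reads):
        lab = ("blunt", "insertion", "deletion")[int(drawn[i])]
        f1 = int(rng.integers(lo, hi + 1))
        f2 = int(rng.integers(lo, hi + 1))
        ins = ""
        if lab == "blunt":
            d, a = cut_left, 0
        elif lab == "insertion":
            d, a = cut_left, 0
            ilen = int(rng.geometric(cfg.insertion_len_law))
            ins = "".join(rng.choice(_BASES, size=ilen))
        elif cfg.planted_junction is not None:
            d, a, _k = cfg.planted_junction
        else:
            total = int(rng.geometric(1.0 / cfg.deletion_mean))
            del_l = int(rng.integers(0, total + 1))
            del_r = total - del_l
            d, a = cut_left - del_l, del_r
            if d < f1 or a + f2 > len(aseq):
                d, a = cut_left - min(del_l, cut_left - f1), del_r
        # canonicalize truth at the donor-maximal placement
        if not ins:
            r = _right_extension(dseq, d, aseq, a)
            d, a = d + r, a + r
            mh = compute_microhomology(dseq, d, aseq, a)
        else:
            mh = 0
        deletion = (cut_left - d) + a
        seq = dseq[d - f1:d] + ins + aseq[a:a + f2]
        seq = _mutate(rng, seq, cfg.substitution_rate)
        rid = f"{cfg.label}_{i:05d}"
        reads.append(JunctionRead(rid, seq, cohort=cfg.label))
        truths.append(SimTruth(rid, d, a, mh, ins, cfg.label,
                               true_deletion_len=deletion))
    return SimResult(reads, truths,
                     Reference(reporter.name + "|L", dseq, "donor"),
                     Reference(reporter.name + "|R", aseq, "acceptor"))


# ---------------------------------------------------------------------------
# class-count (truth-level) cohort simulation for power / calibration work


def simulate_class_counts(masses: Mapping[str, float], n: int,
                          rng: np.random.Generator,
                          cohort: str = "sim") -> CohortTable:
    """Draw a cohort's class counts directly from the multinomial over the
    four categories -- the truth-level view of a simulated cohort, used
    for power and type-I-error studies of the cohort comparison."""
    p = np.array([masses[lab] for lab in LABELS], dtype=float)
    counts = rng.multinomial(n, p / p.sum())
    return cohort_table_from_counts(cohort, dict(zip(LABELS, counts.tolist())))


# ---------------------------------------------------------------------------
# truth TSV round trip

_TRUTH_COLS = ("read_id", "true_donor_end", "true_acceptor_start",
               "true_mh_len", "true_insertion_seq", "regime",
               "true_deletion_len")


def write_truth_tsv(truths: Sequence[SimTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLS) + "\n")
        for t in truths:
            fh.write("\t".join([
                t.read_id, str(t.true_donor_end), str(t.true_acceptor_start),
                str(t.true_mh_len), t.true_insertion_seq, t.regime,
                str(t.true_deletion_len)]) + "\n")


def read_truth_tsv(path: str | Path) -> list[SimTruth]:
    lines = Path(path).read_text().splitlines()
    if not lines or tuple(lines[0].split("\t")) != _TRUTH_COLS:
        raise ValueError(f"{path}: not a truth TSV")
    out = []
    for ln in lines[1:]:
        f = ln.split("\t")
        out.append(SimTruth(f[0], int(f[1]), int(f[2]), int(f[3]), f[4], f[5],
                            int(f[6])))
    return out
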