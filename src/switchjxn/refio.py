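"""Reading, writing and canonicalization of the pipeline's file formats.

Switch-region references and junction reads travel as FASTA; breakpoint
calls travel as a fixed-header TSV.  All sequences handed to downstream
modules are canonical: uppercase, U mapped to T, alphabet restricted to
A, C, G, T, N.

Coordinates everywhere in this package are 0-based, half-open.  A
breakpoint is the index of the first base NOT taken from the donor
reference (``donor_end``) and the index of the first base taken from the
acceptor reference (``acceptor_start``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")

#: fixed column order of the calls TSV (External Interfaces contract)
CALLS_TSV_COLUMNS = (
    "read_id",
    "cohort",
    "donor_name",
    "donor_end",
    "acceptor_name",
    "acceptor_start",
    "mh_len",
    "insertion_seq",
    "n_mismatch_flank",
    "class",
    "footprint_ref",
    "score",
)


class FormatError(ValueError):
    """Malformed input file (bad FASTA, bad alphabet, duplicate names)."""


def canonicalize(seq: str, name: str = "<sequence>") -> str:
    """Uppercase, map U->T, validate against the A/C/G/T/N alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - ALPHABET
    if bad:
        raise FormatError(
            f"record {name!r}: non-IUPAC characters {sorted(bad)!r} "
            "(allowed: A, C, G, T, N)"
        )
    return s


@dataclass(frozen=True)
class Reference:
    """A named nucleotide reference sequence.

    ``role`` distinguishes the donor switch region (e.g. Smu), the
    acceptor (Salpha/Sgamma), an intermediate region used only for
    sequential-switching footprints (e.g. Sgamma3), and the religated
    construct of reporter assays.
    """

    name: str
    seq: str
    role: str = "donor"

    _ROLES = ("donor", "acceptor", "intermediate", "reporter")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}, got {self.role!r}")
        if not self.seq:
            raise ValueError(f"reference {self.name!r}: empty sequence")
        object.__setattr__(self, "seq", canonicalize(self.seq, self.name))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class JunctionRead:
    """A single (Sanger-length) junction read with its cohort label."""

    read_id: str
    seq: str
    cohort: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", canonicalize(self.seq, self.read_id))

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into a list of ``(name, seq)`` tuples.

    Sequences are canonicalized (uppercased, U->T).  Raises
    :class:`FormatError` on an empty file, duplicate record names, or
    characters outside A/C/G/T/N/U.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record name {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, canonicalize(str(rec.seq), rec.id)))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_references(path: str | Path, role: str) -> list[Reference]:
    """Read a FASTA of references, assigning every record the same role."""
    return [Reference(name, seq, role) for name, seq in read_fasta(path)]


def read_junction_reads(path: str | Path, cohort: str = "") -> list[JunctionRead]:
    return [JunctionRead(name, seq, cohort) for name, seq in read_fasta(path)]


def write_calls_tsv(calls: Sequence, path: str | Path) -> None:
    """Serialize breakpoint calls to the fixed-header TSV.

    ``calls`` are :class:`switchjxn.caller.BreakpointCall` objects (any
    object with the matching attributes works).  An empty list yields a
    header-only file.  Uncallable reads are serialized with empty
    coordinate fields.
    """
    buf = io.StringIO()
    buf.write("\t".join(CALLS_TSV_COLUMNS) + "\n")
    for c in calls:
        if getattr(c, "callable", True):
            row = [
                c.read_id,
                c.cohort,
                c.donor_name,
                str(c.donor_end),
                c.acceptor_name,
                str(c.acceptor_start),
                str(c.mh_len),
                c.insertion_seq,
                str(c.n_mismatch_flank),
                c.class_label or "",
                c.footprint_ref or "",
                str(c.score),
            ]
        else:
            row = [c.read_id, c.cohort, c.donor_name, "", c.acceptor_name,
                   "", "", "", "", "uncallable", "", ""]
        buf.write("\t".join(row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_calls_tsv(path: str | Path) -> list:
    """Read a calls TSV back into :class:`BreakpointCall` objects.

    Round-trips losslessly with :func:`write_calls_tsv`.
    """
    from .caller import BreakpointCall  # deferred: avoid import cycle

    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty calls file")
    header = tuple(lines[0].split("\t"))
    if header != CALLS_TSV_COLUMNS:
        raise FormatError(
            f"{path}: unexpected header {header!r}; "
            f"expected {CALLS_TSV_COLUMNS!r}"
        )
    calls = []
    for ln in lines[1:]:
        f = ln.split("\t")
        if len(f) != len(CALLS_TSV_COLUMNS):
            raise FormatError(f"{path}: malformed row {ln!r}")
        rec = dict(zip(CALLS_TSV_COLUMNS, f))
        if rec["class"] == "uncallable":
            calls.append(
                BreakpointCall(
                    read_id=rec["read_id"], cohort=rec["cohort"],
                    donor_name=rec["donor_name"], acceptor_name=rec["acceptor_name"],
                    donor_end=0, acceptor_start=0, mh_len=0, insertion_seq="",
                    n_mismatch_flank=0, score=0, callable=False,
                )
            )
        else:
            calls.append(
                BreakpointCall(
                    read_id=rec["read_id"], cohort=rec["cohort"],
                    donor_name=rec["donor_name"],
                    donor_end=int(rec["donor_end"]),
                    acceptor_name=rec["acceptor_name"],
                    acceptor_start=int(rec["acceptor_start"]),
                    mh_len=int(rec["mh_len"]),
                    insertion_seq=rec["insertion_seq"],
                    n_mismatch_flank=int(rec["n_mismatch_flank"]),
                    class_label=rec["class"] or None,
                    footprint_ref=rec["footprint_ref"] or None,
                    score=int(rec["score"]),
                )
            )
    return calls


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
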