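"""Repair-pattern classification of called junctions and cohort summaries.

Callable switch junctions fall into exactly one of four categories based
on perfectly matched microhomology at the breakpoint:

* ``direct``    -- blunt join: no microhomology, no inserted bases
                   (a classical end-joining signature);
* ``insertion`` -- untemplated bases at the junction (also a classical
                   end-joining footprint, via polymerase fill-in);
* ``mh_1_6``    -- 1-6 bp of microhomology;
* ``mh_ge7``    -- >= 7 bp of microhomology, the hallmark of
                   microhomology-mediated alternative end-joining.

A junction carrying both an insertion and incidental reference-reference
homology counts as ``insertion`` (microhomology is defined as 0 whenever
inserted bases are present), so the four categories partition the calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .caller import BreakpointCall, ReporterCall

LABELS = ("direct", "insertion", "mh_1_6", "mh_ge7")

#: default deletion-size bin edges for reporter junction summaries, nt
DEFAULT_DELETION_EDGES = (0, 1, 11, 21)


@dataclass(frozen=True)
class CohortTable:
    """Per-cohort junction category counts, the machine form of a
    characterization table (one row per cohort, one column per category).

    Percentages are integer, rounded half away from zero.
    """

    cohort: str
    counts: Mapping[str, int]
    total: int

    @property
    def percentages(self) -> dict[str, int]:
        return {lab: _round_half_up(100.0 * self.counts[lab] / self.total)
                for lab in LABELS}

    def as_row(self) -> dict:
        row: dict = {"cohort": self.cohort}
        pct = self.percentages
        for lab in LABELS:
            row[lab] = f"{self.counts[lab]} ({pct[lab]})"
        row["total"] = self.total
        return row


def _round_half_up(x: float) -> int:
    """Round half away from zero (102.5 -> 103), as printed tables do."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def classify_junction(call: BreakpointCall) -> str:
    """Map one callable breakpoint call to its repair-pattern label."""
    if not call.callable:
        raise ValueError("classify requires a successful call "
                         f"(read {call.read_id!r} is uncallable)")
    if call.insertion_seq:
        return "insertion"
    if call.mh_len == 0:
        return "direct"
    if call.mh_len <= 6:
        return "mh_1_6"
    return "mh_ge7"


def classify_calls(calls: Iterable[BreakpointCall]) -> list[BreakpointCall]:
    """Attach class labels to callable calls; uncallable pass through."""
    from dataclasses import replace

    out = []
    for c in calls:
        if c.callable:
            out.append(replace(c, class_label=classify_junction(c)))
        else:
            out.append(c)
    return out


def summarize_cohort(classes: Sequence[str], cohort: str) -> CohortTable:
    """Count and percentage each category for one cohort of labels."""
    classes = list(classes)
    if not classes:
        raise ValueError(f"cohort {cohort!r}: no classified junctions")
    unknown = set(classes) - set(LABELS)
    if unknown:
        raise ValueError(f"unknown class labels {sorted(unknown)!r}")
    counts = {lab: classes.count(lab) for lab in LABELS}
    return CohortTable(cohort=cohort, counts=counts, total=len(classes))


def cohort_table_from_counts(cohort: str, counts: Mapping[str, int]) -> CohortTable:
    """Build a CohortTable directly from printed per-category counts."""
    full = {lab: int(counts.get(lab, 0)) for lab in LABELS}
    total = sum(full.values())
    if total < 1:
        raise ValueError(f"cohort {cohort!r}: empty table")
    return CohortTable(cohort=cohort, counts=full, total=total)


def summarize_calls(calls: Iterable[BreakpointCall]) -> list[CohortTable]:
    """Group labelled calls by cohort and summarize each cohort."""
    by_cohort: dict[str, list[str]] = {}
    for c in calls:
        if c.callable:
            lab = c.class_label or classify_junction(c)
            by_cohort.setdefault(c.cohort, []).append(lab)
    return [summarize_cohort(labels, cohort)
            for cohort, labels in sorted(by_cohort.items())]


def tables_to_tsv(tables: Sequence[CohortTable], path: str | Path) -> None:
    """Write cohort tables as a characterization-table-shaped TSV with
    "count (percent)" cells."""
    df = pd.DataFrame([t.as_row() for t in tables])
    df.to_csv(path, sep="\t", index=False)


def bin_deletion_sizes(calls: Sequence[ReporterCall],
                       edges: Sequence[int] = DEFAULT_DELETION_EDGES,
                       ) -> dict[str, int]:
    """Histogram of reporter deletion sizes over half-open bins.

    ``edges`` must be strictly increasing and start at 0; the final bin
    is open-ended.  With the defaults the bins are 0, 1-10, 11-20, >=21 nt.
    """
    edges = list(edges)
    if not edges or edges[0] != 0 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing and start at 0")
    names = []
    for k, lo in enumerate(edges):
        hi = edges[k + 1] - 1 if k + 1 < len(edges) else None
        if hi is None:
            names.append(f">={lo}")
        elif hi == lo:
            names.append(str(lo))
        else:
            names.append(f"{lo}-{hi}")
    hist = {n: 0 for n in names}
    for c in calls:
        if not c.callable:
            continue
        if c.deletion_len < 0:
            raise ValueError("negative deletion_len")
        k = 0
        for k2, lo in enumerate(edges):
            if c.deletion_len >= lo:
                k = k2
        hist[names[k]] += 1
    return hist


def mh_usage_in_deletions(calls: Sequence[ReporterCall]) -> dict[int, int]:
    """Frequency table of microhomology length among deletion-bearing
    reporter junctions (junctions with ``deletion_len > 0`` and no
    insertion); empty when there are none."""
    table: dict[int, int] = {}
    for c in calls:
        if c.callable and c.deletion_len > 0 and not c.insertion_seq:
            table[c.mh_len] = table.get(c.mh_len, 0) + 1
    return dict(sorted(table.items()))


def reporter_signature(calls: Sequence[ReporterCall],
                       edges: Sequence[int] = DEFAULT_DELETION_EDGES) -> dict:
    """Mutational-signature summary of reporter junctions: per-class
    counts (blunt / insertion / deletion), deletion-size histogram, and
    microhomology usage among deletions."""
    callable_ = [c for c in calls if c.callable]
    classes = {lab: sum(1 for c in callable_ if c.class_label == lab)
               for lab in ("blunt", "insertion", "deletion")}
    return {
        "classes": classes,
        "deletion_sizes": bin_deletion_sizes(
            [c for c in callable_ if c.class_label == "deletion"], edges),
        "mh_usage": mh_usage_in_deletions(callable_),
        "n": len(callable_),
    }
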