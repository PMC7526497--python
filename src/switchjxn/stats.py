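"""Cohort statistics and scalar assay formulas.

Repair-pathway usage between cohorts is compared per category with an
uncorrected Pearson chi-square on the 2x2 table (in category / not in
category x cohort A / cohort B).  No continuity correction is applied:
the uncorrected statistic is what reproduces published junction-table
p-values from their printed counts, and no multiple-testing adjustment
is applied by default (per-category reporting), with Holm adjustment
available as an option for new analyses.

Rank-based comparison of junction characteristics (deletion counts,
N-nucleotides, ...) uses the two-sided Mann-Whitney U test: exact null
distribution for small samples (m*n <= 400, no ties), normal
approximation with tie correction otherwise.  The two-sided exact
convention is the doubled one-sided tail, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .classify import CohortTable, LABELS


@dataclass(frozen=True)
class TwoByTwo:
    """Contingency table: rows = cohorts, columns = in/not-in category."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table total must be >= 1")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_two_sided: float


@dataclass(frozen=True)
class IntensityTriple:
    """Mean pixel intensities at a laser-damage track, in the surrounding
    nucleoplasm, and in a cell-free background region (arbitrary units)."""

    i_damage: float
    i_nucleoplasm: float
    i_background: float


@dataclass(frozen=True)
class IntegrationCounts:
    """Readouts of the random plasmid-integration assay for end-joining:
    cloning efficiency with and without selection, and transfection
    efficiency, all as fractions in (0, 1]."""

    cloning_eff_selected: float
    cloning_eff_unselected: float
    transfection_eff: float

    def __post_init__(self) -> None:
        for name in ("cloning_eff_selected", "cloning_eff_unselected",
                     "transfection_eff"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


def chisq_2x2(t: TwoByTwo) -> TestResult:
    """Uncorrected Pearson chi-square (df=1) on a 2x2 table, two-sided p.

    Raises on a zero row or column marginal (degenerate table).
    """
    table = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero marginal")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(statistic=float(chi2), p_two_sided=float(p))


def compare_categories(a: CohortTable, b: CohortTable,
                       holm: bool = False) -> dict[str, dict]:
    """Per-category 2x2 chi-square between two cohorts.

    For each category the table is (in category vs rest) x (cohort a vs
    cohort b).  Returns ``label -> {statistic, p, direction, count_a,
    total_a, count_b, total_b}`` where direction is "up"/"down"/"none"
    for cohort a relative to cohort b.  A category absent from both
    cohorts yields statistic 0, p 1.  With ``holm=True``, p-values are
    Holm-adjusted across the categories.
    """
    out: dict[str, dict] = {}
    for lab in LABELS:
        ca, cb = a.counts[lab], b.counts[lab]
        if ca == 0 and cb == 0:
            res = TestResult(0.0, 1.0)
        else:
            res = chisq_2x2(TwoByTwo(ca, a.total - ca, cb, b.total - cb))
        pa, pb = ca / a.total, cb / b.total
        direction = "up" if pa > pb else ("down" if pa < pb else "none")
        out[lab] = {
            "statistic": res.statistic, "p": res.p_two_sided,
            "direction": direction,
            "count_a": ca, "total_a": a.total,
            "count_b": cb, "total_b": b.total,
        }
    if holm:
        labs = list(out)
        padj = _holm([out[l]["p"] for l in labs])
        for l, p in zip(labs, padj):
            out[l]["p"] = p
    return out


def _holm(ps: Sequence[float]) -> list[float]:
    m = len(ps)
    order = np.argsort(ps)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * ps[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact p (doubled one-sided tail, capped at 1) when ``m*n <= 400``
    and there are no ties; otherwise the normal approximation with tie
    correction (no continuity correction, so identical samples give p=1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size * y.size <= 400 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
    p = float(res.pvalue)
    if np.isnan(p):  # all pooled values identical: no evidence either way
        p = 1.0
    return TestResult(statistic=float(res.statistic), p_two_sided=min(p, 1.0))


def plasmid_integration_efficiency(c: IntegrationCounts,
                                   control: IntegrationCounts) -> float:
    """End-joining efficiency from the plasmid integration assay,
    normalized to a control condition.

    raw = selected cloning efficiency / (unselected cloning efficiency
    x transfection efficiency); the result is raw(c) / raw(control).
    """

    def raw(ic: IntegrationCounts) -> float:
        denom = ic.cloning_eff_unselected * ic.transfection_eff
        if denom == 0:
            raise ZeroDivisionError("zero denominator in integration formula")
        return ic.cloning_eff_selected / denom

    control_raw = raw(control)
    if control_raw == 0:
        raise ZeroDivisionError("control raw efficiency is zero")
    return raw(c) / control_raw


def relative_accumulation(m: IntensityTriple) -> float:
    """Background-corrected accumulation at a damage track relative to the
    nucleoplasmic level: (Id - Ibg)/(Inp - Ibg) - 1.

    0 means no enrichment over the nucleoplasm; -1 means signal at
    background level.
    """
    if m.i_nucleoplasm <= m.i_background:
        raise ValueError("invalid measurement: i_nucleoplasm must exceed "
                         "i_background")
    return (m.i_damage - m.i_background) / (m.i_nucleoplasm - m.i_background) - 1.0
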