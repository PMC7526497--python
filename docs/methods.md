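# Methods

## Breakpoint model

A junction read is modelled as `donor prefix | untemplated insertion |
acceptor suffix`. Both flanks are aligned semi-globally — the read end
of each flank is fixed, the reference end away from the junction is free
— with affine gaps. Scores: match +1, mismatch −2, gap open −4 (first
gapped base), gap extend −1. These values are conventional Sanger-style
settings; the published analyses this package reimplements state only
that junction sequences were aligned to the switch-region references,
so the scores are package defaults, configurable via `CallerParams`.
Insertion bases between the two flank alignments are unaligned and score
0; with mismatch −2 this means a junction-adjacent base that matches
neither reference is attributed to the insertion rather than forced into
a flank as a mismatch.

Because the total score is `P(i) + S(j)` with independent flank terms,
maximizing it over all splits `(i, j)` is exactly the exhaustive
enumeration over (prefix length, insertion length, donor_end,
acceptor_start). The implementation fills one prefix DP (every read
prefix vs donor) and one reversed DP (every read suffix vs acceptor)
with numba kernels, then maximizes the outer sum; the test suite checks
score equality against an independent Biopython-based enumeration oracle
on 500 random instances.

### Microhomology

`compute_microhomology(donor, d, acceptor, a)` extends left and right
from the junction for as long as the two *references* agree exactly.
Only perfect matches count (the four-category scheme is defined on
perfectly matched homology); N never matches, so Sanger ambiguity calls
cannot create phantom homology. `mh_len` is invariant to where inside
the homology window the junction is placed; calls report the
donor-maximal placement (largest `donor_end`), a pure convention.

### Determinism and tie-breaking

Among equal-scoring splits the caller prefers, in order: larger
`mh_len`, shorter insertion, smaller `donor_end`, smaller
`acceptor_start`. This total order makes calls deterministic, and puts
a junction with both an insertion and incidental flanking homology in
the `insertion` category with mh 0 — required for the four categories
to partition.

### Callability

Reads whose donor- or acceptor-aligned flank is shorter than
`min_flank` (default 15 nt) or scores ≤ 0 are flagged uncallable and
excluded from classification; this guards against spurious splits in
repeat-rich S regions.

### Sequential-switching footprints

Two successive switch events (e.g. Sμ→Sγ3→Sγ2) leave a block of the
intermediate S region between donor and acceptor segments. Published
descriptions name the phenomenon but no algorithm, so the detection here
is the package's own design: the block is located as the best local
(Smith–Waterman) alignment of the read against each intermediate
reference; it is reported when the aligned read segment is ≥ 15 nt
(`footprint_min_len`) at ≥ 90% identity (`footprint_min_ident`), the
donor/acceptor flanks outside the segment still score positively, and
the three-part total strictly exceeds the two-part score. The
thresholds are configurable; the defaults keep false footprints from
random S-region sequence rare while detecting exact blocks of 15+ nt.

### Reporter junctions

For nuclease-cut reporter constructs the sequence left of the first cut
is the donor, right of the second cut the acceptor.
`deletion_len = (cut_left − donor_end) + acceptor_start` counts bases
resected beyond the cuts (pooled over both sides; invariant to homology
sliding). Junctions are labelled `insertion` (untemplated bases),
`deletion` (deletion_len > 0) or `blunt`. Deletion-size bins default to
0 / 1–10 / 11–20 / ≥21 nt — the published figure does not state its
edges, so these are package defaults, configurable in
`bin_deletion_sizes`.

## Cohort statistics

Per-category comparisons use the uncorrected Pearson χ² (df 1) on the
2×2 table (in-category vs rest × cohort A vs B); only the uncorrected
statistic reproduces the published p-values from their printed counts
(Yates' correction does not). No multiple-testing adjustment is applied
by default, matching per-category reporting; `holm=True` offers Holm
adjustment. A category absent from both cohorts returns statistic 0,
p 1 rather than a degenerate-table error.

Integer percentages round half away from zero, which reproduces the
published Sμ-Sγ rows exactly. Two published Sμ-Sα cells (34 of 82
printed as 42%, 50 of 213 printed as 24%) are inconsistent with any
standard rounding of their printed counts; the package reports 41% and
23% and does not chase the discrepancy.

Mann–Whitney U is two-sided: exact when `m·n ≤ 400` with no ties
(doubled one-sided tail, capped at 1 — scipy's exact method, verified
against full permutation enumeration), otherwise the normal
approximation with tie correction and no continuity correction, so
identical samples give p = 1 exactly.

The assay scalars are direct formula evaluations: plasmid-integration
end-joining efficiency `selected / (unselected × transfection)`,
normalized to a control; laser-track relative accumulation
`(I_damage − I_bg)/(I_nucleoplasm − I_bg) − 1`.

## Synthetic data

`make_switch_reference` emulates S-region structure: tandem repeats of
short motifs (defaults GAGCT/GGGGT, the Sμ-style pentamers) with
per-base divergence (default 0.08). The divergence makes 100+ nt flanks
effectively unique, which real S regions achieve through their own
degeneracy; without it, perfectly periodic references would make every
flank placement ambiguous.

`simulate_junctions` draws each read's outcome from the configured
masses (`p_direct`, `p_insertion`, `mh_law` over lengths 1–20), flank
lengths uniform in `flank_len_law` (default 100–250 nt per flank, giving
Sanger-length 200–500 nt reads), then applies substitution noise
(default 0.002/base — the true per-read error rate of archival Sanger
data is unknown; this placeholder is surfaced in the config). Ground
truth is guaranteed realizable by construction:

- microhomology of length k is **planted** by locally editing the
  acceptor reference so its bases before the junction equal the donor's
  last k bases, with a pinned mismatch on each side so the homology
  window is exactly k. Each read's edit occupies its own
  non-overlapping slot along the acceptor (slots are `max_k + 2` nt
  apart), so edits never clash; the acceptor must be long enough or the
  generator raises. The *edited* acceptor is returned and is the
  reference downstream calls must use.
- direct joins get a pinned mismatch on each side of the junction so
  chance homology cannot blur the truth; insertion reads get edge bases
  that extend neither flank.

Truth coordinates are recorded at the donor-maximal placement, matching
the caller's convention, so noise-free recovery can be checked for exact
equality. Cohort presets `control-like` (16/24/36/24% over the four
categories) and `ICF2-like` (5/13/42/40%) carry published cohort
spectra; within the 1–6 and ≥7 classes the per-length mass is uniform
(1–6 and 7–12 respectively), a package choice since per-length spectra
were not published.

`simulate_reporter_junctions` religates a cut reporter with blunt,
insertion, or deletion outcomes; total deletion is geometric (mean
`deletion_mean`, default 8 nt) split uniformly between sides. A
"planted" microhomology regime uses a reporter built with a direct
repeat straddling the cuts (`make_reporter_reference`), at which
deletion reads anneal — modelling microhomology-mediated joining. The
reporter outcome fractions (default 0.4/0.3/0.3) are synthetic
placeholders: the corresponding published figure reports its spectra
only graphically.

What the generator does **not** emulate: AID hotspot positioning,
chromatogram/quality artefacts, PCR chimeras, and (by default) Sanger
indel errors — substitution noise only, so truth/call comparisons stay
crisp. A green recovery test therefore establishes correctness of the
calling and classification machinery on reads whose error process is
substitution-only, not performance on raw chromatogram data.

## Statistical acceptance checks

Power and type-I-error properties of the cohort comparison
(discrimination of the two presets at n = 200, and calibration under a
common multinomial null) are computed at the class-count level — cohorts
drawn directly from the preset multinomials — because those properties
depend only on the class frequencies and the χ² test. Base-level
fidelity (simulate → call → classify) is checked separately at n = 500
per preset: class proportions within the binomial 99% CI of the
configured masses, and exact microhomology recovery ≥ 95% at the default
substitution rate.

## Known limitations

- Only perfectly matched microhomology is scored; mismatch-tolerant
  "imperfect homology" schemes are out of scope.
- The caller assumes one junction (or one intermediate block) per read;
  reads with more than two S-region transitions are not modelled.
- Reference choice matters in repeat-rich regions: the package treats
  references as user input and does not ship switch-region sequences.
- The asymptotic χ² is unreliable for very small cohorts; no exact test
  is offered by default (the published analyses used χ²).
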