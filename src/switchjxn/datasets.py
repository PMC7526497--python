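"""Packaged worked-example data.

``csr_junction_counts.tsv`` holds published per-cohort junction category
counts at the Smu-Salpha and Smu-Sgamma loci (ICF2 patients, LIG4- and
Artemis-deficient patients, healthy-children controls), the worked
example for the cohort summary and comparison stages.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .classify import CohortTable, cohort_table_from_counts


def load_csr_junction_counts() -> pd.DataFrame:
    with resources.files("switchjxn.data").joinpath(
            "csr_junction_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def cohort_tables(locus: str = "Smu-Salpha") -> dict[str, CohortTable]:
    """CohortTable per cohort for one locus of the packaged counts."""
    df = load_csr_junction_counts()
    df = df[df["locus"] == locus]
    if df.empty:
        raise ValueError(f"unknown locus {locus!r}")
    out = {}
    for _, row in df.iterrows():
        out[row["cohort"]] = cohort_table_from_counts(
            row["cohort"],
            {lab: int(row[lab])
             for lab in ("direct", "insertion", "mh_1_6", "mh_ge7")})
    return out
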