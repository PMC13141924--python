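"""Cohort characteristic summaries (counts and percentages).

A small bundled fixture carries the recruited cohort's categorical counts
(40 LUAD patients: sex, smoking status, comorbidities) so the percentage
arithmetic is reproducible without patient-level data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_clinical_counts", "percentages"]


def load_clinical_counts() -> pd.DataFrame:
    """Bundled per-characteristic counts (columns: characteristic, count, total)."""
    with resources.files("pairedmicro.data").joinpath("clinical_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def percentages(counts: pd.DataFrame | None = None, decimals: int = 1) -> pd.Series:
    """Percentage of each characteristic, rounded as conventionally printed."""
    if counts is None:
        counts = load_clinical_counts()
    pct = (100.0 * counts["count"] / counts["total"]).round(decimals)
    return pd.Series(pct.values, index=counts["characteristic"], name="percent")
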