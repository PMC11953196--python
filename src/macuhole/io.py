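"""Cohort-table and report I/O.

Tables are UTF-8 comma-delimited text with a header row; missing values are
encoded as empty fields (never sentinel numbers) and round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COHORT_COLUMNS",
    "SCORED_COLUMNS",
    "read_cohort",
    "write_cohort",
]

COHORT_COLUMNS = [
    "eye_id",
    "sex",
    "age_years",
    "symptom_months",
    "basal_diameter_um",
    "minimum_diameter_um",
    "la_mm2",
    "ta_mm2",
    "bcva_t0_logmar",
    "bcva_t1_logmar",
    "ez_t0_um",
    "ez_t1_um",
    "elm_t0_um",
    "elm_t1_um",
    "grader2_la_mm2",
    "grader2_ta_mm2",
]

SCORED_COLUMNS = COHORT_COLUMNS + [
    "pra_mm2",
    "norm_pra",
    "norm_la",
    "piin",
    "ivts_class",
    "delta_bcva_logmar",
    "delta_ez_um",
    "delta_elm_um",
]

_STRING_COLUMNS = {"eye_id", "sex", "ivts_class"}


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort table; empty fields become missing values."""
    df = pd.read_csv(path, keep_default_na=True, na_values=[""])
    for col in df.columns:
        if col not in _STRING_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table with missing values as empty fields.

    Floats are written with full (round-trippable) precision.
    """
    table.to_csv(path, index=False, na_rep="", float_format="%.17g")
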