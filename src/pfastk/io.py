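"""Cohort CSV schema, validation, and run reporting."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

COHORT_COLUMNS = [
    "participant_id",
    "sex",
    "age_baseline",
    "serum_creatinine",
    "analyte",
    "c_baseline",
    "c_followup",
    "interval_days",
]


class SchemaError(ValueError):
    """Input table does not match the cohort schema; lists offending columns."""


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate the long-format cohort table.

    One row per participant x analyte; concentrations must be positive and
    the interval consistent within each participant x analyte pair.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if (df["c_baseline"] <= 0).any() or (df["c_followup"] <= 0).any():
        bad = df[(df["c_baseline"] <= 0) | (df["c_followup"] <= 0)]
        raise SchemaError(
            f"non-positive concentrations for participants {sorted(set(bad['participant_id']))}"
        )
    if (df["interval_days"] <= 0).any():
        raise SchemaError("interval_days must be positive")
    return df


def substitute_below_lod(values, lod: float):
    """Replace values below the assay LOD by LOD/sqrt(2).

    Standard biomonitoring convention for left-censored measurements.
    Returns (substituted array, boolean flag array of substituted entries).
    """
    v = np.asarray(values, dtype=float)
    flagged = v < lod
    out = np.where(flagged, lod / np.sqrt(2.0), v)
    return out, flagged


def write_run_report(
    path: str | Path, settings: dict, exclusions: dict[str, dict[str, str]]
) -> None:
    """JSON run report: settings used and per-analyte exclusion log."""
    Path(path).write_text(
        json.dumps({"settings": settings, "exclusions": exclusions}, indent=2)
        + "\n"
    )
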