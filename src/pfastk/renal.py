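"""Kidney-function covariate: eGFR from serum creatinine, age, and sex.

Uses the three-variable Japanese Society of Nephrology equation

    eGFR = 194 * Scr^(-1.094) * age^(-0.287)   [* 0.739 if female]

in mL/min/1.73 m^2, with Scr in mg/dL and age in years.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class ParticipantRecord:
    """Demographics and renal covariates for one subject."""

    participant_id: str
    sex: str  # "female" | "male"
    age_baseline: float
    serum_creatinine: float
    height: float | None = None  # cm
    weight: float | None = None  # kg
    egfr: float | None = None  # mL/min/1.73 m^2, computed
    excluded: bool = False
    exclusion_reason: str = ""


def egfr_japanese(serum_creatinine: float, age: float, sex: str) -> float:
    """Estimated GFR (mL/min/1.73 m^2) by the Japanese 3-variable equation.

    Parameters: Scr in mg/dL (> 0), age in years (>= 18), sex "female" or
    "male" (female values carry the 0.739 factor).
    """
    if serum_creatinine <= 0:
        raise ValueError("serum_creatinine must be positive")
    if age < 18:
        raise ValueError("equation is for adults (age >= 18)")
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    egfr = 194.0 * serum_creatinine ** -1.094 * age ** -0.287
    if sex == "female":
        egfr *= 0.739
    return egfr


def add_egfr(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the participant table with an ``egfr`` column."""
    out = records.copy()
    out["egfr"] = [
        egfr_japanese(float(r.serum_creatinine), float(r.age_baseline), str(r.sex))
        for r in out.itertuples()
    ]
    return out
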