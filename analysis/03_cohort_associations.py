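#!/usr/bin/env python
"""Descriptive panel statistics and covariate associations on the synthetic cohort.

Produces the two-timepoint panel summary (GM, median, range, mean percent
decrease, paired-test p), Pearson correlations of baseline concentration with
age, and the eGFR vs individual-half-life regressions. All on the synthetic
cohort, so the point is the shape of the analysis, not the specific numbers.

Writes results/panel_summary.csv and results/associations.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pfastk.cohort_stats import (
    correlate,
    panel_to_frame,
    regress_simple,
    summarize_panel,
)
from pfastk.io import read_cohort_csv
from pfastk.kinetics import AnalyteSpec, run_estimation
from pfastk.renal import add_egfr

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort_path = OUT / "cohort.csv"
    if not cohort_path.exists():
        raise SystemExit(f"{cohort_path} missing; run 01_simulate_cohort.py first")
    cohort = read_cohort_csv(cohort_path)
    participants = add_egfr(cohort.drop_duplicates("participant_id"))

    summaries = [
        summarize_panel(sub["c_baseline"], sub["c_followup"], analyte=code)
        for code, sub in cohort.groupby("analyte", sort=False)
    ]
    panel = panel_to_frame(summaries)
    panel.to_csv(OUT / "panel_summary.csv", index=False)
    print("panel summary (GM baseline -> follow-up, mean % decrease, paired p):")
    for s in summaries:
        print(f"  {s.analyte:8s} {s.gm_baseline:5.1f} -> {s.gm_followup:5.1f} ng/mL, "
              f"{s.mean_pct_decrease:5.1f}%, p={s.paired_p:.3f}")

    rows = []
    for code, sub in cohort.groupby("analyte", sort=False):
        merged = sub.merge(
            participants[["participant_id", "egfr"]], on="participant_id"
        )
        res = correlate(
            merged["age_baseline"], merged["c_baseline"],
            predictor="age_baseline", response=f"{code} baseline",
        )
        rows.append(vars(res))

        (hl,) = run_estimation(sub, [AnalyteSpec(code)])
        indiv = pd.Series(
            hl.individual_half_lives_years, index=hl.participant_ids, name="hl"
        )
        merged = merged.set_index("participant_id").join(indiv).dropna(subset=["hl"])
        reg = regress_simple(
            merged["egfr"], merged["hl"],
            predictor="egfr", response=f"{code} individual half-life",
        )
        rows.append(vars(reg))
        print(f"  {code:8s} eGFR vs half-life: slope {reg.slope:+.3f} y per unit, "
              f"R^2 {reg.r_or_r2:.3f}, p {reg.p:.3f}")

    pd.DataFrame(rows).to_csv(OUT / "associations.csv", index=False)
    print(f"wrote {OUT / 'panel_summary.csv'} and {OUT / 'associations.csv'}")


if __name__ == "__main__":
    main()
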