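#!/usr/bin/env python
"""Generate the default synthetic biomonitoring cohort.

17 amenorrheic female subjects, three analytes (L-PFOS, L-PFHxS, L-PFOA) with
lognormal baselines matching the observed 2020 geometric means, per-subject
lognormal elimination rates, first-order decay toward national-survey
background levels over 1099 days, and 10% multiplicative follow-up noise.
Writes results/cohort.csv (the analysis input) and results/truth.csv (the
hidden per-subject truth, kept separate from the analysis table).
"""

from pathlib import Path

from pfastk.synthetic import CohortConfig, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = CohortConfig(seed=20260927)
    cohort = generate_cohort(cfg)
    OUT.mkdir(exist_ok=True)
    cohort.pairs.to_csv(OUT / "cohort.csv", index=False)
    cohort.truth.to_csv(OUT / "truth.csv", index=False)
    print(f"cohort: {cfg.n_participants} subjects x {len(cfg.analytes)} analytes, "
          f"interval {cfg.interval_days:.0f} d, noise CV {cfg.noise_cv:.0%}, "
          f"seed {cfg.seed}")
    import numpy as np

    for code, sub in cohort.pairs.groupby("analyte"):
        gm_b = np.exp(np.log(sub["c_baseline"]).mean())
        gm_f = np.exp(np.log(sub["c_followup"]).mean())
        print(f"  {code:8s} realized GM {gm_b:5.1f} -> {gm_f:5.1f} ng/mL")
    print(f"wrote {OUT / 'cohort.csv'} and {OUT / 'truth.csv'}")


if __name__ == "__main__":
    main()
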