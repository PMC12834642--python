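import numpy as np
import pandas as pd
import pytest

from pfastk.synthetic import CohortConfig, cohort_from_geometric_means, generate_cohort

#: Observed geometric means (ng/mL) of the three linear-isomer panels at the
#: two sampling timepoints, 1099 days apart.
GM_PAIRS = {"L-PFOS": (13.9, 8.1), "L-PFHxS": (21.0, 14.6), "L-PFOA": (5.5, 4.2)}


@pytest.fixture(scope="session")
def gm_cohort() -> pd.DataFrame:
    """17-subject paired set whose log-means equal the published GMs exactly."""
    df = cohort_from_geometric_means(GM_PAIRS, n=17, interval_days=1099.0, seed=7)
    # attach demographics so stratified runs and eGFR have covariates
    rng = np.random.default_rng(7)
    ages = np.concatenate([rng.integers(53, 71, size=8), rng.integers(71, 84, size=9)])
    demo = pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:02d}" for i in range(17)],
            "sex": "female",
            "age_baseline": ages.astype(float),
            "serum_creatinine": np.round(rng.normal(0.68, 0.07, size=17), 2),
        }
    )
    return df.merge(demo, on="participant_id")


@pytest.fixture(scope="session")
def default_cohort():
    """One draw from the default synthetic cohort configuration."""
    return generate_cohort(CohortConfig(seed=11))
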