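"""Rate-constant estimation, pooling, and confidence intervals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfastk.kinetics import (
    DAYS_PER_YEAR,
    LN2,
    AnalyteSpec,
    BackgroundExceedsConcentration,
    PairedConcentration,
    RateConstantSet,
    estimate_rate_constant,
    individual_half_life,
    pool_half_life,
    rate_constants_for,
    run_estimation,
)


def pc(cb, cf, t=1099.0, pid="P01", analyte="X"):
    return PairedConcentration(pid, analyte, cb, cf, t)


class TestEstimateRateConstant:
    def test_exact_halving_gives_ln2_over_t(self):
        # closed form: one half-life elapsed => k = ln2 / t
        k = estimate_rate_constant(pc(8.0, 4.0, t=693.1))
        assert k == pytest.approx(LN2 / 693.1)
        assert k == pytest.approx(1.0e-3, rel=2e-4)

    def test_no_decline_gives_zero(self):
        assert estimate_rate_constant(pc(10.0, 10.0)) == 0.0

    def test_gm_level_decline_matches_published_pooled_value(self):
        # a subject declining exactly like the cohort GMs carries the pooled rate
        k = estimate_rate_constant(pc(13.9, 8.1, t=1099.0))
        assert LN2 / k == pytest.approx(1411, abs=1)  # days
        assert individual_half_life(k) == pytest.approx(3.9, abs=0.05)

    def test_rising_concentration_gives_negative_k(self):
        assert estimate_rate_constant(pc(5.0, 6.0)) < 0

    def test_background_at_or_above_concentration_raises(self):
        with pytest.raises(BackgroundExceedsConcentration):
            estimate_rate_constant(pc(3.0, 1.4), c0=1.5)

    def test_background_subtraction_increases_rate(self):
        naive = estimate_rate_constant(pc(10.0, 6.0))
        adjusted = estimate_rate_constant(pc(10.0, 6.0), c0=1.5)
        assert adjusted > naive

    def test_invalid_concentrations_rejected(self):
        with pytest.raises(ValueError):
            pc(-1.0, 5.0)
        with pytest.raises(ValueError):
            pc(5.0, 5.0, t=0.0)


class TestIndividualHalfLife:
    @pytest.mark.parametrize(
        "k, expected_years",
        [
            (LN2 / 365.25, 1.0),
            (6.931e-4, 1000.07 / 365.25),  # ~1000 days
            (LN2 / 1099.0, 1099.0 / 365.25),  # the sampling interval itself
        ],
    )
    def test_closed_form(self, k, expected_years):
        assert individual_half_life(k) == pytest.approx(expected_years, rel=1e-4)

    def test_non_positive_rate_flagged_as_nan(self):
        assert math.isnan(individual_half_life(0.0))
        assert math.isnan(individual_half_life(-1e-4))


class TestPooling:
    def test_constant_rates_give_degenerate_ci_at_estimate(self):
        k = np.full(5, LN2 / 1099.0)
        res = pool_half_life(RateConstantSet("X", False, k, [f"P{i}" for i in range(5)]))
        assert res.pooled_half_life_years == pytest.approx(1099.0 / 365.25)
        assert res.pooled_half_life_years == pytest.approx(3.009, abs=5e-4)
        assert res.pooled_ci[0] == pytest.approx(res.pooled_half_life_years)
        assert res.pooled_ci[1] == pytest.approx(res.pooled_half_life_years)

    def test_ci_brackets_estimate_and_is_asymmetric(self):
        rng = np.random.default_rng(3)
        k = rng.lognormal(math.log(5e-4), 0.3, size=17)
        res = pool_half_life(RateConstantSet("X", False, k, [str(i) for i in range(17)]))
        lo, hi = res.pooled_ci
        assert lo < res.pooled_half_life_years < hi
        # reciprocal transform: upper gap exceeds lower gap
        assert hi - res.pooled_half_life_years > res.pooled_half_life_years - lo

    def test_nonpositive_mean_rate_is_nonidentifiable_not_an_error(self):
        k = np.array([1e-4, -3e-4])
        res = pool_half_life(RateConstantSet("X", False, k, ["a", "b"]))
        assert not res.identifiable
        assert math.isnan(res.pooled_half_life_years)

    def test_single_subject_has_no_ci(self):
        res = pool_half_life(RateConstantSet("X", False, np.array([5e-4]), ["a"]))
        assert res.n == 1
        assert not res.ci_available
        assert math.isnan(res.pooled_ci[0]) and math.isnan(res.pooled_ci[1])

    def test_rising_subjects_stay_in_pool_but_not_in_individual_mean(self):
        k = np.array([5e-4, 6e-4, -1e-4])
        res = pool_half_life(RateConstantSet("X", False, k, ["a", "b", "c"]))
        assert res.n == 3 and res.n_rising == 1
        assert res.pooled_half_life_years == pytest.approx(
            LN2 / np.mean(k) / DAYS_PER_YEAR
        )
        finite = res.individual_half_lives_years[np.isfinite(res.individual_half_lives_years)]
        assert res.individual_mean_years == pytest.approx(np.mean(finite))


class TestRunEstimation:
    def test_one_result_per_analyte_without_strata(self, gm_cohort):
        res = run_estimation(gm_cohort, adjusted=False)
        assert len(res) == 3
        assert {r.stratum for r in res} == {"all"}
        assert all(r.n == 17 for r in res)

    def test_age_stratification_yields_all_and_two_groups(self, gm_cohort):
        res = run_estimation(gm_cohort, adjusted=False, strata="age_70")
        assert len(res) == 9  # 3 analytes x {all, <=70, >70}
        for analyte in ("L-PFOS", "L-PFHxS", "L-PFOA"):
            strata = {r.stratum: r.n for r in res if r.analyte == analyte}
            assert strata["all"] == strata["<=70"] + strata[">70"] == 17
            assert strata["<=70"] == 8 and strata[">70"] == 9

    def test_adjusted_exclusions_are_logged(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "participant_id": ["A", "B"],
                "analyte": "L-PFOA",
                "c_baseline": [5.0, 1.4],  # B is below the 1.5 ng/mL background
                "c_followup": [4.0, 1.2],
                "interval_days": 1099.0,
            }
        )
        (res,) = run_estimation(df, [AnalyteSpec("L-PFOA", 1.5)], adjusted=True)
        assert res.n == 1
        assert "B" in res.excluded_ids


class TestNoiseFreeRecovery:
    def test_generator_truth_recovered_to_machine_precision(self):
        from pfastk.synthetic import CohortConfig, generate_cohort

        cfg = CohortConfig(seed=5, noise_cv=0.0)
        cohort = generate_cohort(cfg)
        for row, truth in zip(
            cohort.pairs.itertuples(), cohort.truth.itertuples(), strict=True
        ):
            c0 = cfg.analytes[row.analyte].background_c0
            k_hat = estimate_rate_constant(
                PairedConcentration(
                    row.participant_id, row.analyte, row.c_baseline,
                    row.c_followup, row.interval_days,
                ),
                c0=c0,
            )
            assert k_hat == pytest.approx(truth.true_k, rel=1e-10)


# --- properties -------------------------------------------------------------

log_conc = st.floats(min_value=0.5, max_value=200.0)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    st.lists(st.tuples(log_conc, log_conc), min_size=2, max_size=30),
    st.floats(min_value=30.0, max_value=4000.0),
)
def test_pooled_half_life_equals_gm_ratio_form(pairs, t):
    """Pooled ln2/mean(k) identically equals ln2*t/(ln GM_b - ln GM_f)."""
    ks = RateConstantSet(
        "X",
        False,
        np.array([
            estimate_rate_constant(pc(cb, cf, t=t, pid=str(i)))
            for i, (cb, cf) in enumerate(pairs)
        ]),
        [str(i) for i in range(len(pairs))],
    )
    res = pool_half_life(ks)
    cb = np.array([p[0] for p in pairs])
    cf = np.array([p[1] for p in pairs])
    log_gm_diff = np.mean(np.log(cb)) - np.mean(np.log(cf))
    if log_gm_diff > 1e-6:
        gm_form = LN2 * t / log_gm_diff / DAYS_PER_YEAR
        assert res.pooled_half_life_years == pytest.approx(gm_form, rel=1e-10)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(min_value=5.0, max_value=100.0),
            st.floats(min_value=0.3, max_value=0.95),
        ),
        min_size=2,
        max_size=25,
    ),
    st.floats(min_value=0.5, max_value=4.0),
)
def test_background_subtraction_shortens_half_life(decliners, c0):
    """With declining levels all above C0 > 0, every k_s > k_i, so the
    adjusted half-life is shorter than the unadjusted one."""
    pairs = [
        pc(cb + c0, (cb + c0) * frac, pid=str(i))
        for i, (cb, frac) in enumerate(decliners)
        if (cb + c0) * frac > c0 + 0.1
    ]
    if len(pairs) < 2:
        return
    spec_raw, spec_adj = AnalyteSpec("X", 0.0), AnalyteSpec("X", c0)
    raw = rate_constants_for(pairs, spec_raw, adjusted=True)
    adj = rate_constants_for(pairs, spec_adj, adjusted=True)
    assert np.all(adj.per_participant_k > raw.per_participant_k)
    hl_raw = pool_half_life(raw).pooled_half_life_years
    hl_adj = pool_half_life(adj).pooled_half_life_years
    assert hl_adj < hl_raw
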