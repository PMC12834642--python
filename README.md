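# pfastk — serum PFAS elimination half-lives from two-timepoint biomonitoring data

`pfastk` estimates first-order elimination half-lives of per- and
polyfluoroalkyl substances (PFAS) in serum from paired measurements taken at
two timepoints, the design used when a cohort is resampled a few years after
a drinking-water exposure stops. It is written for exposure scientists and
biostatisticians working with small biomonitoring cohorts: it implements the
estimators, their confidence intervals, the background-exposure correction,
the accompanying cohort statistics (geometric-mean panels, paired tests,
correlations, an eGFR renal covariate), a seeded synthetic-cohort generator,
and a Monte-Carlo experiment quantifying the bias that ongoing background
exposure induces in the naive estimator.

## Model

For participant *i* with serum concentrations *C*ᵢ(0) at baseline and
*C*ᵢ(*t*) after *t* days, first-order elimination gives the per-participant
rate constant (per day)

    kᵢ = [ln Cᵢ(0) − ln Cᵢ(t)] / t

and, when elimination proceeds toward a constant ambient background *C*₀
rather than toward zero, the background-subtracted variant

    kₛᵢ = [ln(Cᵢ(0) − C₀) − ln(Cᵢ(t) − C₀)] / t .

The pooled cohort half-life is t½ = ln 2 / mean(kᵢ), and individual
half-lives are t½ᵢ = ln 2 / kᵢ (365.25 d/y). The half-life CI is the
reciprocal-transformed Student-*t* CI of mean *k* (n − 1 df), which is
asymmetric around the point estimate. Because the mean of log-declines equals
the difference of log geometric means, the pooled estimate is recomputable
from published GMs alone:

    t½ = ln 2 · t / (ln GM_baseline − ln GM_followup).

Default backgrounds are national-survey serum means: 2.5 ng/mL (L-PFOS),
1.5 ng/mL (L-PFOA), 0.4 ng/mL (L-PFHxS). Participants whose concentration
falls at or below the assumed background are excluded from the adjusted
analysis and logged.

## Worked example

```python
from pfastk import AnalyteSpec, run_estimation
from pfastk.synthetic import cohort_from_geometric_means

# any 17-subject paired set whose GMs are 13.9 -> 8.1 ng/mL over 1099 days
cohort = cohort_from_geometric_means({"L-PFOS": (13.9, 8.1)}, n=17, seed=0)
(res,) = run_estimation(cohort, [AnalyteSpec("L-PFOS")])
print(round(res.pooled_half_life_years, 1))   # 3.9
```

The pooled value depends only on the two geometric means and the interval, so
the seed does not matter: a 13.9 → 8.1 ng/mL GM decline over 1099 days is a
half-life of 3.9 years. Running the numbered drivers:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_estimate_half_lives.py
python analysis/03_cohort_associations.py
python analysis/04_background_bias.py
```

prints, among other output,

```
pooled half-lives from published GMs (raw | background-subtracted):
  L-PFOS    3.9 y |  2.8 y
  L-PFHxS   5.7 y |  5.6 y
  L-PFOA    7.7 y |  4.6 y

analyte-like scenarios (true adjusted half-life -> mean estimates):
  L-PFOS   true 2.7 y: naive 3.7 y, adjusted 2.7 y (naive bias +35.4%)
  L-PFHxS  true 5.6 y: naive 5.8 y, adjusted 5.6 y (naive bias +3.0%)
  L-PFOA   true 5.1 y: naive 7.7 y, adjusted 5.1 y (naive bias +51.6%)
```

The first block is the summary-statistic reproduction: raw pooled half-lives
implied by the published GMs, and how background subtraction shortens them —
strongly for the low-signal analyte (L-PFOA, background ≈ 27% of baseline),
hardly at all for the high-signal one (L-PFHxS, ≈ 2%). The second block is
the Monte-Carlo converse: cohorts simulated with known half-lives and real
ongoing background show the naive estimator inflating by the same pattern,
while subtracting the correct background recovers the truth.

A `pfastk` console command wraps the same library
(`pfastk simulate | estimate | bias`; exit codes 0/2/1 for
success/validation error/unexpected failure).

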