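# Methods

## The estimation problem

A small cohort (n = 17 amenorrheic women, ages 53–83) exposed to PFAS through
contaminated drinking water is sampled twice, 1099 days apart, after the
exposure source was removed. Under one-compartment first-order elimination,
each participant's serum concentration declines exponentially, and the
per-participant rate constant is identified from the log-ratio of the two
measurements. The package estimates:

- **naive rate** kᵢ = (ln C_baseline − ln C_followup)/t, which assumes decay
  toward zero;
- **background-subtracted rate** kₛ = (ln(C_b − C₀) − ln(C_f − C₀))/t, which
  assumes decay toward a constant ambient background C₀ maintained by
  ongoing diet/consumer-product exposure;
- the **pooled half-life** ln 2/mean(k) and **individual half-lives**
  ln 2/kᵢ, in years (365.25 d/y).

Default C₀ values are national biomonitoring survey means: 2.5 ng/mL
(L-PFOS), 1.5 ng/mL (L-PFOA), 0.4 ng/mL (L-PFHxS).

## Confidence intervals

The published analysis derives the half-life CI from the CI of mean k without
stating the CI method. We use the Student-t interval with n − 1 df on the
per-participant rate constants, then map both bounds through the reciprocal:
the lower half-life bound comes from the upper k bound and vice versa. This
produces the characteristic asymmetry (wider upward) of reciprocal
transforms. When the lower k bound crosses zero the upper half-life bound is
reported as +inf; when mean k ≤ 0 the half-life is reported as
non-identifiable (NaN), not raised as an error. With n < 2 the CI is marked
unavailable.

## Handling of edge cases

- **C ≤ C₀ under adjustment**: the adjusted rate is undefined; the
  participant is excluded from the adjusted analysis for that analyte and
  logged. No imputation.
- **Rising concentrations (k < 0)**: retained in mean(k) for pooling
  (dropping them would bias mean k upward); the individual half-life is
  reported as NaN and excluded from the individual mean and its CI, since a
  negative half-life has no physical meaning.
- **Values below the assay LOD**: substituted by LOD/√2 and flagged
  (standard biomonitoring convention); not exercised by the bundled
  cohorts, which contain no censored values.
- **Stratification ties**: "high" groups are strictly above the cut
  (> 70 years, > median, > 75th percentile); ties go low. The 75th
  percentile uses linear interpolation between order statistics. With 17
  distinct values this pins the p75 cut at the 13th order statistic, giving
  a 13/4 split; published subgroup counts from real data can differ when
  ties are present.

## Cohort statistics

Panel summaries report the geometric mean (exp of the mean log), median, and
range at each timepoint, plus the mean of individual percent declines —
deliberately the average of 100·(1 − C_f/C_b) per subject, not the decline of
the GM ratio, which differs when declines are heterogeneous. Paired tests
default to log-transformed concentrations, consistent with GM reporting and
the multiplicative error structure of serum assays; a flag switches to the
raw scale. Associations use Pearson correlation and simple OLS
(statsmodels). The renal covariate is the three-variable Japanese Society of
Nephrology eGFR equation, 194·Scr⁻¹·⁰⁹⁴·age⁻⁰·²⁸⁷ (×0.739 for women), chosen
because the cohort is Japanese; no CKD-EPI/MDRD variants are provided.

## Synthetic cohorts

The generator (`pfastk.synthetic`) emulates the study's structure: lognormal
baseline concentrations; per-subject lognormal rate constants; follow-up
concentrations from the forward model C(t) = C₀ + (C_init − C₀)e^(−kt) times
multiplicative lognormal noise on the follow-up measurement only (a flag adds
baseline noise). Defaults are fixed at the study conditions: n = 17, interval
1099 days, baseline GMs 13.9/21.0/5.5 ng/mL, backgrounds 2.5/0.4/1.5 ng/mL,
true rates set from the background-adjusted half-lives (2.7/5.6/5.1 years) so
that naive estimation on synthetic data reproduces the background-bias
mechanism, noise CV 10%, ages uniform over 53–83, creatinine N(0.68, 0.07).
Baseline geometric SDs (1.45, 2.0, 1.4) were set once from the observed
min–max ranges read as roughly ±2σ on the log scale. Per-subject rate GSD is
1.3, a moderate inter-individual spread consistent with the reported
variability of individual half-lives.

What the generator does **not** emulate: time-varying background intake,
assay censoring, within-subject kinetic changes (e.g. renal decline over the
interval), correlations between analytes within a subject, or branched
isomers. Passing tests therefore demonstrate correctness of the estimators
under the assumed lognormal first-order model, not robustness to violations
of it.

A hidden truth table (per-subject k and initial concentration) is written
separately from the cohort table so estimation code cannot accidentally
consume it.

## Background-bias experiment

`pfastk.bias` makes the background-exposure argument executable. Each
scenario fixes a true half-life, a true background C₀ driving the decay, an
assumed C₀ used by the adjusted estimator, a baseline GM/GSD, a noise CV, and
n = 17. Each of 500 replicates draws a cohort from the forward model and
pools both estimators. Noise-free, the naive log-ratio provably understates k
whenever C₀ > 0 (the measured decline is flatter than the decline of the
eliminable excess), so the naive half-life is inflated, increasingly so as
C₀/GM grows; the correctly specified adjustment recovers k exactly. The
default grid spans C₀/GM ∈ {0, 0.05, 0.1, 0.27, 0.5} × noise CV ∈
{0, 0.1, 0.2}, bracketing the three analytes (≈0.02 for PFHxS, ≈0.18 for
PFOS, ≈0.27 for PFOA). Replicates where more than half the subjects fall
below the assumed background are flagged unreliable rather than silently
averaged.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` with explicit seeds;
same seed ⇒ byte-identical outputs. Monte-Carlo checks in the test suite use
500–1000 replicates of n = 17 cohorts and a 10 000-subject draw for
law-of-large-numbers checks — sizes at which every sampling tolerance used
(±2% on a recovered GM, ±0.02 on a type-I error rate, <5% mean relative
bias) is several Monte-Carlo standard errors wide. The GM-reproduction
construction recentres lognormal scatter so realized log-means match
requested GMs to machine precision; the pooled estimate is then independent
of the scatter seed by the log-GM identity.

## Known limitations

- Two timepoints identify a single exponential only; no multi-compartment or
  mechanistic renal-clearance modelling, and no Bayesian hierarchical
  pooling.
- The background correction treats C₀ as known and constant; it is not
  inferred from the data, and mis-specified C₀ biases the adjusted estimator
  (quantifiable with `pfastk.bias` by setting `assumed_c0 ≠ true_c0`).
- Published subgroup counts and individual-level statistics from the original
  cohort cannot be reproduced exactly without the unpublished
  participant-level data; the package instead pins the summary-statistic
  identities and validates individual-level behaviour on synthetic cohorts.
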