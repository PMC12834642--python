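"""First-order elimination kinetics from two-timepoint serum concentrations.

For a participant *i* with serum concentrations ``C_b`` at baseline and
``C_f`` at follow-up, separated by ``t`` days, first-order elimination gives

    k_i = [ln(C_b) - ln(C_f)] / t        (naive)
    k_s = [ln(C_b - C0) - ln(C_f - C0)] / t   (background-subtracted)

where ``C0`` is a population background concentration attributable to ongoing
ambient exposure. The cohort ("pooled") half-life is ``ln 2 / mean(k)`` and
individual half-lives are ``ln 2 / k_i``, converted to years at 365.25 d/y.
The half-life CI is the reciprocal-transformed Student-t CI of mean k, which
is asymmetric around the point estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
LN2 = math.log(2.0)

#: National biomonitoring survey mean serum concentrations (ng/mL), used as
#: the default background C0 for the adjusted estimator.
DEFAULT_BACKGROUND_C0 = {"L-PFOS": 2.5, "L-PFOA": 1.5, "L-PFHxS": 0.4}


@dataclass(frozen=True)
class AnalyteSpec:
    """An analyte and its background serum concentration C0 (ng/mL)."""

    code: str
    background_c0: float = 0.0

    def __post_init__(self) -> None:
        if self.background_c0 < 0:
            raise ValueError(f"background_c0 must be >= 0, got {self.background_c0}")


def default_analytes() -> list[AnalyteSpec]:
    """The three linear-isomer analytes with survey backgrounds (ng/mL)."""
    return [AnalyteSpec(code, c0) for code, c0 in DEFAULT_BACKGROUND_C0.items()]


@dataclass(frozen=True)
class PairedConcentration:
    """One analyte's serum level for one subject at two timepoints.

    Concentrations in ng/mL, interval in days. Both concentrations must be
    positive; the interval must be positive.
    """

    participant_id: str
    analyte: str
    c_baseline: float
    c_followup: float
    interval_days: float

    def __post_init__(self) -> None:
        if self.c_baseline <= 0 or self.c_followup <= 0:
            raise ValueError(
                f"{self.participant_id}/{self.analyte}: concentrations must be "
                f"positive (got {self.c_baseline}, {self.c_followup})"
            )
        if self.interval_days <= 0:
            raise ValueError("interval_days must be positive")


class BackgroundExceedsConcentration(ValueError):
    """Background-subtracted concentration is non-positive.

    Signals a serum level at or below the assumed background; the adjusted
    rate constant is undefined for this participant and the participant is
    excluded from the adjusted analysis.
    """


def estimate_rate_constant(pc: PairedConcentration, c0: float = 0.0) -> float:
    """Per-participant elimination rate constant, per day.

    With ``c0 = 0`` this is the naive estimator k_i; with ``c0 > 0`` it is the
    background-subtracted estimator k_s. The result may be negative when the
    concentration rose over the interval.

    Raises
    ------
    BackgroundExceedsConcentration
        If either background-subtracted concentration is non-positive.
    """
    cb = pc.c_baseline - c0
    cf = pc.c_followup - c0
    if cb <= 0 or cf <= 0:
        raise BackgroundExceedsConcentration(
            f"{pc.participant_id}/{pc.analyte}: concentration at or below "
            f"background C0={c0} ng/mL (baseline {pc.c_baseline}, "
            f"follow-up {pc.c_followup})"
        )
    return (math.log(cb) - math.log(cf)) / pc.interval_days


def individual_half_life(k: float) -> float:
    """Individual half-life ln2/k in years; NaN when k <= 0 (no elimination)."""
    if k <= 0:
        return math.nan
    return LN2 / k / DAYS_PER_YEAR


@dataclass
class RateConstantSet:
    """Per-participant rate constants for one analyte/stratum.

    ``adjusted`` distinguishes background-subtracted k_s from naive k_i.
    ``excluded_ids`` maps participant ids dropped from this set (adjusted
    analysis only) to the reason.
    """

    analyte: str
    adjusted: bool
    per_participant_k: np.ndarray
    participant_ids: list[str]
    excluded_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.per_participant_k = np.asarray(self.per_participant_k, dtype=float)
        if not np.all(np.isfinite(self.per_participant_k)):
            raise ValueError("per_participant_k must contain only finite values")
        if len(self.per_participant_k) != len(self.participant_ids):
            raise ValueError("rate constants and participant ids differ in length")

    @property
    def n(self) -> int:
        return len(self.per_participant_k)


def rate_constants_for(
    pcs: list[PairedConcentration],
    analyte: AnalyteSpec,
    adjusted: bool = False,
) -> RateConstantSet:
    """Estimate a RateConstantSet, excluding subjects with C <= C0 if adjusted."""
    c0 = analyte.background_c0 if adjusted else 0.0
    ks: list[float] = []
    ids: list[str] = []
    excluded: dict[str, str] = {}
    for pc in pcs:
        try:
            ks.append(estimate_rate_constant(pc, c0))
            ids.append(pc.participant_id)
        except BackgroundExceedsConcentration as err:
            logger.warning("excluding %s: %s", pc.participant_id, err)
            excluded[pc.participant_id] = str(err)
    return RateConstantSet(analyte.code, adjusted, np.array(ks), ids, excluded)


@dataclass
class HalfLifeResult:
    """Pooled and individual half-life estimates for one analyte/stratum.

    All half-lives in years. ``pooled_half_life_years`` is ln2/mean(k);
    ``pooled_ci`` is the reciprocal-transformed t-CI of mean k. Individual
    half-lives are ln2/k_i per subject (NaN where k_i <= 0, which are excluded
    from ``individual_mean_years`` and its CI). CIs are NaN where n < 2, and a
    CI bound is +inf where the corresponding mean-k bound crosses zero.
    """

    analyte: str
    adjusted: bool
    stratum: str
    n: int
    pooled_half_life_years: float
    pooled_ci: tuple[float, float]
    individual_half_lives_years: np.ndarray
    individual_mean_years: float
    individual_ci: tuple[float, float]
    participant_ids: list[str] = field(default_factory=list)
    excluded_ids: dict[str, str] = field(default_factory=dict)
    n_rising: int = 0
    identifiable: bool = True
    ci_available: bool = True


def _t_ci_of_mean(x: np.ndarray, alpha: float) -> tuple[float, float]:
    """Student-t CI for the mean of x with n-1 df; (nan, nan) when n < 2."""
    n = len(x)
    if n < 2:
        return (math.nan, math.nan)
    m = float(np.mean(x))
    se = float(np.std(x, ddof=1)) / math.sqrt(n)
    tcrit = float(stats.t.ppf(1 - alpha / 2, n - 1))
    return (m - tcrit * se, m + tcrit * se)


def _reciprocal_hl(k: float) -> float:
    """ln2/k in years; +inf at k <= 0 (bound crossed zero, no upper limit)."""
    if k <= 0:
        return math.inf
    return LN2 / k / DAYS_PER_YEAR


def pool_half_life(
    ks: RateConstantSet, alpha: float = 0.05, stratum: str = "all"
) -> HalfLifeResult:
    """Pool per-participant rate constants into a cohort half-life.

    The pooled estimate is ln2/mean(k) converted to years; its CI maps the
    (lower, upper) t-CI bounds of mean k through the reciprocal, so the lower
    half-life bound comes from the upper k bound. mean(k) <= 0 is reported as
    non-identifiable (NaN half-life), not raised.
    """
    k = ks.per_participant_k
    n = ks.n
    mean_k = float(np.mean(k)) if n else math.nan
    identifiable = n > 0 and mean_k > 0

    pooled = LN2 / mean_k / DAYS_PER_YEAR if identifiable else math.nan
    lo_k, hi_k = _t_ci_of_mean(k, alpha)
    ci_available = n >= 2 and identifiable
    if ci_available:
        pooled_ci = (_reciprocal_hl(hi_k), _reciprocal_hl(lo_k))
    else:
        pooled_ci = (math.nan, math.nan)

    indiv = np.array([individual_half_life(ki) for ki in k])
    pos = indiv[np.isfinite(indiv)]
    n_rising = int(np.sum(~np.isfinite(indiv)))
    indiv_mean = float(np.mean(pos)) if len(pos) else math.nan
    indiv_ci = _t_ci_of_mean(pos, alpha) if len(pos) >= 2 else (math.nan, math.nan)

    return HalfLifeResult(
        analyte=ks.analyte,
        adjusted=ks.adjusted,
        stratum=stratum,
        n=n,
        pooled_half_life_years=pooled,
        pooled_ci=pooled_ci,
        individual_half_lives_years=indiv,
        individual_mean_years=indiv_mean,
        individual_ci=indiv_ci,
        participant_ids=list(ks.participant_ids),
        excluded_ids=dict(ks.excluded_ids),
        n_rising=n_rising,
        identifiable=identifiable,
        ci_available=ci_available,
    )


def _pairs_from_frame(df: pd.DataFrame) -> list[PairedConcentration]:
    return [
        PairedConcentration(
            participant_id=str(row.participant_id),
            analyte=str(row.analyte),
            c_baseline=float(row.c_baseline),
            c_followup=float(row.c_followup),
            interval_days=float(row.interval_days),
        )
        for row in df.itertuples()
    ]


def run_estimation(
    cohort: pd.DataFrame,
    analytes: list[AnalyteSpec] | None = None,
    adjusted: bool = False,
    strata: str | None = None,
    alpha: float = 0.05,
) -> list[HalfLifeResult]:
    """Half-life results per analyte x stratum for one adjustment setting.

    ``cohort`` is the long-format table (one row per participant x analyte)
    with columns participant_id, analyte, c_baseline, c_followup,
    interval_days and, when stratifying by age, age_baseline. ``strata`` is
    one of None, "age_70", "median_split", "p75_split"; the "all" stratum is
    always produced. Strata with n < 2 are emitted with the CI marked
    unavailable.
    """
    from pfastk.cohort_stats import stratify_cohort

    if analytes is None:
        analytes = default_analytes()
    results: list[HalfLifeResult] = []
    for spec in analytes:
        sub = cohort[cohort["analyte"] == spec.code]
        if sub.empty:
            continue
        partitions: dict[str, list[str]] = {
            "all": [str(p) for p in sub["participant_id"]]
        }
        if strata is not None:
            partitions.update(stratify_cohort(sub, strata))
        pcs = {pc.participant_id: pc for pc in _pairs_from_frame(sub)}
        for label, ids in partitions.items():
            group = [pcs[i] for i in ids if i in pcs]
            ks = rate_constants_for(group, spec, adjusted=adjusted)
            results.append(pool_half_life(ks, alpha=alpha, stratum=label))
    return results


def results_to_frame(results: list[HalfLifeResult]) -> pd.DataFrame:
    """Flatten results into the Table-3/4/5-shaped output frame."""
    rows = []
    for r in results:
        rows.append(
            {
                "analyte": r.analyte,
                "stratum": r.stratum,
                "adjusted": r.adjusted,
                "n": r.n,
                "pooled_hl": r.pooled_half_life_years,
                "ci_low": r.pooled_ci[0],
                "ci_high": r.pooled_ci[1],
                "indiv_mean": r.individual_mean_years,
                "indiv_ci_low": r.individual_ci[0],
                "indiv_ci_high": r.individual_ci[1],
                "n_excluded": len(r.excluded_ids),
                "n_rising": r.n_rising,
            }
        )
    return pd.DataFrame(rows)
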