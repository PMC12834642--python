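"""Descriptive and inferential cohort statistics.

Geometric-mean panel summaries, paired t-tests (log scale by default, matching
the lognormal structure of serum biomonitoring data), Pearson correlations,
simple OLS regression, and the stratification rules used for subgroup
half-life tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class PanelSummary:
    """Two-timepoint summary for one analyte panel (concentrations in ng/mL)."""

    analyte: str
    gm_baseline: float
    median_baseline: float
    min_baseline: float
    max_baseline: float
    gm_followup: float
    median_followup: float
    min_followup: float
    max_followup: float
    mean_pct_decrease: float
    paired_p: float


@dataclass
class AssociationResult:
    predictor: str
    response: str
    r_or_r2: float
    p: float
    slope: float
    intercept: float
    n: int


def summarize_panel(
    values_baseline, values_followup, analyte: str = ""
) -> PanelSummary:
    """GM / median / range at both timepoints, mean percent decrease, paired p.

    The percent decrease is the mean over participants of
    100 * (1 - c_followup / c_baseline), i.e. the average of the individual
    percent declines (not the decline of the GM ratio).
    """
    b = np.asarray(values_baseline, dtype=float)
    f = np.asarray(values_followup, dtype=float)
    if b.shape != f.shape:
        raise ValueError("baseline and followup lists must be paired (equal length)")
    if len(b) < 2:
        raise ValueError("need at least 2 pairs")
    if np.any(b <= 0) or np.any(f <= 0):
        raise ValueError("concentrations must be positive")
    return PanelSummary(
        analyte=analyte,
        gm_baseline=float(np.exp(np.mean(np.log(b)))),
        median_baseline=float(np.median(b)),
        min_baseline=float(np.min(b)),
        max_baseline=float(np.max(b)),
        gm_followup=float(np.exp(np.mean(np.log(f)))),
        median_followup=float(np.median(f)),
        min_followup=float(np.min(f)),
        max_followup=float(np.max(f)),
        mean_pct_decrease=float(np.mean(100.0 * (1.0 - f / b))),
        paired_p=paired_test(b, f),
    )


def paired_test(values_baseline, values_followup, on_log: bool = True) -> float:
    """Two-sided paired t-test p-value; NaN when the differences are constant.

    Defaults to log-transformed concentrations, consistent with geometric-mean
    reporting; set ``on_log=False`` for the raw scale.
    """
    b = np.asarray(values_baseline, dtype=float)
    f = np.asarray(values_followup, dtype=float)
    if b.shape != f.shape or len(b) < 2:
        raise ValueError("need >= 2 paired observations")
    if on_log:
        b, f = np.log(b), np.log(f)
    d = b - f
    if np.allclose(np.std(d, ddof=1), 0.0):
        return math.nan  # degenerate: zero variance of differences
    return float(stats.ttest_rel(b, f).pvalue)


def correlate(x, y, predictor: str = "x", response: str = "y") -> AssociationResult:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    r, p = stats.pearsonr(x, y)
    return AssociationResult(predictor, response, float(r), float(p),
                             slope=math.nan, intercept=math.nan, n=len(x))


def regress_simple(x, y, predictor: str = "x", response: str = "y") -> AssociationResult:
    """OLS of y on x: slope, intercept, R^2, slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.allclose(np.std(x), 0.0):
        raise ValueError("x has zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return AssociationResult(
        predictor,
        response,
        r_or_r2=float(fit.rsquared),
        p=float(fit.pvalues[1]),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        n=len(x),
    )


def stratify_cohort(records: pd.DataFrame, rule: str) -> dict[str, list[str]]:
    """Partition participants by one of the subgroup rules.

    Rules: ``age_70`` (<=70 vs >70 years on age_baseline), ``median_split``
    and ``p75_split`` (baseline concentration of the frame's analyte; the 75th
    percentile uses linear interpolation between order statistics). Ties at
    the cut-point go to the low group — "high" means strictly above the cut.
    Returns disjoint, exhaustive label -> participant_id lists.
    """
    df = records.drop_duplicates("participant_id")
    ids = df["participant_id"].astype(str)
    if rule == "age_70":
        cov = df["age_baseline"].astype(float)
        high = cov > 70
        labels = ("<=70", ">70")
    elif rule in ("median_split", "p75_split"):
        cov = df["c_baseline"].astype(float)
        q = 0.5 if rule == "median_split" else 0.75
        cut = float(np.quantile(cov, q))  # linear interpolation
        high = cov > cut
        labels = ("low", "high")
    else:
        raise ValueError(f"unknown stratification rule: {rule!r}")
    return {
        labels[0]: list(ids[~high.to_numpy()]),
        labels[1]: list(ids[high.to_numpy()]),
    }


def panel_to_frame(summaries: list[PanelSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for year, pre in (("baseline", "baseline"), ("followup", "followup")):
            rows.append(
                {
                    "analyte": s.analyte,
                    "timepoint": year,
                    "gm": getattr(s, f"gm_{pre}"),
                    "median": getattr(s, f"median_{pre}"),
                    "min": getattr(s, f"min_{pre}"),
                    "max": getattr(s, f"max_{pre}"),
                    "mean_pct_decrease": s.mean_pct_decrease,
                    "paired_p": s.paired_p,
                }
            )
    return pd.DataFrame(rows)
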