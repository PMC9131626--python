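"""Descriptive survival summaries by covariate group.

Counts, percentages married and mean/median/min/max observed marriage age,
overall and per covariate category.  Percentages use the full-sample
denominator throughout, and the age summaries are computed over observed
event cases only (a Kaplan-Meier median is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GroupSummary", "overall_summary", "describe_by_group"]


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n_total: int
    pct_total: float
    n_married: int
    pct_married_of_total: float
    mean_age: float | None
    median_age: float | None
    min_age: float | None = None
    max_age: float | None = None


def _age_stats(ages: np.ndarray):
    if ages.size == 0:
        return None, None, None, None
    return (
        float(ages.mean()),
        float(np.median(ages)),
        float(ages.min()),
        float(ages.max()),
    )


def overall_summary(
    data: pd.DataFrame, time_col: str = "time", event_col: str = "event"
) -> GroupSummary:
    """Whole-sample summary: % ever married and age-at-marriage statistics
    over the event cases."""
    if len(data) == 0:
        raise ValueError("dataset is empty")
    n = len(data)
    ev = data[event_col].to_numpy().astype(bool)
    ages = data.loc[ev, time_col].to_numpy(dtype=float)
    mean, med, lo, hi = _age_stats(ages)
    return GroupSummary(
        group="overall",
        n_total=n,
        pct_total=100.0,
        n_married=int(ev.sum()),
        pct_married_of_total=100.0 * ev.sum() / n,
        mean_age=mean,
        median_age=med,
        min_age=lo,
        max_age=hi,
    )


def describe_by_group(
    data: pd.DataFrame,
    covariate: str,
    time_col: str = "time",
    event_col: str = "event",
    km_median: bool = False,
) -> pd.DataFrame:
    """Per-category summaries for one covariate.

    Percentages are against the full-sample denominator, so the n_total
    percentages sum to 100 and the married percentages sum to the overall
    married percentage.  With ``km_median=True`` a Kaplan-Meier median
    (censoring-adjusted) is added per group.
    """
    if covariate not in data.columns:
        raise ValueError(f"unknown covariate {covariate!r}")
    n_all = len(data)
    if n_all == 0:
        raise ValueError("dataset is empty")
    rows = []
    grouped = data.groupby(covariate, observed=False, sort=False)
    for label, grp in grouped:
        ev = grp[event_col].to_numpy().astype(bool)
        ages = grp.loc[ev, time_col].to_numpy(dtype=float)
        mean, med, lo, hi = _age_stats(ages)
        row = {
            "group": str(label),
            "n_total": len(grp),
            "pct_total": 100.0 * len(grp) / n_all,
            "n_married": int(ev.sum()),
            "pct_married_of_total": 100.0 * ev.sum() / n_all,
            "mean_age": mean,
            "median_age": med,
            "min_age": lo,
            "max_age": hi,
        }
        if km_median:
            row["km_median_age"] = _km_median(
                grp[time_col].to_numpy(dtype=float), ev
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _km_median(times: np.ndarray, events: np.ndarray):
    from lifelines import KaplanMeierFitter

    if times.size == 0:
        return None
    km = KaplanMeierFitter().fit(times, events)
    med = km.median_survival_time_
    return None if np.isinf(med) else float(med)


def format_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Display rounding: percentages to 2 dp, ages to 1 dp (exact values
    are kept in the unformatted frame)."""
    out = df.copy()
    for c in ("pct_total", "pct_married_of_total"):
        if c in out:
            out[c] = out[c].round(2)
    for c in ("mean_age", "median_age", "min_age", "max_age", "km_median_age"):
        if c in out:
            out[c] = out[c].astype(float).round(1)
    return out
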