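"""Ground-visit detection, daily behavioural budgets and peak hours.

A Ground Visit is a cluster of Walking-labelled 20 s bins whose inter-bin
gaps are at most 60 s; a gap above 60 s starts a new visit. Budgets count
20 s bins per (individual, day), rescale each day's recorded time to
1440 min, and summarise study-level means by averaging within individuals
across days first, then across individuals.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .labels import CATEGORIES, WALKING
from .postprocess import BIN_S

MIN_RECORDED_MIN = 60.0  # days with less coverage are excluded from budgets


def detect_visits(bins: pd.DataFrame, max_gap_s: float = 60.0,
                  bin_s: int = BIN_S) -> pd.DataFrame:
    """Cluster Walking bins into Ground Visits.

    Returns one row per visit: individual, start_s, end_s, n_bins and
    walking_minutes (= n_bins * bin_s / 60). Bins need not be pre-sorted.
    """
    rows = []
    walk = bins.loc[bins["label"] == WALKING]
    for ind, grp in walk.groupby("individual_id", sort=True):
        starts = np.sort(grp["start_s"].to_numpy(dtype=float))
        if len(starts) == 0:
            continue
        ends = starts + bin_s
        # a new visit starts where the gap since the previous bin's end > max_gap_s
        new_visit = np.concatenate([[True], starts[1:] - ends[:-1] > max_gap_s])
        visit_id = np.cumsum(new_visit)
        for _, vstarts in pd.Series(starts).groupby(visit_id):
            arr = vstarts.to_numpy()
            rows.append(
                {
                    "individual_id": ind,
                    "start_s": float(arr[0]),
                    "end_s": float(arr[-1] + bin_s),
                    "n_bins": len(arr),
                    "walking_minutes": len(arr) * bin_s / 60.0,
                }
            )
    return pd.DataFrame(
        rows, columns=["individual_id", "start_s", "end_s", "n_bins",
                       "walking_minutes"]
    )


def visit_rates(visits: pd.DataFrame, bins: pd.DataFrame,
                bin_s: int = BIN_S) -> pd.DataFrame:
    """Per-individual visit frequency and ground time per 24 h of record."""
    rows = []
    for ind, grp in bins.groupby("individual_id", sort=True):
        days = len(grp) * bin_s / 86400.0
        v = visits.loc[visits["individual_id"] == ind]
        rows.append(
            {
                "individual_id": ind,
                "recorded_days": days,
                "visits_per_day": len(v) / days if days else np.nan,
                "walking_min_per_day": v["walking_minutes"].sum() / days
                if days else np.nan,
                "minutes_per_visit": v["walking_minutes"].mean()
                if len(v) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def daily_budget(bins: pd.DataFrame, bin_s: int = BIN_S) -> pd.DataFrame:
    """Per (individual, day) behaviour budgets rescaled to 1440 min.

    Gap bins are excluded from recorded time; days with under an hour of
    coverage are dropped with a warning. Returns a long table with one row
    per (individual, date, category): raw minutes, percent of recorded
    time, and minutes rescaled to a full 1440 min day.
    """
    usable = bins.loc[~bins["is_gap"] & (bins["label"] != "")]
    rows = []
    dropped = 0
    for (ind, date), grp in usable.groupby(["individual_id", "date"], sort=True):
        recorded_min = len(grp) * bin_s / 60.0
        if recorded_min < MIN_RECORDED_MIN:
            dropped += 1
            continue
        counts = grp["label"].value_counts()
        cats = list(CATEGORIES) + [
            c for c in counts.index if c not in CATEGORIES
        ]
        for cat in cats:
            raw_min = counts.get(cat, 0) * bin_s / 60.0
            percent = 100.0 * raw_min / recorded_min
            rows.append(
                {
                    "individual_id": ind,
                    "date": date,
                    "category": cat,
                    "raw_minutes": raw_min,
                    "percent": percent,
                    "minutes": percent * 14.4,  # rescaled to 1440 min
                    "recorded_minutes": recorded_min,
                }
            )
    if dropped:
        warnings.warn(f"{dropped} day(s) with <1 h coverage excluded")
    return pd.DataFrame(rows)


def summarise_budgets(budgets: pd.DataFrame) -> pd.DataFrame:
    """Study-level budget summary: average within individuals across days,
    then across individuals (mean +/- SD per category)."""
    per_ind = (
        budgets.groupby(["category", "individual_id"], sort=True)[
            ["minutes", "percent"]
        ]
        .mean()
        .reset_index()
    )
    out = per_ind.groupby("category", sort=True).agg(
        minutes_mean=("minutes", "mean"),
        minutes_sd=("minutes", "std"),
        percent_mean=("percent", "mean"),
        percent_sd=("percent", "std"),
        n_individuals=("individual_id", "nunique"),
    )
    return out.reset_index()


def peak_hour(bins: pd.DataFrame, category: str) -> tuple[int, int] | None:
    """The clock hour with the maximum mean share of ``category``.

    Shares are computed per individual per hour (pooled across days), then
    averaged across individuals; ties resolve to the earlier hour. Requires
    at least 24 h of bins; returns ``None`` (with a warning) if the category
    never occurs.
    """
    usable = bins.loc[~bins["is_gap"] & (bins["label"] != "")]
    if len(usable) * BIN_S < 86400:
        raise ValueError("need at least 24 h of bins")
    if not (usable["label"] == category).any():
        warnings.warn(f"category {category!r} absent; peak hour undefined")
        return None
    share = (
        usable.assign(hit=usable["label"] == category)
        .groupby(["individual_id", "hour"], sort=True)["hit"]
        .mean()
        .groupby("hour")
        .mean()
    )
    share = share.reindex(range(24), fill_value=0.0)
    h = int(share.idxmax())  # idxmax takes the first (earliest) maximum
    return (h, h + 1)
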