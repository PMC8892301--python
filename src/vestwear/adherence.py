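"""42-day adherence profiles: days worn, weekly bins, runs, gaps and missingness.

A day counts as *worn* when its wear time reaches the policy's minimum
(default 1 h, the loosest value of the protocol's 1-16 h sensitivity range;
the full sweep is exposed via :func:`days_worn_sweep`). Participant-level
aggregates pool worn epochs across days (wear-time-weighted) rather than
averaging daily values, so days contribute in proportion to their evidence.

"Occasions of missing days" counts maximal gaps of non-worn days strictly
between the first and last worn day; never-worn leading/trailing tails are
not occasions (a participant who stops wearing the vest has one decision,
not one occasion per remaining day).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WearPolicy",
    "classify_day_worn",
    "days_worn",
    "days_worn_sweep",
    "weekly_category",
    "WEEKLY_CATEGORIES",
    "longest_consecutive_run",
    "missing_day_occasions",
    "attribute_missingness",
    "summarize_participant",
    "summarize_cohort",
    "PARTICIPANT_SUMMARY_COLUMNS",
]

WEEKLY_CATEGORIES = (">5", "4-5", "3-4", "2-3", "1-2", "<1")

PARTICIPANT_SUMMARY_COLUMNS = [
    "participant_id",
    "days_worn",
    "pct_protocol_worn",
    "weekly_category",
    "longest_consecutive_days",
    "missing_day_occasions",
    "any_battery_depletion",
    "mean_daily_wear_hours",
    "hr_signal_quality",
    "rr_signal_quality",
    "hr_data_quality",
    "rr_data_quality",
    "st_data_quality",
    "mean_hr",
    "mean_rr",
    "mean_st",
    "stationary_hours_per_day",
    "ambulatory_pct",
    "ambulatory_hours_per_day",
]


@dataclass(frozen=True)
class WearPolicy:
    """Minimum daily wear for a day to count as worn, and the protocol length."""

    min_daily_wear_hours: float = 1.0
    protocol_days: int = 42

    def __post_init__(self) -> None:
        if not 1.0 <= self.min_daily_wear_hours <= 16.0:
            raise ValueError("min_daily_wear_hours must be within [1, 16]")
        if self.protocol_days <= 0:
            raise ValueError("protocol_days must be positive")


_DEFAULT = WearPolicy()


def classify_day_worn(day, policy: WearPolicy = _DEFAULT) -> bool:
    """True iff the day's wear time meets the minimum (inclusive boundary)."""
    wear = day["wear_hours"] if not np.isscalar(day) else day
    return bool(wear >= policy.min_daily_wear_hours)


def worn_flags(days: pd.DataFrame, policy: WearPolicy = _DEFAULT) -> np.ndarray:
    """Boolean worn flag per protocol day, ordered by day_index (1..protocol_days).

    Days absent from ``days`` are non-worn.
    """
    flags = np.zeros(policy.protocol_days, dtype=bool)
    if len(days):
        idx = days["day_index"].to_numpy(int)
        keep = (idx >= 1) & (idx <= policy.protocol_days)
        worn = days["wear_hours"].to_numpy(float) >= policy.min_daily_wear_hours
        flags[idx[keep] - 1] = worn[keep]
    return flags


def days_worn(days: pd.DataFrame, policy: WearPolicy = _DEFAULT) -> int:
    """Number of protocol days deemed worn under the policy."""
    return int(worn_flags(days, policy).sum())


def days_worn_sweep(
    days: pd.DataFrame, thresholds_hours: Sequence[float] = tuple(range(1, 17)), protocol_days: int = 42
) -> pd.Series:
    """Days worn at each minimum-wear threshold (the 1-16 h sensitivity sweep)."""
    counts = {
        float(h): days_worn(days, WearPolicy(min_daily_wear_hours=float(h), protocol_days=protocol_days))
        for h in thresholds_hours
    }
    return pd.Series(counts, name="days_worn")


def weekly_category(days_worn_count: int, protocol_days: int = 42) -> str:
    """Weeks-worn bin for a days-worn count.

    Bins are lower-inclusive weeks: <1 -> [0,7), 1-2 -> [7,14), ..., 4-5 ->
    [28,35), >5 -> [35, protocol_days]. 35 days (= 5 weeks) is assigned to
    ">5" so the six labels partition 0..42.
    """
    if not 0 <= days_worn_count <= protocol_days:
        raise ValueError(f"days_worn {days_worn_count} outside [0, {protocol_days}]")
    if days_worn_count >= 35:
        return ">5"
    labels = ("<1", "1-2", "2-3", "3-4", "4-5")
    return labels[days_worn_count // 7]


def longest_consecutive_run(flags: Sequence[bool]) -> int:
    """Length of the longest maximal run of True flags."""
    best = cur = 0
    for f in flags:
        cur = cur + 1 if f else 0
        best = max(best, cur)
    return best


def missing_day_occasions(flags: Sequence[bool]) -> int:
    """Number of maximal non-worn gaps between the first and last worn day."""
    flags = np.asarray(flags, dtype=bool)
    if not flags.any():
        return 0
    worn_idx = np.flatnonzero(flags)
    inner = flags[worn_idx[0] : worn_idx[-1] + 1]
    # count False->(start of gap) transitions within the worn span
    starts = (~inner) & np.r_[True, inner[:-1]]
    return int(starts.sum())


def attribute_missingness(
    days: pd.DataFrame, policy: WearPolicy = _DEFAULT
) -> pd.DataFrame:
    """Per-day status: worn, nonwear, or battery_depletion.

    A non-worn day directly after a day whose recording ended battery-depleted
    while worn is attributed to battery depletion (the SEM was flat and not
    recharged); every other non-worn day is nonwear.
    """
    flags = worn_flags(days, policy)
    depleted = np.zeros(policy.protocol_days, dtype=bool)
    if len(days) and "battery_depleted" in days.columns:
        idx = days["day_index"].to_numpy(int)
        keep = (idx >= 1) & (idx <= policy.protocol_days)
        depleted[idx[keep] - 1] = days["battery_depleted"].to_numpy(bool)[keep]
    status = np.where(flags, "worn", "nonwear").astype(object)
    for d in range(1, policy.protocol_days):
        if not flags[d] and depleted[d - 1]:
            status[d] = "battery_depletion"
    return pd.DataFrame(
        {"day_index": np.arange(1, policy.protocol_days + 1), "status": status}
    )


def summarize_participant(
    days: pd.DataFrame, policy: WearPolicy = _DEFAULT, *, participant_id: str | None = None
) -> dict:
    """Pool a participant's daily summaries into the adherence profile.

    Signal/data qualities and vital signs are wear-time-weighted means over
    worn epochs of all days; per-day rates (wear hours, ambulatory hours) are
    averaged over worn days. With zero worn days every aggregate is NaN.
    """
    if participant_id is None:
        participant_id = str(days["participant_id"].iloc[0]) if len(days) else ""
    flags = worn_flags(days, policy)
    n_worn = int(flags.sum())

    row: dict = {
        "participant_id": participant_id,
        "days_worn": n_worn,
        "pct_protocol_worn": 100.0 * n_worn / policy.protocol_days,
        "weekly_category": weekly_category(n_worn, policy.protocol_days),
        "longest_consecutive_days": longest_consecutive_run(flags),
        "missing_day_occasions": missing_day_occasions(flags),
        "any_battery_depletion": bool(days["battery_depleted"].any()) if len(days) else False,
    }

    worn_days = days[
        (days["day_index"] >= 1)
        & (days["day_index"] <= policy.protocol_days)
        & (days["wear_hours"] >= policy.min_daily_wear_hours)
    ]
    agg_cols = [
        "hr_signal_quality",
        "rr_signal_quality",
        "hr_data_quality",
        "rr_data_quality",
        "st_data_quality",
        "mean_hr",
        "mean_rr",
        "mean_st",
        "ambulatory_pct",
    ]
    if len(worn_days) == 0:
        row["mean_daily_wear_hours"] = float("nan")
        for c in agg_cols:
            row[c] = float("nan")
        row["ambulatory_hours_per_day"] = float("nan")
        row["stationary_hours_per_day"] = float("nan")
    else:
        w = worn_days["wear_hours"].to_numpy(float)  # proportional to worn-epoch counts
        row["mean_daily_wear_hours"] = float(w.mean())
        for c in agg_cols:
            row[c] = float(np.average(worn_days[c].to_numpy(float), weights=w))
        row["ambulatory_hours_per_day"] = float(worn_days["ambulatory_hours"].mean())
        row["stationary_hours_per_day"] = row["mean_daily_wear_hours"] - row["ambulatory_hours_per_day"]
    return {k: row[k] for k in PARTICIPANT_SUMMARY_COLUMNS}


def summarize_cohort(daily: pd.DataFrame, policy: WearPolicy = _DEFAULT) -> pd.DataFrame:
    """Participant summaries for every participant present in ``daily``."""
    rows = [
        summarize_participant(g, policy, participant_id=str(pid))
        for pid, g in daily.groupby("participant_id", sort=True)
    ]
    return pd.DataFrame(rows, columns=PARTICIPANT_SUMMARY_COLUMNS)
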