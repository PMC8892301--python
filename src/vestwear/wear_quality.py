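"""Epoch- and day-level wear, signal-quality, data-quality and vital-sign metrics.

The on-body ("worn") criterion for a single epoch is strict: heart rate
> 25 beats/min AND skin temperature > 25 degrees C. Everything downstream is
defined over worn epochs only:

* **wear time** — worn-epoch count x epoch length;
* **signal quality** — mean device confidence over worn epochs (per channel);
* **data quality** — percentage of worn epochs whose confidence meets the
  channel's acceptance threshold (HR >= 85 %, RR >= 80 %; comparisons are
  inclusive);
* **skin-temperature data quality** — percentage of worn epochs where either
  channel's confidence is acceptable (the OR of the two validity sets, hence
  always >= each channel's own data quality);
* **vital-sign summaries** — mean HR/RR/ST over worn epochs, and the
  ambulatory percentage/hours of wear time.

Days are device-local calendar days (midnight to midnight); the wear protocol
is waking-hours only, so days do not straddle midnight. On a day with no worn
epochs the quality and vital-sign fields are undefined and reported as NaN,
never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .epoch_io import EpochRecord

__all__ = [
    "QualityThresholds",
    "classify_epoch_wear",
    "worn_mask",
    "daily_wear_time",
    "signal_quality",
    "data_quality",
    "st_data_quality",
    "vital_summaries",
    "summarize_day",
    "summarize_days",
    "DAILY_SUMMARY_COLUMNS",
]

DAILY_SUMMARY_COLUMNS = [
    "participant_id",
    "day_index",
    "date",
    "wear_hours",
    "hr_signal_quality",
    "rr_signal_quality",
    "hr_data_quality",
    "rr_data_quality",
    "st_data_quality",
    "mean_hr",
    "mean_rr",
    "mean_st",
    "ambulatory_pct",
    "ambulatory_hours",
    "battery_depleted",
]


@dataclass(frozen=True)
class QualityThresholds:
    """Wear and confidence-acceptance thresholds.

    Defaults follow the device manufacturer's recommendation: HR confidence
    acceptable at >= 85 %, RR at >= 80 %; an epoch counts as worn when
    HR > 25 beats/min and skin temperature > 25 C.
    """

    hr_conf_min: float = 85.0
    rr_conf_min: float = 80.0
    wear_hr_min: float = 25.0
    wear_st_min: float = 25.0
    epoch_seconds: float = 15.0

    def __post_init__(self) -> None:
        if not (0 < self.hr_conf_min <= 100 and 0 < self.rr_conf_min <= 100):
            raise ValueError("confidence thresholds must be in (0, 100]")
        if self.wear_hr_min <= 0 or self.wear_st_min <= 0 or self.epoch_seconds <= 0:
            raise ValueError("wear thresholds and epoch length must be positive")


_DEFAULT = QualityThresholds()


def classify_epoch_wear(
    epoch: EpochRecord | Mapping, thresholds: QualityThresholds = _DEFAULT
) -> bool:
    """True iff the epoch meets the on-body criterion (strict inequalities)."""
    hr = epoch.hr if isinstance(epoch, EpochRecord) else epoch["hr"]
    st = epoch.st if isinstance(epoch, EpochRecord) else epoch["st"]
    return bool(hr > thresholds.wear_hr_min and st > thresholds.wear_st_min)


def worn_mask(epochs: pd.DataFrame, thresholds: QualityThresholds = _DEFAULT) -> pd.Series:
    """Vectorized wear classification over an epoch DataFrame."""
    return (epochs["hr"] > thresholds.wear_hr_min) & (epochs["st"] > thresholds.wear_st_min)


def daily_wear_time(epochs: pd.DataFrame, thresholds: QualityThresholds = _DEFAULT) -> float:
    """Wear time in hours: worn-epoch count x epoch length. Empty day -> 0."""
    if len(epochs) == 0:
        return 0.0
    return float(worn_mask(epochs, thresholds).sum()) * thresholds.epoch_seconds / 3600.0


def _conf_col(channel: str) -> str:
    if channel not in ("hr", "rr"):
        raise ValueError(f"channel must be 'hr' or 'rr', got {channel!r}")
    return f"{channel}_conf"


def signal_quality(
    epochs: pd.DataFrame, channel: str, thresholds: QualityThresholds = _DEFAULT
) -> float:
    """Mean channel confidence over worn epochs; NaN when nothing was worn."""
    worn = epochs[worn_mask(epochs, thresholds)]
    if len(worn) == 0:
        return float("nan")
    return float(worn[_conf_col(channel)].mean())


def data_quality(
    epochs: pd.DataFrame, channel: str, thresholds: QualityThresholds = _DEFAULT
) -> float:
    """Percentage of worn epochs with channel confidence at or above threshold."""
    worn = epochs[worn_mask(epochs, thresholds)]
    if len(worn) == 0:
        return float("nan")
    thr = thresholds.hr_conf_min if channel == "hr" else thresholds.rr_conf_min
    return float(100.0 * (worn[_conf_col(channel)] >= thr).mean())


def st_data_quality(epochs: pd.DataFrame, thresholds: QualityThresholds = _DEFAULT) -> float:
    """Percentage of worn epochs where either channel's confidence is acceptable."""
    worn = epochs[worn_mask(epochs, thresholds)]
    if len(worn) == 0:
        return float("nan")
    ok = (worn["hr_conf"] >= thresholds.hr_conf_min) | (worn["rr_conf"] >= thresholds.rr_conf_min)
    return float(100.0 * ok.mean())


def vital_summaries(
    epochs: pd.DataFrame, thresholds: QualityThresholds = _DEFAULT
) -> dict[str, float]:
    """Worn-epoch vital-sign means and the ambulatory share of wear time."""
    worn = epochs[worn_mask(epochs, thresholds)]
    if len(worn) == 0:
        return {k: float("nan") for k in ("mean_hr", "mean_rr", "mean_st", "ambulatory_pct", "ambulatory_hours")}
    amb = worn["activity"].eq("ambulatory")
    return {
        "mean_hr": float(worn["hr"].mean()),
        "mean_rr": float(worn["rr"].mean()),
        "mean_st": float(worn["st"].mean()),
        "ambulatory_pct": float(100.0 * amb.mean()),
        "ambulatory_hours": float(amb.sum()) * thresholds.epoch_seconds / 3600.0,
    }


def _battery_depleted(epochs: pd.DataFrame, thresholds: QualityThresholds) -> bool:
    """Depletion flag: the day's final record was worn with battery <= 1 %.

    Operationalizes "flat SEM during wear": a stream that stops because the
    battery ran out ends mid-wear at an (almost) empty battery, whereas normal
    doffing ends with charge remaining.
    """
    if len(epochs) == 0:
        return False
    last = epochs.loc[epochs["timestamp"].idxmax()]
    return bool(classify_epoch_wear(last, thresholds) and last["battery"] <= 1.0)


def summarize_day(
    epochs: pd.DataFrame,
    thresholds: QualityThresholds = _DEFAULT,
    *,
    participant_id: str = "",
    day_index: int | None = None,
) -> dict:
    """All daily-summary fields for the epochs of one calendar day."""
    if len(epochs):
        days = pd.to_datetime(epochs["timestamp"]).dt.date.unique()
        if len(days) > 1:
            raise ValueError(f"epochs span multiple calendar days: {sorted(days)}")
        date = days[0]
    else:
        date = None
    row = {
        "participant_id": participant_id,
        "day_index": day_index,
        "date": date,
        "wear_hours": daily_wear_time(epochs, thresholds),
        "hr_signal_quality": signal_quality(epochs, "hr", thresholds),
        "rr_signal_quality": signal_quality(epochs, "rr", thresholds),
        "hr_data_quality": data_quality(epochs, "hr", thresholds),
        "rr_data_quality": data_quality(epochs, "rr", thresholds),
        "st_data_quality": st_data_quality(epochs, thresholds),
        "battery_depleted": _battery_depleted(epochs, thresholds),
    }
    row.update(vital_summaries(epochs, thresholds))
    return {k: row[k] for k in DAILY_SUMMARY_COLUMNS}


def summarize_days(
    epochs: pd.DataFrame,
    thresholds: QualityThresholds = _DEFAULT,
    *,
    participant_id: str = "",
    start_date=None,
    protocol_days: int | None = None,
) -> pd.DataFrame:
    """Daily summaries for one participant's full stream.

    Splits the stream on device-local calendar days. ``start_date`` anchors
    ``day_index`` = 1 (defaults to the first record's date); with
    ``protocol_days`` set, days without records are emitted explicitly with
    zero wear and NaN qualities, and records beyond the protocol are dropped.
    """
    epochs = epochs.sort_values("timestamp", kind="stable")
    ts = pd.to_datetime(epochs["timestamp"]) if len(epochs) else pd.Series(dtype="datetime64[ns]")
    dates = ts.dt.normalize()
    if start_date is None:
        if len(epochs) == 0:
            raise ValueError("empty stream needs an explicit start_date")
        start_date = dates.iloc[0]
    start_date = pd.Timestamp(start_date).normalize()

    if len(epochs):
        worn = worn_mask(epochs, thresholds).to_numpy()
        amb = epochs["activity"].eq("ambulatory").to_numpy() & worn
        hr_ok = (epochs["hr_conf"] >= thresholds.hr_conf_min).to_numpy() & worn
        rr_ok = (epochs["rr_conf"] >= thresholds.rr_conf_min).to_numpy() & worn
        work = pd.DataFrame(
            {
                "worn": worn.astype(float),
                "amb": amb.astype(float),
                "hr_ok": hr_ok.astype(float),
                "rr_ok": rr_ok.astype(float),
                "either_ok": (hr_ok | rr_ok).astype(float),
                "hr_sum": np.where(worn, epochs["hr"], 0.0),
                "rr_sum": np.where(worn, epochs["rr"], 0.0),
                "st_sum": np.where(worn, epochs["st"], 0.0),
                "hrc_sum": np.where(worn, epochs["hr_conf"], 0.0),
                "rrc_sum": np.where(worn, epochs["rr_conf"], 0.0),
                # last record of the day (stream is time-sorted)
                "last_worn": worn.astype(float),
                "last_battery": epochs["battery"].to_numpy(float),
            },
            index=dates.values,
        )
        agg = work.groupby(level=0).agg(
            {c: "sum" for c in work.columns[:-2]} | {"last_worn": "last", "last_battery": "last"}
        )
        n_worn = agg["worn"]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = pd.DataFrame(
                {
                    "participant_id": participant_id,
                    "day_index": (agg.index - start_date).days + 1,
                    "date": agg.index.date,
                    "wear_hours": n_worn * thresholds.epoch_seconds / 3600.0,
                    "hr_signal_quality": agg["hrc_sum"] / n_worn,
                    "rr_signal_quality": agg["rrc_sum"] / n_worn,
                    "hr_data_quality": 100.0 * agg["hr_ok"] / n_worn,
                    "rr_data_quality": 100.0 * agg["rr_ok"] / n_worn,
                    "st_data_quality": 100.0 * agg["either_ok"] / n_worn,
                    "mean_hr": agg["hr_sum"] / n_worn,
                    "mean_rr": agg["rr_sum"] / n_worn,
                    "mean_st": agg["st_sum"] / n_worn,
                    "ambulatory_pct": 100.0 * agg["amb"] / n_worn,
                    "ambulatory_hours": agg["amb"] * thresholds.epoch_seconds / 3600.0,
                    "battery_depleted": (agg["last_worn"] > 0) & (agg["last_battery"] <= 1.0),
                }
            ).reset_index(drop=True)
    else:
        out = pd.DataFrame(columns=DAILY_SUMMARY_COLUMNS)
    out = out[DAILY_SUMMARY_COLUMNS]

    if protocol_days is not None:
        out = out[(out["day_index"] >= 1) & (out["day_index"] <= protocol_days)]
        have = set(out["day_index"])
        fillers = []
        for idx in range(1, protocol_days + 1):
            if idx not in have:
                filler = summarize_day(
                    epochs.iloc[0:0], thresholds, participant_id=participant_id, day_index=idx
                )
                filler["date"] = (pd.Timestamp(start_date) + pd.Timedelta(days=idx - 1)).date()
                fillers.append(filler)
        if fillers:
            filler_df = pd.DataFrame(fillers, columns=DAILY_SUMMARY_COLUMNS)
            frames = [f for f in (out, filler_df) if len(f)]
            out = pd.concat(frames, ignore_index=True) if len(frames) > 1 else frames[0]
        out = out.sort_values("day_index", kind="stable").reset_index(drop=True)
    return out
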