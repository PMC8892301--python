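"""Reading, validation and writing of epoch streams and participant metadata.

The interchange formats are plain CSV:

* **Epoch CSV** — one row per 15-second device epoch, columns
  ``timestamp,hr,rr,st,hr_conf,rr_conf,activity,battery``. Timestamps are
  ISO-8601, device-local (no timezone arithmetic is ever performed: the
  analysis is day-of-wear based). ``activity`` is ``stationary`` or
  ``ambulatory``.
* **Metadata CSV** — one row per participant, columns
  ``participant_id,group,age,sex,bmi,chest_circumference_in,
  waist_circumference_cm,fev1_pct_pred,mrc_grade,oversized_vest``.

A *session* is a maximal run of contiguous epochs. The device records at a
fixed epoch length, so any inter-record gap larger than one epoch means the
device was off or not recording and starts a new session.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "EPOCH_COLUMNS",
    "META_COLUMNS",
    "ACTIVITY_LEVELS",
    "GROUPS",
    "EpochRecord",
    "ParticipantMeta",
    "EpochValidationError",
    "validate_epochs",
    "segment_sessions",
    "read_epoch_stream",
    "write_epoch_stream",
    "read_participant_meta",
    "write_participant_meta",
    "read_daily_summaries",
    "write_daily_summaries",
]

EPOCH_COLUMNS = ["timestamp", "hr", "rr", "st", "hr_conf", "rr_conf", "activity", "battery"]
META_COLUMNS = [
    "participant_id",
    "group",
    "age",
    "sex",
    "bmi",
    "chest_circumference_in",
    "waist_circumference_cm",
    "fev1_pct_pred",
    "mrc_grade",
    "oversized_vest",
]
ACTIVITY_LEVELS = ("stationary", "ambulatory")
GROUPS = ("AECOPD", "Stable")
SEXES = ("male", "female")
MRC_GRADES = (2, 3, 4, 5)

#: numeric daily-summary columns and the decimal precision they are written with
_SUMMARY_PRECISION = {
    "wear_hours": 4,
    "hr_signal_quality": 4,
    "rr_signal_quality": 4,
    "hr_data_quality": 4,
    "rr_data_quality": 4,
    "st_data_quality": 4,
    "mean_hr": 4,
    "mean_rr": 4,
    "mean_st": 4,
    "ambulatory_pct": 4,
    "ambulatory_hours": 4,
}


class EpochValidationError(ValueError):
    """Raised when an epoch or metadata file violates the documented dialect."""


@dataclass(frozen=True)
class EpochRecord:
    """One 15-second multiparameter sample.

    ``hr`` beats/min, ``rr`` breaths/min, ``st`` degrees C, confidences and
    battery in percent [0, 100].
    """

    timestamp: datetime
    hr: float
    rr: float
    st: float
    hr_conf: float
    rr_conf: float
    activity: str
    battery: float

    def __post_init__(self) -> None:
        for name in ("hr_conf", "rr_conf", "battery"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise EpochValidationError(f"{name}={v!r} outside [0, 100]")
        if self.hr < 0 or self.rr < 0:
            raise EpochValidationError("hr and rr must be non-negative")
        if self.activity not in ACTIVITY_LEVELS:
            raise EpochValidationError(f"unknown activity {self.activity!r}")


@dataclass(frozen=True)
class ParticipantMeta:
    """Demographic and clinical covariates for one participant."""

    participant_id: str
    group: str
    age: float
    sex: str
    bmi: float
    chest_circumference_in: float
    waist_circumference_cm: float
    fev1_pct_pred: float
    mrc_grade: int
    oversized_vest: bool

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise EpochValidationError(
                f"group {self.group!r} not one of {GROUPS} for {self.participant_id}"
            )
        if self.sex not in SEXES:
            raise EpochValidationError(f"sex {self.sex!r} not one of {SEXES}")
        if int(self.mrc_grade) not in MRC_GRADES:
            raise EpochValidationError(
                f"mrc_grade {self.mrc_grade!r} not in {MRC_GRADES} for {self.participant_id}"
            )


def validate_epochs(df: pd.DataFrame, *, source: str = "<epochs>") -> pd.DataFrame:
    """Validate an epoch DataFrame against the dialect, raising with row numbers.

    Row numbers in error messages are 1-based file line numbers (header = line 1).
    """
    missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
    if missing:
        raise EpochValidationError(f"{source}: missing columns {missing}")

    def _bad_lines(mask: pd.Series) -> str:
        lines = (np.flatnonzero(mask.to_numpy()) + 2).tolist()  # +1 header, +1 one-based
        return ", ".join(map(str, lines[:5])) + ("…" if len(lines) > 5 else "")

    for col in ("hr_conf", "rr_conf", "battery"):
        bad = (df[col] < 0) | (df[col] > 100) | df[col].isna()
        if bad.any():
            raise EpochValidationError(
                f"{source}: {col} outside [0, 100] at line(s) {_bad_lines(bad)}"
            )
    for col in ("hr", "rr"):
        bad = (df[col] < 0) | df[col].isna()
        if bad.any():
            raise EpochValidationError(f"{source}: negative {col} at line(s) {_bad_lines(bad)}")
    bad = ~df["activity"].isin(ACTIVITY_LEVELS)
    if bad.any():
        raise EpochValidationError(
            f"{source}: unknown activity at line(s) {_bad_lines(bad)}"
        )
    return df


def segment_sessions(df: pd.DataFrame, epoch_seconds: float = 15.0) -> pd.DataFrame:
    """Sort by timestamp and assign a ``session`` id.

    A new session starts wherever the gap to the previous record exceeds one
    epoch length. Idempotent: re-segmenting segmented output is a no-op.
    """
    out = df.sort_values("timestamp", kind="stable").reset_index(drop=True)
    if len(out) == 0:
        out["session"] = pd.Series(dtype=int)
        return out
    gaps = out["timestamp"].diff().dt.total_seconds()
    out["session"] = (gaps > epoch_seconds).fillna(False).cumsum().astype(int)
    return out


def read_epoch_stream(path: str | Path, epoch_seconds: float = 15.0) -> pd.DataFrame:
    """Read an epoch CSV, validate it, and segment it into sessions.

    Returns a DataFrame with the dialect columns plus a ``session`` integer
    column; rows are sorted by timestamp.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, parse_dates=["timestamp"])
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise EpochValidationError(f"{path}: malformed CSV ({exc})") from exc
    validate_epochs(df, source=str(path))
    return segment_sessions(df[EPOCH_COLUMNS], epoch_seconds=epoch_seconds)


def write_epoch_stream(df: pd.DataFrame, path: str | Path) -> None:
    """Write an epoch DataFrame in the documented dialect."""
    out = df[EPOCH_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise EpochValidationError(f"cannot parse boolean {v!r}")


def read_participant_meta(path: str | Path) -> list[ParticipantMeta]:
    """Read the metadata CSV into a list of validated :class:`ParticipantMeta`."""
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise EpochValidationError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        return []
    dup = df["participant_id"].astype(str).duplicated()
    if dup.any():
        dupes = df.loc[dup, "participant_id"].unique().tolist()
        raise EpochValidationError(f"{path}: duplicate participant_id(s) {dupes}")
    metas = []
    for row in df.itertuples(index=False):
        metas.append(
            ParticipantMeta(
                participant_id=str(row.participant_id),
                group=str(row.group),
                age=float(row.age),
                sex=str(row.sex),
                bmi=float(row.bmi),
                chest_circumference_in=float(row.chest_circumference_in),
                waist_circumference_cm=float(row.waist_circumference_cm),
                fev1_pct_pred=float(row.fev1_pct_pred),
                mrc_grade=int(row.mrc_grade),
                oversized_vest=_parse_bool(row.oversized_vest),
            )
        )
    return metas


def write_participant_meta(metas: Iterable[ParticipantMeta], path: str | Path) -> None:
    df = meta_frame(metas)
    df.to_csv(path, index=False)


def meta_frame(metas: Iterable[ParticipantMeta]) -> pd.DataFrame:
    """Participant metadata as a DataFrame in dialect column order."""
    rows = [
        {
            "participant_id": m.participant_id,
            "group": m.group,
            "age": m.age,
            "sex": m.sex,
            "bmi": m.bmi,
            "chest_circumference_in": m.chest_circumference_in,
            "waist_circumference_cm": m.waist_circumference_cm,
            "fev1_pct_pred": m.fev1_pct_pred,
            "mrc_grade": m.mrc_grade,
            "oversized_vest": m.oversized_vest,
        }
        for m in metas
    ]
    return pd.DataFrame(rows, columns=META_COLUMNS)


def write_daily_summaries(summaries: pd.DataFrame, path: str | Path) -> None:
    """Write daily summaries so that a read round-trips to declared precision.

    Numeric aggregates are serialized with 4 decimal places; an empty frame
    yields a header-only file.
    """
    out = summaries.copy()
    for col, ndig in _SUMMARY_PRECISION.items():
        if col in out.columns:
            out[col] = out[col].round(ndig)
    out.to_csv(path, index=False)


def read_daily_summaries(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"]).dt.date
    if "battery_depleted" in df.columns and len(df):
        df["battery_depleted"] = df["battery_depleted"].astype(bool)
    return df
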