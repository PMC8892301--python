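"""Synthetic free-living cohort generator for chest-worn vital-sign monitors.

Emulates a two-group COPD monitoring study — a post-exacerbation (AECOPD)
group and a Stable group — wearing a chest vest during waking hours for a
42-day protocol at 15-second epochs. The raw device data of such studies are
rarely shared, so this generator provides streams with the same statistical
skeleton so that every downstream stage (wear detection, quality metrics,
adherence, group statistics) is testable end to end.

Generative model, per participant:

* **Schedule.** Each protocol day is either missing (device not worn at all;
  per-participant propensity drawn from a group-specific Beta distribution so
  the cohort shows the heavy-tailed adherence seen in practice) or contains a
  single wear episode of ~N(12, sd) hours placed uniformly inside the waking
  window. Non-wear is absence of records: the device off the body records
  nothing. An optional off-body mode appends powered-but-doffed records
  (low HR, ambient skin temperature) to exercise the wear classifier.
* **Vitals.** HR = participant baseline + 24-h circadian sinusoid +
  ambulatory elevation + white noise; RR and skin temperature analogous
  (no circadian term). Baselines vary between participants; the baseline is
  calibrated so the expected wear-epoch mean equals ``hr_mean`` despite the
  circadian and activity terms.
* **Confidence.** Device confidence per channel = channel base + a linear
  BMI effect + a participant-level offset + epoch noise, clipped to [0, 100].
  The BMI effect is regime-specific: in the Stable-like regime HR confidence
  rises with BMI (better electrode contact); in the AECOPD-like regime RR
  confidence falls with adiposity.
* **Battery.** Charge decays linearly while recording. On a rare depletion
  day the module starts part-charged and the stream truncates mid-wear with
  the final epoch at <=1 % battery; the following day is missing because the
  flat module was not recharged.

Every realized quantity is recorded in a per-day truth table
(``worn`` / ``nonwear`` / ``battery_depletion``, true wear hours) for
parameter-recovery tests. Identical ``(params, seed)`` give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .epoch_io import (
    EPOCH_COLUMNS,
    ParticipantMeta,
    meta_frame,
    write_epoch_stream,
    write_participant_meta,
)

__all__ = ["SimParams", "simulate_participant", "simulate_cohort", "iter_cohort", "CohortData"]

TRUTH_COLUMNS = ["participant_id", "day_index", "status", "true_wear_hours", "battery_depleted"]


@dataclass(frozen=True)
class SimParams:
    """All tunable knobs of the generator (defaults = the emulated study).

    Group sizes, BMI distributions, ambulatory fractions and missing-day
    propensities are group-specific; the ``*_aecopd`` fields override the
    base value for the post-exacerbation group.
    """

    # cohort composition
    n_aecopd: int = 35
    n_stable: int = 49
    protocol_days: int = 42
    epoch_seconds: float = 15.0
    start_date: str = "2019-01-01"

    # wear schedule (hours, clock hours)
    wear_start_hour: float = 7.0
    wear_end_hour: float = 22.0
    daily_wear_mean: float = 12.0
    daily_wear_sd: float = 1.0          # within-participant, day to day
    daily_wear_between_sd: float = 1.8  # between participants
    p_missing_day: float = 0.12         # Stable-regime mean propensity
    p_missing_day_aecopd: float = 0.24
    missing_concentration: float = 3.0  # Beta concentration of the propensity
    p_battery_depletion_day: float = 0.0015
    offbody_hours_per_day: float = 0.0  # powered-but-doffed records after wear

    # vitals
    hr_mean: float = 84.0
    hr_sd: float = 10.0                 # between participants
    hr_within_sd: float = 3.0           # epoch noise
    rr_mean: float = 20.0
    rr_sd: float = 3.0
    rr_within_sd: float = 1.5
    st_mean: float = 34.2
    st_sd: float = 0.9
    st_within_sd: float = 0.3
    ambulatory_fraction: float = 0.135  # Stable regime, share of wear epochs
    ambulatory_fraction_aecopd: float = 0.10
    ambulatory_concentration: float = 40.0  # Beta concentration of the fraction
    ambulatory_hr_boost: float = 15.0
    ambulatory_rr_boost: float = 2.0
    circadian_amplitude: float = 2.0
    circadian_peak_hour: float = 16.0

    # device confidence
    conf_base_hr: float = 92.0
    conf_base_rr: float = 88.0
    conf_bmi_slope_hr: float = 0.5      # %/(kg/m^2), Stable-like regime
    conf_adiposity_slope_rr: float = -0.5  # %/(kg/m^2), AECOPD-like regime
    conf_noise_sd: float = 8.0          # epoch noise
    conf_participant_sd: float = 5.0    # participant-level offset
    bmi_reference: float = 26.8         # centering for the BMI effect

    # battery
    battery_start: float = 100.0
    battery_rate_per_hour: float = 6.0

    # baseline characteristics (group means/SDs)
    bmi_mean_aecopd: float = 25.2
    bmi_sd_aecopd: float = 6.0
    bmi_mean_stable: float = 28.0
    bmi_sd_stable: float = 6.7
    age_mean: float = 67.0
    age_sd: float = 9.4
    p_male: float = 0.55
    fev1_mean_aecopd: float = 44.8
    fev1_sd_aecopd: float = 22.3
    fev1_mean_stable: float = 53.5
    fev1_sd_stable: float = 27.4
    mrc_probs_aecopd: tuple = (8 / 35, 5 / 35, 14 / 35, 8 / 35)  # grades 2..5
    mrc_probs_stable: tuple = (15 / 49, 17 / 49, 16 / 49, 1 / 49)
    p_oversized_vest: float = 0.40

    def __post_init__(self) -> None:
        for name in (
            "p_missing_day",
            "p_missing_day_aecopd",
            "p_battery_depletion_day",
            "ambulatory_fraction",
            "ambulatory_fraction_aecopd",
            "p_male",
            "p_oversized_vest",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        for name in (
            "daily_wear_sd",
            "daily_wear_between_sd",
            "hr_sd",
            "hr_within_sd",
            "rr_sd",
            "rr_within_sd",
            "st_sd",
            "st_within_sd",
            "conf_noise_sd",
            "conf_participant_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.protocol_days <= 0:
            raise ValueError("protocol_days must be positive")
        if not (0 <= self.wear_start_hour < self.wear_end_hour <= 24):
            raise ValueError("wear window must satisfy 0 <= start < end <= 24")
        if self.daily_wear_mean > self.wear_end_hour - self.wear_start_hour:
            raise ValueError("daily_wear_mean does not fit in the wear window")


def _group_value(params: SimParams, group: str, base: str, aecopd: str) -> float:
    return getattr(params, aecopd) if group == "AECOPD" else getattr(params, base)


def _circadian(params: SimParams, t_hours: np.ndarray) -> np.ndarray:
    return params.circadian_amplitude * np.cos(
        2 * np.pi * (t_hours - params.circadian_peak_hour) / 24.0
    )


def _circadian_window_mean(params: SimParams) -> float:
    """Expected circadian term over a typical wear episode (numeric).

    Averages over episode start offsets (uniform in the window) and epoch
    positions within an episode of the mean wear duration. Used to calibrate
    baselines so wear-epoch HR has expectation ``hr_mean``.
    """
    window = params.wear_end_hour - params.wear_start_hour
    dur = min(params.daily_wear_mean, window)
    starts = params.wear_start_hour + np.linspace(0, window - dur, 101)
    offs = np.linspace(0, dur, 201)
    t = starts[:, None] + offs[None, :]
    return float(_circadian(params, t).mean())


def _wear_epoch_bias(params: SimParams, group: str, channel: str) -> float:
    """Expected offset of wear-epoch means above the participant baseline."""
    amb = _group_value(params, group, "ambulatory_fraction", "ambulatory_fraction_aecopd")
    if channel == "hr":
        return amb * params.ambulatory_hr_boost + _circadian_window_mean(params)
    if channel == "rr":
        return amb * params.ambulatory_rr_boost
    return 0.0


def simulate_participant(
    meta: ParticipantMeta, params: SimParams, seed
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one participant's epoch stream and per-day truth table.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`. Identical
    inputs give byte-identical outputs.
    """
    rng = np.random.default_rng(seed)
    eps = params.epoch_seconds
    window = params.wear_end_hour - params.wear_start_hour
    start = pd.Timestamp(params.start_date)

    amb_frac = _group_value(params, meta.group, "ambulatory_fraction", "ambulatory_fraction_aecopd")
    p_miss_mean = _group_value(params, meta.group, "p_missing_day", "p_missing_day_aecopd")
    slope_hr = params.conf_bmi_slope_hr if meta.group == "Stable" else 0.0
    slope_rr = params.conf_adiposity_slope_rr if meta.group == "AECOPD" else 0.0

    # participant-level latents (drawn in a fixed order for determinism)
    wear_mean_i = rng.normal(params.daily_wear_mean, params.daily_wear_between_sd)
    wear_mean_i = float(np.clip(wear_mean_i, 2.0, window))
    hr_base_i = rng.normal(params.hr_mean - _wear_epoch_bias(params, meta.group, "hr"), params.hr_sd)
    rr_base_i = rng.normal(params.rr_mean - _wear_epoch_bias(params, meta.group, "rr"), params.rr_sd)
    st_base_i = rng.normal(params.st_mean, params.st_sd)
    conf_off_hr_i = rng.normal(0.0, params.conf_participant_sd)
    conf_off_rr_i = rng.normal(0.0, params.conf_participant_sd)
    if p_miss_mean <= 0.0:
        p_miss_i = 0.0
    else:
        k = params.missing_concentration
        p_miss_i = float(rng.beta(p_miss_mean * k, (1.0 - p_miss_mean) * k))
    if 0.0 < amb_frac < 1.0:
        ka = params.ambulatory_concentration
        amb_frac = float(rng.beta(amb_frac * ka, (1.0 - amb_frac) * ka))

    frames: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    dead_next_day = False
    for day in range(params.protocol_days):
        day_start = start + pd.Timedelta(days=day)
        if dead_next_day:
            dead_next_day = False
            rng.random()  # keep the per-day draw count stable
            truth_rows.append(
                dict(
                    participant_id=meta.participant_id,
                    day_index=day + 1,
                    status="battery_depletion",
                    true_wear_hours=0.0,
                    battery_depleted=False,
                )
            )
            continue
        if rng.random() < p_miss_i:
            truth_rows.append(
                dict(
                    participant_id=meta.participant_id,
                    day_index=day + 1,
                    status="nonwear",
                    true_wear_hours=0.0,
                    battery_depleted=False,
                )
            )
            continue

        wear_hours = float(
            np.clip(rng.normal(wear_mean_i, params.daily_wear_sd), 1.0, window)
        )
        ep_start_hour = params.wear_start_hour + rng.uniform(0, window - wear_hours)
        # whole-second episode start so CSV round-trips are exact
        ep_start_hour = round(ep_start_hour * 3600.0) / 3600.0
        n_ep = max(1, round(wear_hours * 3600.0 / eps))

        depletion_day = rng.random() < params.p_battery_depletion_day
        if depletion_day:
            battery0 = params.battery_rate_per_hour * wear_hours * rng.uniform(0.4, 0.9)
        else:
            battery0 = params.battery_start
        t_h = np.arange(n_ep) * eps / 3600.0
        battery = battery0 - params.battery_rate_per_hour * t_h
        keep = battery > 0
        n_ep = int(keep.sum())
        battery = np.clip(battery[:n_ep], 0.0, 100.0)
        t_h = t_h[:n_ep]
        truncated = depletion_day and n_ep < len(keep)

        clock = ep_start_hour + t_h
        amb = rng.random(n_ep) < amb_frac
        hr = (
            hr_base_i
            + _circadian(params, clock)
            + params.ambulatory_hr_boost * amb
            + rng.normal(0.0, params.hr_within_sd, n_ep)
        )
        rr = rr_base_i + params.ambulatory_rr_boost * amb + rng.normal(0.0, params.rr_within_sd, n_ep)
        st = st_base_i + rng.normal(0.0, params.st_within_sd, n_ep)
        hr_conf = (
            params.conf_base_hr
            + slope_hr * (meta.bmi - params.bmi_reference)
            + conf_off_hr_i
            + rng.normal(0.0, params.conf_noise_sd, n_ep)
        )
        rr_conf = (
            params.conf_base_rr
            + slope_rr * (meta.bmi - params.bmi_reference)
            + conf_off_rr_i
            + rng.normal(0.0, params.conf_noise_sd, n_ep)
        )

        day_df = pd.DataFrame(
            {
                "timestamp": day_start + pd.to_timedelta((clock * 3600.0).round(6), unit="s"),
                "hr": np.clip(hr, 0.0, None),
                "rr": np.clip(rr, 0.0, None),
                "st": st,
                "hr_conf": np.clip(hr_conf, 0.0, 100.0),
                "rr_conf": np.clip(rr_conf, 0.0, 100.0),
                "activity": np.where(amb, "ambulatory", "stationary"),
                "battery": battery,
            }
        )

        if params.offbody_hours_per_day > 0 and not truncated:
            n_off = max(1, round(params.offbody_hours_per_day * 3600.0 / eps))
            off_clock = clock[-1] + eps / 3600.0 + np.arange(n_off) * eps / 3600.0
            off_clock = off_clock[off_clock < 24.0]
            n_off = len(off_clock)
            if n_off:
                off_df = pd.DataFrame(
                    {
                        "timestamp": day_start
                        + pd.to_timedelta((off_clock * 3600.0).round(6), unit="s"),
                        "hr": rng.uniform(0.0, 20.0, n_off),
                        "rr": rng.uniform(0.0, 5.0, n_off),
                        "st": rng.normal(22.0, 1.0, n_off),
                        "hr_conf": rng.uniform(0.0, 40.0, n_off),
                        "rr_conf": rng.uniform(0.0, 40.0, n_off),
                        "activity": "stationary",
                        "battery": np.clip(
                            battery[-1] - params.battery_rate_per_hour * (off_clock - clock[-1]),
                            0.0,
                            100.0,
                        ),
                    }
                )
                day_df = pd.concat([day_df, off_df], ignore_index=True)

        frames.append(day_df)
        truth_rows.append(
            dict(
                participant_id=meta.participant_id,
                day_index=day + 1,
                status="worn",
                true_wear_hours=n_ep * eps / 3600.0,
                battery_depleted=bool(truncated),
            )
        )
        if truncated:
            dead_next_day = True

    if frames:
        epochs = pd.concat(frames, ignore_index=True)[EPOCH_COLUMNS]
    else:
        epochs = pd.DataFrame(columns=EPOCH_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return epochs, truth


def _simulate_meta(params: SimParams, rng: np.random.Generator) -> list[ParticipantMeta]:
    metas = []
    specs = [("AECOPD", "A", params.n_aecopd), ("Stable", "S", params.n_stable)]
    for group, prefix, n in specs:
        if group == "AECOPD":
            bmi_mu, bmi_sd = params.bmi_mean_aecopd, params.bmi_sd_aecopd
            fev_mu, fev_sd = params.fev1_mean_aecopd, params.fev1_sd_aecopd
            mrc_probs = params.mrc_probs_aecopd
        else:
            bmi_mu, bmi_sd = params.bmi_mean_stable, params.bmi_sd_stable
            fev_mu, fev_sd = params.fev1_mean_stable, params.fev1_sd_stable
            mrc_probs = params.mrc_probs_stable
        for i in range(n):
            bmi = float(np.clip(rng.normal(bmi_mu, bmi_sd), 15.0, 45.0))
            metas.append(
                ParticipantMeta(
                    participant_id=f"{prefix}{i + 1:02d}",
                    group=group,
                    age=float(np.clip(rng.normal(params.age_mean, params.age_sd), 40.0, 90.0)),
                    sex="male" if rng.random() < params.p_male else "female",
                    bmi=bmi,
                    chest_circumference_in=float(0.55 * bmi + 24.0 + rng.normal(0.0, 2.5)),
                    waist_circumference_cm=float(2.0 * bmi + 43.6 + rng.normal(0.0, 7.0)),
                    fev1_pct_pred=float(np.clip(rng.normal(fev_mu, fev_sd), 15.0, 120.0)),
                    mrc_grade=int(rng.choice([2, 3, 4, 5], p=np.asarray(mrc_probs) / sum(mrc_probs))),
                    oversized_vest=bool(rng.random() < params.p_oversized_vest),
                )
            )
    return metas


def iter_cohort(params: SimParams, seed: int):
    """Yield ``(meta, epochs, truth)`` per participant without holding the cohort.

    Per-participant seeds are spawned from the master seed, so any single
    participant can be regenerated independently and the full cohort is
    deterministic.
    """
    if params.n_aecopd <= 0 or params.n_stable <= 0:
        raise ValueError("both group sizes must be positive")
    ss = np.random.SeedSequence(seed)
    meta_ss, stream_ss = ss.spawn(2)
    metas = _simulate_meta(params, np.random.default_rng(meta_ss))
    for meta, child in zip(metas, stream_ss.spawn(len(metas))):
        epochs, truth = simulate_participant(meta, params, child)
        yield meta, epochs, truth


@dataclass
class CohortData:
    """A fully materialized synthetic cohort."""

    params: SimParams
    seed: int
    metas: list[ParticipantMeta]
    streams: dict[str, pd.DataFrame]
    truth: pd.DataFrame

    @property
    def meta_frame(self) -> pd.DataFrame:
        return meta_frame(self.metas)

    def write(self, out_dir: str | Path) -> None:
        """Emit the epoch/metadata CSV dialects plus the truth sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_participant_meta(self.metas, out / "participants.csv")
        self.truth.to_csv(out / "truth.csv", index=False)
        streams = out / "streams"
        streams.mkdir(exist_ok=True)
        for pid, df in self.streams.items():
            write_epoch_stream(df, streams / f"{pid}.csv")


def simulate_cohort(params: SimParams, seed: int = 0) -> CohortData:
    """Materialize the whole cohort (use :func:`iter_cohort` for big runs)."""
    metas, streams, truths = [], {}, []
    for meta, epochs, truth in iter_cohort(params, seed):
        metas.append(meta)
        streams[meta.participant_id] = epochs
        truths.append(truth)
    truth = pd.concat(truths, ignore_index=True) if truths else pd.DataFrame(columns=TRUTH_COLUMNS)
    return CohortData(params=params, seed=seed, metas=metas, streams=streams, truth=truth)
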