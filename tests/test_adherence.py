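import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vestwear.adherence import (
    WearPolicy,
    attribute_missingness,
    classify_day_worn,
    days_worn,
    days_worn_sweep,
    longest_consecutive_run,
    missing_day_occasions,
    summarize_participant,
    weekly_category,
    WEEKLY_CATEGORIES,
)
from vestwear.wear_quality import summarize_days

from conftest import make_epochs


def brute_longest_run(flags):
    """Exhaustive scan: longest window of all-True flags."""
    best = 0
    for i in range(len(flags)):
        for j in range(i, len(flags)):
            if all(flags[i : j + 1]):
                best = max(best, j - i + 1)
    return best


def brute_gap_count(flags):
    """Count internal maximal False runs between first and last True."""
    worn_idx = [i for i, f in enumerate(flags) if f]
    if not worn_idx:
        return 0
    inner = flags[worn_idx[0] : worn_idx[-1] + 1]
    count, in_gap = 0, False
    for f in inner:
        if not f and not in_gap:
            count += 1
        in_gap = not f
    return count


def daily_frame(wear_hours, depleted=None):
    n = len(wear_hours)
    return pd.DataFrame(
        {
            "participant_id": "P",
            "day_index": np.arange(1, n + 1),
            "date": pd.date_range("2019-01-01", periods=n).date,
            "wear_hours": wear_hours,
            "hr_signal_quality": 90.0,
            "rr_signal_quality": 90.0,
            "hr_data_quality": 80.0,
            "rr_data_quality": 80.0,
            "st_data_quality": 95.0,
            "mean_hr": 84.0,
            "mean_rr": 20.0,
            "mean_st": 34.0,
            "ambulatory_pct": 10.0,
            "ambulatory_hours": [h * 0.1 for h in wear_hours],
            "battery_depleted": depleted if depleted is not None else [False] * n,
        }
    )


class TestDayClassification:
    @pytest.mark.parametrize(
        "wear,threshold,worn",
        [(12.0, 8.0, True), (0.5, 1.0, False), (1.0, 1.0, True)],  # boundary inclusive
    )
    def test_minimum_wear_rule(self, wear, threshold, worn):
        policy = WearPolicy(min_daily_wear_hours=threshold)
        assert classify_day_worn({"wear_hours": wear}, policy) is worn

    def test_policy_bounds(self):
        with pytest.raises(ValueError):
            WearPolicy(min_daily_wear_hours=0.5)
        with pytest.raises(ValueError):
            WearPolicy(min_daily_wear_hours=17)


class TestDaysWorn:
    def test_all_and_none(self):
        policy = WearPolicy(protocol_days=42)
        assert days_worn(daily_frame([12.0] * 42), policy) == 42
        assert days_worn(daily_frame([]), policy) == 0

    def test_sweep_monotone_on_cohort(self, small_cohort):
        for pid, stream in small_cohort.streams.items():
            daily = summarize_days(
                stream,
                participant_id=pid,
                start_date=small_cohort.params.start_date,
                protocol_days=small_cohort.params.protocol_days,
            )
            counts = days_worn_sweep(
                daily, protocol_days=small_cohort.params.protocol_days
            ).to_numpy()
            assert (np.diff(counts) <= 0).all()


class TestWeeklyCategory:
    @pytest.mark.parametrize(
        "days,category",
        [(38, ">5"), (0, "<1"), (35, ">5"), (34, "4-5"), (7, "1-2"), (6, "<1"), (42, ">5")],
    )
    def test_bin_assignment(self, days, category):
        assert weekly_category(days) == category

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            weekly_category(43)
        with pytest.raises(ValueError):
            weekly_category(-1)

    def test_bins_partition_all_counts(self):
        cats = {weekly_category(d) for d in range(43)}
        assert cats == set(WEEKLY_CATEGORIES)


class TestRunsAndGaps:
    @pytest.mark.parametrize(
        "flags,expected",
        [([True, True, False, True, True, True], 3), ([False] * 5, 0), ([True], 1)],
    )
    def test_longest_run_examples(self, flags, expected):
        assert longest_consecutive_run(flags) == expected

    @pytest.mark.parametrize(
        "flags,expected",
        [
            ([True, False, False, True, False, True], 2),
            ([True] * 6, 0),
            ([False, False, True, True, False, True, False, False], 1),
            ([False] * 4, 0),
        ],
    )
    def test_gap_count_examples(self, flags, expected):
        assert missing_day_occasions(flags) == expected

    @given(st.lists(st.booleans(), min_size=0, max_size=60))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_match_brute_force(self, flags):
        assert longest_consecutive_run(flags) == brute_longest_run(flags)
        assert missing_day_occasions(flags) == brute_gap_count(flags)


class TestMissingnessAttribution:
    def test_day_after_depletion_attributed(self):
        daily = daily_frame([12, 8, 0, 12], depleted=[False, True, False, False])
        policy = WearPolicy(protocol_days=4)
        status = attribute_missingness(daily, policy)["status"].tolist()
        assert status == ["worn", "worn", "battery_depletion", "worn"]

    def test_ordinary_gap_is_nonwear(self):
        daily = daily_frame([12, 12, 0, 12], depleted=[False] * 4)
        policy = WearPolicy(protocol_days=4)
        status = attribute_missingness(daily, policy)["status"].tolist()
        assert status == ["worn", "worn", "nonwear", "worn"]

    def test_simulated_truth_recovered(self, small_cohort):
        policy = WearPolicy(protocol_days=small_cohort.params.protocol_days)
        agree = total = 0
        for meta in small_cohort.metas:
            pid = meta.participant_id
            daily = summarize_days(
                small_cohort.streams[pid],
                participant_id=pid,
                start_date=small_cohort.params.start_date,
                protocol_days=policy.protocol_days,
            )
            got = attribute_missingness(daily, policy)["status"]
            truth = small_cohort.truth.query("participant_id == @pid").sort_values("day_index")
            total += len(truth)
            agree += (got.to_numpy() == truth["status"].to_numpy()).sum()
        assert agree / total >= 0.99


class TestParticipantSummary:
    def test_single_perfect_day(self):
        daily = daily_frame([12.0])
        out = summarize_participant(daily, WearPolicy(protocol_days=42))
        assert out["mean_daily_wear_hours"] == pytest.approx(12.0)
        assert out["pct_protocol_worn"] == pytest.approx(100.0 / 42)
        assert out["days_worn"] == 1

    def test_zero_days_all_null(self):
        out = summarize_participant(daily_frame([]), WearPolicy(protocol_days=42),
                                    participant_id="P")
        assert out["days_worn"] == 0
        assert math.isnan(out["mean_daily_wear_hours"])
        assert math.isnan(out["hr_signal_quality"])
        assert out["weekly_category"] == "<1"

    def test_pooled_quality_matches_flat_epoch_oracle(self, small_cohort):
        from vestwear.wear_quality import worn_mask

        pid = "S03"
        stream = small_cohort.streams[pid]
        policy = WearPolicy(protocol_days=small_cohort.params.protocol_days)
        daily = summarize_days(
            stream,
            participant_id=pid,
            start_date=small_cohort.params.start_date,
            protocol_days=policy.protocol_days,
        )
        out = summarize_participant(daily, policy)
        # independent flat pass over all worn epochs of worn days
        dates = pd.to_datetime(stream["timestamp"]).dt.date
        worn_dates = set(daily.loc[daily["wear_hours"] >= 1.0, "date"])
        pool = stream[[d in worn_dates for d in dates]]
        pool = pool[worn_mask(pool)]
        assert out["hr_signal_quality"] == pytest.approx(pool["hr_conf"].mean())
        assert out["rr_data_quality"] == pytest.approx(100 * (pool["rr_conf"] >= 80).mean())
        assert out["mean_hr"] == pytest.approx(pool["hr"].mean())
        assert out["ambulatory_pct"] == pytest.approx(
            100 * pool["activity"].eq("ambulatory").mean()
        )
        assert out["stationary_hours_per_day"] == pytest.approx(
            out["mean_daily_wear_hours"] - out["ambulatory_hours_per_day"]
        )

    def test_longest_run_bounded_by_days_worn(self, small_cohort):
        policy = WearPolicy(protocol_days=small_cohort.params.protocol_days)
        for pid, stream in small_cohort.streams.items():
            daily = summarize_days(
                stream, participant_id=pid,
                start_date=small_cohort.params.start_date,
                protocol_days=policy.protocol_days,
            )
            out = summarize_participant(daily, policy)
            assert out["longest_consecutive_days"] <= out["days_worn"] <= policy.protocol_days
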