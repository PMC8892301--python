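"""Stage 2 — epoch streams to per-day wear/quality/vital-sign summaries.

Reads the config snapshot written by stage 1, regenerates each participant's
epoch stream deterministically, applies the wear criterion (HR > 25 beats/min
and skin temperature > 25 C) and the confidence thresholds (HR >= 85 %,
RR >= 80 %), and writes results/daily_summaries.csv.
"""

from pathlib import Path

import pandas as pd
import yaml

from vestwear.epoch_io import write_daily_summaries
from vestwear.synthetic_cohort import SimParams, iter_cohort
from vestwear.wear_quality import QualityThresholds, summarize_days

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    snap = yaml.safe_load((ROOT / "results" / "cohort" / "config_snapshot.yaml").read_text())
    sim = snap["sim"]
    for k in ("mrc_probs_aecopd", "mrc_probs_stable"):
        sim[k] = tuple(sim[k])
    params = SimParams(**sim)
    thresholds = QualityThresholds(epoch_seconds=params.epoch_seconds)

    frames = []
    for meta, epochs, _ in iter_cohort(params, snap["seed"]):
        frames.append(
            summarize_days(
                epochs,
                thresholds,
                participant_id=meta.participant_id,
                start_date=params.start_date,
                protocol_days=params.protocol_days,
            )
        )
    daily = pd.concat(frames, ignore_index=True)
    write_daily_summaries(daily, ROOT / "results" / "daily_summaries.csv")

    worn = daily[daily["wear_hours"] > 0]
    print(f"{len(daily)} participant-days summarized, {len(worn)} with any wear")
    print(f"median daily wear time: {worn['wear_hours'].median():.1f} h")
    for col in ("hr_signal_quality", "rr_signal_quality",
                "hr_data_quality", "rr_data_quality", "st_data_quality"):
        print(f"median {col.replace('_', ' ')}: {worn[col].median():.1f}%")


if __name__ == "__main__":
    main()
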