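"""Stage 1 — generate the synthetic two-group cohort.

Simulates the default study conditions (35 post-exacerbation + 49 stable
participants, 42-day protocol, ~12 h/day waking wear at 15-s epochs) and
writes the participant metadata, the per-day generator truth table and a
config snapshot under results/cohort/. Epoch streams are regenerated
deterministically from the snapshot by later stages; pass --write-streams to
also dump them as CSVs under scratch/streams/ (large).
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from vestwear.epoch_io import write_epoch_stream, write_participant_meta
from vestwear.synthetic_cohort import SimParams, iter_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--write-streams", action="store_true")
    args = ap.parse_args()

    params = SimParams()
    out = ROOT / "results" / "cohort"
    out.mkdir(parents=True, exist_ok=True)

    metas, truths = [], []
    stream_dir = ROOT / "scratch" / "streams"
    if args.write_streams:
        stream_dir.mkdir(parents=True, exist_ok=True)
    n_epochs = 0
    for meta, epochs, truth in iter_cohort(params, args.seed):
        metas.append(meta)
        truths.append(truth)
        n_epochs += len(epochs)
        if args.write_streams:
            write_epoch_stream(epochs, stream_dir / f"{meta.participant_id}.csv")

    write_participant_meta(metas, out / "participants.csv")
    truth = pd.concat(truths, ignore_index=True)
    truth.to_csv(out / "truth.csv", index=False)
    (out / "config_snapshot.yaml").write_text(
        yaml.safe_dump({"seed": args.seed, "sim": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in dataclasses.asdict(params).items()
        }})
    )

    by_group = pd.Series([m.group for m in metas]).value_counts()
    worn = truth[truth["status"] == "worn"]
    print(f"simulated {len(metas)} participants "
          f"({by_group.get('AECOPD', 0)} AECOPD, {by_group.get('Stable', 0)} Stable), "
          f"{n_epochs:,} epochs")
    print(f"worn days: {len(worn)}/{len(truth)} "
          f"({100 * len(worn) / len(truth):.1f}% of protocol days)")
    print(f"battery-depletion events during wear: {int(truth['battery_depleted'].sum())}")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
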