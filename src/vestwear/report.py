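"""End-to-end pipeline: simulate (or read) -> daily summaries -> adherence -> report.

:class:`PipelineConfig` captures everything a run depends on (thresholds,
wear policy, generator parameters, seed, paths); a YAML snapshot of the
config and its hash are written beside the outputs so every bundle is
reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .adherence import WearPolicy, summarize_cohort
from .cohort_stats import build_cohort_table, format_p  # noqa: F401  (re-export)
from .epoch_io import (
    meta_frame,
    read_epoch_stream,
    read_participant_meta,
    write_daily_summaries,
    write_participant_meta,
)
from .synthetic_cohort import SimParams, iter_cohort
from .wear_quality import QualityThresholds, summarize_days

__all__ = ["PipelineConfig", "run_pipeline", "format_p", "config_to_yaml", "config_from_yaml"]

log = logging.getLogger("vestwear")


@dataclass
class PipelineConfig:
    """Serializable description of one pipeline run."""

    thresholds: QualityThresholds = field(default_factory=QualityThresholds)
    policy: WearPolicy = field(default_factory=WearPolicy)
    sim: SimParams = field(default_factory=SimParams)
    simulate: bool = True
    epoch_dir: str | None = None  # directory of <participant_id>.csv when not simulating
    meta_path: str | None = None
    out_dir: str = "results/run"
    write_epochs: bool = False  # also emit the (large) per-participant epoch CSVs
    log_level: str = "INFO"
    seed: int = 0


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def config_to_yaml(config: PipelineConfig) -> str:
    return yaml.safe_dump(_plain(dataclasses.asdict(config)), sort_keys=True)


def config_from_yaml(text: str) -> PipelineConfig:
    raw = yaml.safe_load(text) or {}
    for key, cls in (("thresholds", QualityThresholds), ("policy", WearPolicy), ("sim", SimParams)):
        if key in raw and isinstance(raw[key], dict):
            if key == "sim":
                for tup in ("mrc_probs_aecopd", "mrc_probs_stable"):
                    if tup in raw[key] and raw[key][tup] is not None:
                        raw[key][tup] = tuple(raw[key][tup])
            raw[key] = cls(**raw[key])
    return PipelineConfig(**raw)


def _iter_inputs(config: PipelineConfig):
    """Yield (participant_id, group-aware meta row or None, epochs, truth or None)."""
    if config.simulate:
        yield from iter_cohort(config.sim, config.seed)
    else:
        if not config.epoch_dir or not config.meta_path:
            raise FileNotFoundError("epoch_dir and meta_path are required when not simulating")
        metas = read_participant_meta(config.meta_path)
        for meta in metas:
            path = Path(config.epoch_dir) / f"{meta.participant_id}.csv"
            if not path.exists():
                raise FileNotFoundError(f"no epoch stream for {meta.participant_id} at {path}")
            yield meta, read_epoch_stream(path, config.thresholds.epoch_seconds), None


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Run all stages; returns the bundle as in-memory DataFrames.

    With ``write=True`` the bundle (daily summaries, participant summaries,
    cohort comparison report, participant metadata, truth table when
    simulated, config snapshot, log) lands under ``config.out_dir``. Output
    files are written atomically (temp file + rename).
    """
    out_dir = Path(config.out_dir)
    handlers: list[logging.Handler] = []
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out_dir / "pipeline.log", mode="w")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
        handlers.append(fh)
    log.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    snapshot = config_to_yaml(config)
    cfg_hash = hashlib.sha256(snapshot.encode()).hexdigest()[:16]
    log.info("pipeline start: seed=%s config_hash=%s simulate=%s", config.seed, cfg_hash, config.simulate)

    try:
        metas, daily_frames, truth_frames = [], [], []
        protocol_days = config.policy.protocol_days
        n_failed = 0
        for item in _iter_inputs(config):
            meta, epochs, truth = item
            try:
                daily = summarize_days(
                    epochs,
                    config.thresholds,
                    participant_id=meta.participant_id,
                    start_date=config.sim.start_date if config.simulate else None,
                    protocol_days=protocol_days,
                )
            except ValueError as exc:
                n_failed += 1
                log.warning("skipping participant %s: %s", meta.participant_id, exc)
                continue
            metas.append(meta)
            daily_frames.append(daily)
            if truth is not None:
                truth_frames.append(truth)
            if write and config.write_epochs:
                stream_dir = out_dir / "streams"
                stream_dir.mkdir(exist_ok=True)
                from .epoch_io import write_epoch_stream

                write_epoch_stream(epochs, stream_dir / f"{meta.participant_id}.csv")
        if not metas:
            raise RuntimeError("no participants produced daily summaries")
        if n_failed:
            log.warning("%d participant(s) skipped", n_failed)

        daily = pd.concat(daily_frames, ignore_index=True)
        participants = summarize_cohort(daily, config.policy)
        meta_df = meta_frame(metas)
        report = build_cohort_table(participants, meta_df)
        truth = pd.concat(truth_frames, ignore_index=True) if truth_frames else None

        if write:
            _atomic(write_daily_summaries, daily, out_dir / "daily_summaries.csv")
            _atomic(lambda d, p: d.to_csv(p, index=False), participants, out_dir / "participant_summaries.csv")
            _atomic(lambda d, p: d.to_csv(p, index=False), report, out_dir / "cohort_comparison.csv")
            write_participant_meta(metas, out_dir / "participants.csv")
            if truth is not None:
                _atomic(lambda d, p: d.to_csv(p, index=False), truth, out_dir / "truth.csv")
            (out_dir / "config_snapshot.yaml").write_text(snapshot)
        log.info(
            "pipeline done: %d participants, %d participant-days", len(metas), len(daily)
        )
        return {
            "daily_summaries": daily,
            "participant_summaries": participants,
            "cohort_comparison": report,
            "metadata": meta_df,
            "truth": truth,
            "config_hash": cfg_hash,
        }
    finally:
        for h in handlers:
            log.removeHandler(h)
            h.close()


def _atomic(writer, df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    writer(df, tmp)
    tmp.replace(path)
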