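"""End-to-end composition: events -> encoding -> entropy -> detection -> scores."""

from __future__ import annotations

from datetime import datetime, timedelta
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .config import RunConfig
from .detection import (
    DetectionFlag,
    daily_profile,
    detect,
    entropy_series,
    flags_to_frame,
)
from .encoding import ActivitySequence, RoomCodeMap, SensorEvent, encode_events
from .evaluation import (
    ConfusionCounts,
    Metrics,
    VisitInterval,
    confusion,
    label_windows,
    metrics,
)
from .simulate import SimRun, simulate

__all__ = ["encode_days", "run_detection", "evaluate_flags", "run_preset"]


def _midnight(ts: datetime) -> datetime:
    return ts.replace(hour=0, minute=0, second=0, microsecond=0)


def encode_days(
    events: Sequence[SensorEvent],
    code_map: RoomCodeMap,
    resolution: int = 1,
    days: Optional[int] = None,
    start: Optional[datetime] = None,
) -> List[ActivitySequence]:
    """Encode a multi-day event log into one full-day sequence per day.

    Day boundaries are local midnight; the span defaults to the calendar
    days touched by the log.
    """
    if not events:
        raise ValueError("no events to encode")
    first = _midnight(min(e.timestamp for e in events)) if start is None else start
    if days is None:
        last = max(e.timestamp for e in events)
        days = max(int((last - first).total_seconds() // 86400) + 1, 1)
    return [
        encode_events(events, code_map, first + timedelta(days=d), 1440, resolution)
        for d in range(days)
    ]


def run_detection(
    events: Sequence[SensorEvent], cfg: RunConfig, days: Optional[int] = None
) -> List[DetectionFlag]:
    """Encode, window, profile, and flag a full event log under ``cfg``."""
    day_seqs = encode_days(events, cfg.room_code_map(), cfg.resolution, days=days or cfg.days)
    windows = entropy_series(day_seqs, cfg.entropy_config(), cfg.window_len, cfg.shift)
    profile = daily_profile(windows, k=cfg.k)
    return detect(windows, profile)


def evaluate_flags(
    flags: Sequence[DetectionFlag],
    visits: Sequence[VisitInterval],
    min_overlap: float = 30.0,
) -> Tuple[ConfusionCounts, Metrics]:
    truth = label_windows([f.window for f in flags], visits, min_overlap)
    counts = confusion(flags, truth)
    return counts, metrics(counts)


def run_preset(cfg: RunConfig) -> dict:
    """Simulate a preset run and score detection on it.

    Returns a dict with the simulated run, the per-window detection frame,
    and the confusion counts / metrics.
    """
    run: SimRun = simulate(cfg.preset, cfg.seed, days=cfg.days)
    flags = run_detection(run.events, cfg, days=run.days)
    counts, scores = evaluate_flags(flags, run.truth, cfg.min_overlap)
    frame: pd.DataFrame = flags_to_frame(flags)
    return {
        "run": run,
        "flags": flags,
        "windows": frame,
        "counts": counts,
        "metrics": scores,
    }
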