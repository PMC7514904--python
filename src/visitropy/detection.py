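"""Windowed entropy series, the across-days threshold profile, and flagging.

A multi-day recording is cut into clock-aligned windows (optionally shifted
from midnight).  Entropy is computed per window, and for every time-of-day
slot the mean and standard deviation across days form a time-varying
threshold ``mean + k * SD``.  Windows whose entropy strictly exceeds their
slot's threshold are flagged as candidate visitor (multi-occupancy) windows.
Also provides the Indoor Mobility baseline: the count of room-to-room
transitions in a sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .encoding import ActivitySequence
from .entropy import EntropyConfig, EntropyResult, entropy

__all__ = [
    "EntropyWindow",
    "DailyProfile",
    "DetectionFlag",
    "entropy_series",
    "daily_profile",
    "detect",
    "overlap_fraction",
    "indoor_mobility",
    "flags_to_frame",
]

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class EntropyWindow:
    """One computation window with its entropy result."""

    start: datetime
    length: int  # minutes
    shift: int  # minutes offset from midnight alignment
    result: EntropyResult

    @property
    def value(self) -> Optional[float]:
        return self.result.value

    @property
    def end(self) -> datetime:
        return self.start + timedelta(minutes=self.length)

    @property
    def slot(self) -> int:
        """Start minute within the day (time-of-day slot key)."""
        return self.start.hour * 60 + self.start.minute


@dataclass(frozen=True)
class DailyProfile:
    """Per-slot across-days mean and SD, with threshold ``mean + k * SD``."""

    stats: Dict[int, Tuple[float, float]]  # slot -> (mean, population SD)
    k: float

    def threshold(self, slot: int) -> float:
        if slot not in self.stats:
            raise KeyError(f"no profile statistics for slot {slot}")
        mean, sd = self.stats[slot]
        return mean + self.k * sd


@dataclass(frozen=True)
class DetectionFlag:
    """Per-window detector decision plus the threshold that produced it."""

    window: EntropyWindow
    threshold: float
    flag: bool


def entropy_series(
    days: Sequence[ActivitySequence],
    config: EntropyConfig,
    window_len: int = 60,
    shift: int = 0,
) -> List[EntropyWindow]:
    """Cut each day into consecutive windows and compute entropy per window.

    Windows start at midnight + ``shift`` and tile the day; a trailing
    partial window is dropped.  Undefined results (SampEn without matches)
    are propagated, not substituted.
    """
    if window_len <= 0 or MINUTES_PER_DAY % 1 != 0:
        raise ValueError("window_len must be positive")
    if not 0 <= shift < window_len:
        raise ValueError("shift must satisfy 0 <= shift < window_len")

    windows: List[EntropyWindow] = []
    for day in days:
        res = day.resolution
        day_minutes = len(day) * res
        samples_per_window = window_len // res
        if window_len % res != 0:
            raise ValueError("window_len must be divisible by the resolution")
        if samples_per_window < config.m + 2:
            raise ValueError(
                f"window of {samples_per_window} samples is too short for m={config.m}"
            )
        start_min = shift
        while start_min + window_len <= day_minutes:
            i0 = start_min // res
            chunk = day.codes[i0 : i0 + samples_per_window]
            result = entropy(chunk, config)
            windows.append(
                EntropyWindow(
                    start=day.start + timedelta(minutes=start_min),
                    length=window_len,
                    shift=shift,
                    result=result,
                )
            )
            start_min += window_len
    return windows


def daily_profile(
    windows: Sequence[EntropyWindow],
    k: float = 1.0,
    clip_passes: Optional[int] = None,
) -> DailyProfile:
    """Across-days mean and population SD of defined values per time-of-day slot.

    Anomalous windows (the very episodes the detector is after) would
    otherwise inflate their own slot's mean and SD, masking weaker episodes
    that share the slot on other days.  The statistics are therefore
    estimated with one-sided sigma-clipping: values above the current
    ``mean + k * SD`` are excluded and the statistics re-estimated, by
    default until no value is removed (``clip_passes=None``); pass a finite
    number to cap the rounds, or 0 for the plain estimate.  The smallest
    value of a slot always survives clipping, so every slot keeps at least
    one observation.
    """
    by_slot: Dict[int, List[float]] = {}
    n_undefined = 0
    for w in windows:
        if w.value is None:
            n_undefined += 1
            continue
        by_slot.setdefault(w.slot, []).append(w.value)
    if n_undefined:
        logger.info("excluded %d undefined windows from the profile", n_undefined)
    if not by_slot:
        raise ValueError("no defined entropy values to build a profile from")

    stats: Dict[int, Tuple[float, float]] = {}
    for slot, vals in by_slot.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            logger.warning("slot %d has %d defined value(s); SD recorded as 0", slot, arr.size)
            stats[slot] = (float(arr.mean()), 0.0)
            continue
        kept = arr
        max_passes = arr.size if clip_passes is None else max(clip_passes, 0)
        for _ in range(max_passes):
            cut = kept.mean() + k * (kept.std(ddof=0) if kept.size > 1 else 0.0)
            retained = kept[kept <= cut]
            if retained.size == kept.size or retained.size == 0:
                break
            kept = retained
        sd = float(kept.std(ddof=0)) if kept.size > 1 else 0.0
        stats[slot] = (float(kept.mean()), sd)
    return DailyProfile(stats=stats, k=k)


def detect(
    windows: Sequence[EntropyWindow], profile: DailyProfile
) -> List[DetectionFlag]:
    """Flag windows whose value strictly exceeds their slot threshold.

    Undefined windows never flag.  A window whose slot has no profile
    statistics is a grid mismatch and raises ``KeyError``.
    """
    flags = []
    for w in windows:
        thr = profile.threshold(w.slot)
        flag = w.value is not None and w.value > thr
        flags.append(DetectionFlag(window=w, threshold=thr, flag=flag))
    return flags


def overlap_fraction(
    visit_start: datetime,
    visit_end: datetime,
    window_start: datetime,
    window_len: int,
) -> float:
    """Percentage of the window covered by the visit interval (0-100)."""
    if visit_end < visit_start:
        raise ValueError("visit interval must be well ordered")
    window_end = window_start + timedelta(minutes=window_len)
    lo = max(visit_start, window_start)
    hi = min(visit_end, window_end)
    overlap_min = max((hi - lo).total_seconds() / 60.0, 0.0)
    return 100.0 * overlap_min / window_len


def indoor_mobility(seq: ActivitySequence) -> int:
    """Indoor Mobility baseline: number of room-to-room transitions."""
    codes = np.asarray(seq.codes)
    if codes.size == 0:
        raise ValueError("empty sequence")
    return int(np.count_nonzero(codes[1:] != codes[:-1]))


def flags_to_frame(flags: Sequence[DetectionFlag]) -> pd.DataFrame:
    """Tabulate detection results (one row per window)."""
    return pd.DataFrame(
        {
            "window_start": [f.window.start for f in flags],
            "length": [f.window.length for f in flags],
            "shift": [f.window.shift for f in flags],
            "measure": [f.window.result.measure for f in flags],
            "value": [f.window.value for f in flags],
            "threshold": [f.threshold for f in flags],
            "flag": [f.flag for f in flags],
        }
    )
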