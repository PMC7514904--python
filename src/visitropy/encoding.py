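"""Encode timestamped binary occupancy events into per-minute room-code sequences.

A home's PIR (passive infra-red) motion sensors emit an *activation* event
each time a room's sensor fires.  The encoder turns a day's worth of such
events into an *encoded daily activity sequence*: one odd integer room code
per minute, where the repetition of a code reflects the time spent in the
room.  Odd codes keep distinct rooms at least 2 apart, so a tolerance
``r < 2`` separates "same room" from "different room" exactly.

Conventions (see the methods note for the rationale):

* Event timestamps are rounded to the nearest minute (30 s rounds up).
* Each half-open minute ``[t, t+1)`` is attributed to the room of the most
  recent activation at or before ``t``.
* Two activations with the *identical* raw timestamp: the first one in log
  order wins; the later ones are discarded.
* Deactivation events carry no location information and are ignored.
* Minutes before the first activation carry back the last known room from
  earlier events, or failing that carry the first room activated inside the
  window backwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SensorEvent",
    "RoomCodeMap",
    "ActivitySequence",
    "CANONICAL_ROOMS",
    "build_code_map",
    "encode_events",
    "read_events_csv",
    "write_events_csv",
]

#: canonical room order used when no dwell statistics are supplied
CANONICAL_ROOMS = ("Living room", "Bedroom", "Bathroom", "Kitchen", "Corridor")


@dataclass(frozen=True)
class SensorEvent:
    """One timestamped binary occupancy reading from one location."""

    timestamp: datetime
    location: str
    state: int = 1  # 1 = activated, 0 = deactivated


@dataclass(frozen=True)
class RoomCodeMap:
    """Injective mapping from room name to an odd positive integer code."""

    codes: Mapping[str, int]

    def __post_init__(self) -> None:
        vals = list(self.codes.values())
        if any(c <= 0 or c % 2 == 0 for c in vals):
            raise ValueError("room codes must be odd positive integers")
        if len(set(vals)) != len(vals):
            raise ValueError("room codes must be distinct")

    def __getitem__(self, room: str) -> int:
        try:
            return self.codes[room]
        except KeyError:
            raise KeyError(f"unknown location {room!r}; known: {sorted(self.codes)}")

    def __contains__(self, room: str) -> bool:
        return room in self.codes

    @property
    def rooms(self) -> List[str]:
        return list(self.codes)


@dataclass(frozen=True)
class ActivitySequence:
    """Per-minute encoded activity sequence starting at ``start``."""

    start: datetime
    resolution: int  # minutes per sample
    codes: np.ndarray  # 1-D integer array

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", np.asarray(self.codes, dtype=int))

    def __len__(self) -> int:
        return int(self.codes.size)


def build_code_map(
    locations: Sequence[str],
    dwell_stats: Optional[Mapping[str, float]] = None,
) -> RoomCodeMap:
    """Assign odd codes 1, 3, 5, ... to rooms.

    With ``dwell_stats`` (total dwell time per room), codes are assigned in
    descending order of dwell — the longest-occupied room gets 1, and the
    highest codes go to rooms used frequently for short periods (e.g. the
    corridor).  Without statistics, the canonical order
    Living room=1, Bedroom=3, Bathroom=5, Kitchen=7, Corridor=9 is used when
    those names are present; remaining rooms follow in input order.
    """
    locations = list(locations)
    if not locations:
        raise ValueError("at least one location is required")
    if len(set(locations)) != len(locations):
        raise ValueError("duplicate location names")

    if dwell_stats is not None:
        missing = [loc for loc in locations if loc not in dwell_stats]
        if missing:
            raise ValueError(f"dwell_stats missing rooms: {missing}")
        # stable sort: ties keep input order
        ordered = sorted(locations, key=lambda loc: -float(dwell_stats[loc]))
    else:
        canonical = [r for r in CANONICAL_ROOMS if r in locations]
        rest = [r for r in locations if r not in CANONICAL_ROOMS]
        ordered = canonical + rest

    return RoomCodeMap({room: 2 * i + 1 for i, room in enumerate(ordered)})


def _rounded_minute(ts: datetime) -> int:
    """Minutes since the epoch, with seconds >= 30 rounding up."""
    epoch = datetime(1970, 1, 1)
    seconds = (ts - epoch).total_seconds()
    return int((seconds + 30) // 60)


def encode_events(
    events: Iterable[SensorEvent],
    code_map: RoomCodeMap,
    window_start: datetime,
    duration: int,
    resolution: int = 1,
) -> ActivitySequence:
    """Encode ``duration`` minutes starting at ``window_start``.

    ``duration`` must be divisible by ``resolution``.  Events outside the
    window still matter: earlier activations provide the carry-back state.
    """
    if duration <= 0 or resolution <= 0:
        raise ValueError("duration and resolution must be positive")
    if duration % resolution != 0:
        raise ValueError("duration must be divisible by resolution")

    active = [e for e in events if e.state]
    # stable sort keeps log order among identical timestamps
    active.sort(key=lambda e: e.timestamp)
    # identical raw timestamps: first in log order wins, later ones discarded
    seen: Dict[datetime, SensorEvent] = {}
    for e in active:
        if e.timestamp not in seen:
            seen[e.timestamp] = e
    active = sorted(seen.values(), key=lambda e: e.timestamp)
    if not active:
        raise ValueError("no activation events to encode")

    minutes = np.array([_rounded_minute(e.timestamp) for e in active])
    codes = np.array([code_map[e.location] for e in active])

    n = duration // resolution
    start_minute = _rounded_minute(window_start)
    sample_minutes = start_minute + resolution * np.arange(n)

    idx = np.searchsorted(minutes, sample_minutes, side="right") - 1
    if idx[-1] < 0:
        raise ValueError("window ends before the first activation event")
    # minutes before any activation carry the first in-window room backwards
    first = int(np.argmax(idx >= 0))
    idx[:first] = idx[first]
    return ActivitySequence(window_start, resolution, codes[idx])


# ---------------------------------------------------------------------------
# CSV dialect: columns timestamp (ISO-8601), location, state (1/0)

def read_events_csv(path) -> List[SensorEvent]:
    """Read an event log; unsorted rows are sorted stably by timestamp."""
    df = pd.read_csv(path, comment="#")
    required = {"timestamp", "location", "state"}
    if not required.issubset(df.columns):
        raise ValueError(f"event CSV must have columns {sorted(required)}")
    events = [
        SensorEvent(
            timestamp=pd.Timestamp(row.timestamp).to_pydatetime(),
            location=str(row.location),
            state=int(row.state),
        )
        for row in df.itertuples(index=False)
    ]
    events.sort(key=lambda e: e.timestamp)
    return events


def write_events_csv(events: Sequence[SensorEvent], path, header_lines: Sequence[str] = ()) -> None:
    df = pd.DataFrame(
        {
            "timestamp": [e.timestamp.isoformat() for e in events],
            "location": [e.location for e in events],
            "state": [e.state for e in events],
        }
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
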