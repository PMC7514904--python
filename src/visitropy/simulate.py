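"""Seeded generator of single-occupant PIR event logs with visitor injection.

The resident model is a semi-Markov daily routine: within each time-of-day
block a room is drawn from the block's room distribution and occupied for a
log-normally distributed dwell, with a one-minute transit-room (corridor)
passage between rooms.  A PIR activation event is emitted at every room
entry.  By default the sampled daily timetable is *replayed* on every day of
the recording — a single resident's scripted, highly regular routine, which
is what makes the across-days threshold profile sharp.  Set
``independent_days=True`` (or a nonzero ``day_jitter_sd``) for day-to-day
variability.

A visitor is injected by superimposing a second occupancy stream during each
realized visit interval: two co-present people trigger PIRs in different
rooms, so the merged log alternates rooms rapidly.  The alternation rate is
``interleaving intensity x`` the resident's own mean hourly activation rate,
with gaps truncated at twice their mean (co-present occupants keep
re-triggering sensors within minutes).  Arrival offsets are whole hours
around the nominal visit times; visit durations vary continuously.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, datetime, timedelta
from typing import Dict, List, Optional, Tuple

import numpy as np

from .encoding import SensorEvent
from .evaluation import VisitInterval

__all__ = [
    "ScheduleBlock",
    "ResidentSchedule",
    "VisitPlan",
    "SimRun",
    "DEFAULT_SCHEDULE",
    "simulate_resident",
    "inject_visitor",
    "preset",
    "simulate",
]

MINUTES_PER_DAY = 1440
DEFAULT_START_DATE = date(2025, 1, 6)  # a Monday


@dataclass(frozen=True)
class ScheduleBlock:
    """One time-of-day block of the resident's routine."""

    start_hour: float
    end_hour: float
    room_probs: Dict[str, float]
    dwell_mean: float  # minutes (arithmetic mean of the log-normal)
    dwell_sigma: float = 0.35  # log-scale dispersion

    def __post_init__(self) -> None:
        total = sum(self.room_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"room probabilities must sum to 1, got {total}")
        if self.dwell_mean < 1:
            raise ValueError("dwell mean must be >= 1 minute")
        if self.dwell_sigma < 0:
            raise ValueError("dwell sigma must be >= 0")


@dataclass(frozen=True)
class ResidentSchedule:
    """Blocks covering 24 h plus the transit room used between dwells."""

    blocks: Tuple[ScheduleBlock, ...]
    transit_room: str = "Corridor"
    transit_minutes: float = 1.0

    def __post_init__(self) -> None:
        hours = sorted((b.start_hour, b.end_hour) for b in self.blocks)
        if hours[0][0] != 0 or hours[-1][1] != 24:
            raise ValueError("schedule blocks must cover 00:00-24:00")
        for (s0, e0), (s1, _) in zip(hours, hours[1:]):
            if e0 != s1:
                raise ValueError("schedule blocks must be contiguous")

    def block_at(self, minute: float) -> ScheduleBlock:
        hour = (minute % MINUTES_PER_DAY) / 60.0
        for b in self.blocks:
            if b.start_hour <= hour < b.end_hour:
                return b
        return self.blocks[-1]

    @property
    def rooms(self) -> List[str]:
        names: List[str] = []
        for b in self.blocks:
            for room in b.room_probs:
                if room not in names:
                    names.append(room)
        if self.transit_room not in names:
            names.append(self.transit_room)
        return names


@dataclass(frozen=True)
class VisitPlan:
    """Where, when, and how intensely visits perturb the merged log."""

    visit_days: Tuple[int, ...] = ()  # 0-based day indices
    nominal_times: Tuple[str, ...] = ()  # "HH:MM" nominal arrival times
    offset_hours: Tuple[int, ...] = (0,)  # whole-hour arrival jitter choices
    duration_range: Tuple[float, float] = (100.0, 120.0)  # minutes
    intensity: float = 3.0  # multiplier on the room-transition rate
    social_rooms: Tuple[str, ...] = ("Living room", "Kitchen", "Bathroom", "Corridor")
    recording_days: int = 7

    def __post_init__(self) -> None:
        if self.intensity < 1:
            raise ValueError("interleaving intensity must be >= 1")
        if self.duration_range[0] > self.duration_range[1] or self.duration_range[0] <= 0:
            raise ValueError("invalid visit duration range")


@dataclass(frozen=True)
class SimRun:
    """A simulated recording: events plus ground-truth visit intervals."""

    seed: int
    days: int
    start_date: date
    events: Tuple[SensorEvent, ...]
    truth: Tuple[VisitInterval, ...] = ()

    @property
    def midnight(self) -> datetime:
        return datetime.combine(self.start_date, datetime.min.time())


DEFAULT_SCHEDULE = ResidentSchedule(
    blocks=(
        ScheduleBlock(0, 8, {"Bedroom": 0.85, "Bathroom": 0.15}, dwell_mean=180.0, dwell_sigma=0.4),
        ScheduleBlock(8, 12, {"Kitchen": 0.4, "Living room": 0.4, "Bathroom": 0.1, "Bedroom": 0.1}, dwell_mean=30.0),
        ScheduleBlock(12, 18, {"Living room": 0.5, "Kitchen": 0.3, "Bathroom": 0.1, "Bedroom": 0.1}, dwell_mean=30.0),
        ScheduleBlock(18, 24, {"Living room": 0.55, "Kitchen": 0.25, "Bedroom": 0.15, "Bathroom": 0.05}, dwell_mean=40.0),
    )
)


def _sample_dwell(rng: np.random.Generator, block: ScheduleBlock) -> float:
    if block.dwell_sigma == 0:
        return max(block.dwell_mean, 1.0)
    mu = np.log(block.dwell_mean) - block.dwell_sigma**2 / 2.0
    return max(float(rng.lognormal(mu, block.dwell_sigma)), 1.0)


def _sample_day_plan(
    rng: np.random.Generator, schedule: ResidentSchedule
) -> List[Tuple[float, str]]:
    """One day's (minute offset, room) entries, transit passages included."""
    plan: List[Tuple[float, str]] = []
    t = 0.0
    prev: Optional[str] = None
    while t < MINUTES_PER_DAY:
        block = schedule.block_at(t)
        rooms = list(block.room_probs)
        probs = np.array([block.room_probs[r] for r in rooms])
        room = rooms[int(rng.choice(len(rooms), p=probs))]
        dwell = _sample_dwell(rng, block)
        if room == prev or prev is None:
            # same room: extend the stay without a new activation
            if prev is None:
                plan.append((t, room))
                prev = room
            t += dwell
            continue
        plan.append((t, schedule.transit_room))
        t += schedule.transit_minutes
        if t >= MINUTES_PER_DAY:
            break
        plan.append((t, room))
        prev = room
        t += dwell
    return plan


def _minutes_to_ts(midnight: datetime, minutes: float) -> datetime:
    return midnight + timedelta(seconds=round(minutes * 60))


def simulate_resident(
    schedule: ResidentSchedule,
    days: int,
    seed: int,
    start_date: date = DEFAULT_START_DATE,
    independent_days: bool = False,
    day_jitter_sd: float = 0.0,
) -> SimRun:
    """Simulate ``days`` days of a single resident's PIR activations.

    By default one timetable is sampled and replayed every day (a scripted
    routine); ``independent_days`` resamples the routine each day and
    ``day_jitter_sd`` (minutes) perturbs each entry time per day.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    midnight = datetime.combine(start_date, datetime.min.time())

    base_plan = _sample_day_plan(rng, schedule)
    events: List[SensorEvent] = []
    for d in range(days):
        plan = _sample_day_plan(rng, schedule) if (independent_days and d > 0) else base_plan
        offsets = [m for m, _ in plan]
        if day_jitter_sd > 0:
            jitter = rng.normal(0.0, day_jitter_sd, size=len(offsets))
            jitter[0] = 0.0  # the day always starts in a known room
            offsets = np.clip(np.sort(np.asarray(offsets) + jitter), 0, MINUTES_PER_DAY - 1)
        for off, (_, room) in zip(offsets, plan):
            events.append(
                SensorEvent(_minutes_to_ts(midnight, d * MINUTES_PER_DAY + float(off)), room, 1)
            )
    events.sort(key=lambda e: e.timestamp)
    return SimRun(seed=seed, days=days, start_date=start_date, events=tuple(events))


def _room_lookup(run: SimRun):
    """Occupied room (and since when) as a function of time, from the baseline log."""
    times = np.array([e.timestamp.timestamp() for e in run.events])
    rooms = [e.location for e in run.events]

    def room_at(ts: datetime) -> Tuple[str, float]:
        i = max(int(np.searchsorted(times, ts.timestamp(), side="right")) - 1, 0)
        return rooms[i], float(times[i])

    return room_at


def _baseline_hourly_rate(run: SimRun) -> float:
    """Mean activations per hour, floored at 1 (sets the visit alternation pace)."""
    return max(len(run.events) / run.days / 24.0, 1.0)


def inject_visitor(run: SimRun, plan: VisitPlan, seed: int) -> SimRun:
    """Superimpose a visitor stream during each realized visit interval."""
    if not plan.visit_days or not plan.nominal_times:
        return run
    rng = np.random.default_rng(seed)
    room_at = _room_lookup(run)
    rate = _baseline_hourly_rate(run)
    gap_mean = 60.0 / (plan.intensity * rate)
    gap_cap = 2.0 * gap_mean

    new_events: List[SensorEvent] = list(run.events)
    truth: List[VisitInterval] = list(run.truth)

    for day in sorted(plan.visit_days):
        if not 0 <= day < run.days:
            raise ValueError(f"visit day {day} outside the {run.days}-day recording")
        for visit_no, hhmm in enumerate(plan.nominal_times):
            hh, mm = (int(p) for p in hhmm.split(":"))
            offset = int(rng.choice(plan.offset_hours))
            start_min = day * MINUTES_PER_DAY + (hh + offset) * 60 + mm
            duration = float(rng.uniform(*plan.duration_range))
            duration = min(duration, (day + 1) * MINUTES_PER_DAY - start_min)
            if duration < 5:
                continue
            start_ts = _minutes_to_ts(run.midnight, start_min)
            end_ts = _minutes_to_ts(run.midnight, start_min + duration)

            # alternating merged stream: each injected event switches the
            # active room, counting scripted resident moves in between
            last_emit: Optional[Tuple[str, float]] = None  # (room, epoch seconds)
            t = 0.0
            first = True
            while True:
                if first:
                    gap = min(max(float(rng.gamma(2.0, gap_mean / 4.0)), 0.5), gap_cap)
                    first = False
                else:
                    gap = min(max(float(rng.gamma(4.0, gap_mean / 4.0)), 1.0), gap_cap)
                t += gap
                if t >= duration:
                    break
                ts = _minutes_to_ts(run.midnight, start_min + t)
                base_room, base_time = room_at(ts)
                if last_emit is not None and last_emit[1] >= base_time:
                    current = last_emit[0]
                else:
                    current = base_room
                pool = [r for r in plan.social_rooms if r != current]
                room = pool[int(rng.choice(len(pool)))]
                new_events.append(SensorEvent(ts, room, 1))
                last_emit = (room, ts.timestamp())
            # the resident resumes the scripted routine when the visitor leaves
            new_events.append(SensorEvent(end_ts, room_at(end_ts)[0], 1))
            truth.append(
                VisitInterval(start_ts, end_ts, visitor_id=f"visitor-d{day + 1}-{visit_no + 1}")
            )

    new_events.sort(key=lambda e: e.timestamp)
    truth.sort(key=lambda v: v.start)
    return replace(run, events=tuple(new_events), truth=tuple(truth))


def preset(name: str) -> Tuple[ResidentSchedule, VisitPlan]:
    """Named study configurations.

    ``datasetA``: 3-day recording, three visits of up to an hour on day 3
    (nominal 10:00, 14:00, 19:00, +-1 h arrival jitter).
    ``datasetB``: 7-day recording, visits around 12:00 and 20:00 on days
    2, 4, and 6, arrival jitter of one or two hours either way, duration
    about two hours.
    """
    if name == "datasetA":
        plan = VisitPlan(
            visit_days=(2,),
            nominal_times=("10:00", "14:00", "19:00"),
            offset_hours=(-1, 0, 1),
            duration_range=(30.0, 60.0),
            intensity=3.0,
            recording_days=3,
        )
        return DEFAULT_SCHEDULE, plan
    if name == "datasetB":
        plan = VisitPlan(
            visit_days=(1, 3, 5),
            nominal_times=("12:00", "20:00"),
            offset_hours=(-2, -1, 0, 1, 2),
            duration_range=(100.0, 120.0),
            intensity=3.0,
            recording_days=7,
        )
        return DEFAULT_SCHEDULE, plan
    raise ValueError(f"unknown preset {name!r} (expected 'datasetA' or 'datasetB')")


def simulate(
    preset_name: str,
    seed: int,
    days: Optional[int] = None,
    start_date: date = DEFAULT_START_DATE,
) -> SimRun:
    """Generate a full preset run (resident + injected visits) from one seed."""
    schedule, plan = preset(preset_name)
    child = np.random.SeedSequence(seed).generate_state(2) >> 1  # keep < 2**31
    run = simulate_resident(schedule, days or plan.recording_days, int(child[0]), start_date)
    return inject_visitor(run, plan, int(child[1]))
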