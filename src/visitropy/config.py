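"""Run configuration: one validated object holding every pipeline parameter.

Defaults are the headline regime: FuzzyEn with m=2, r=1, n=2 on one-hour
clock-aligned windows, threshold mean + 1 SD, 30% minimum overlap for a
window to count as a true visitor window.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from typing import Dict, Optional

import yaml

from .encoding import CANONICAL_ROOMS, RoomCodeMap, build_code_map
from .entropy import EntropyConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    measure: str = "fuzzyen"
    m: int = 2
    r: float = 1.0
    n: float = 2.0
    window_len: int = 60  # minutes
    shift: int = 0  # minutes
    k: float = 1.0  # SD multiplier of the threshold profile
    resolution: int = 1  # minutes per encoded sample
    min_overlap: float = 30.0  # % of a window a visit must cover
    preset: str = "datasetB"
    seed: int = 0
    days: Optional[int] = None  # None: use the preset's recording span
    code_map: Optional[Dict[str, int]] = None  # None: canonical odd codes

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        # EntropyConfig re-checks measure/m/r/n
        self.entropy_config()
        if self.window_len <= 0 or self.window_len > 1440:
            raise ValueError("window_len must lie in (0, 1440] minutes")
        if not 0 <= self.shift < self.window_len:
            raise ValueError("shift must satisfy 0 <= shift < window_len")
        if self.resolution <= 0 or self.window_len % self.resolution != 0:
            raise ValueError("resolution must divide window_len")
        if not 0 <= self.min_overlap <= 100:
            raise ValueError("min_overlap must lie in [0, 100]")
        if self.days is not None and self.days < 1:
            raise ValueError("days must be >= 1")

    def entropy_config(self) -> EntropyConfig:
        return EntropyConfig(measure=self.measure, m=self.m, r=self.r, n=self.n)

    def room_code_map(self) -> RoomCodeMap:
        if self.code_map is not None:
            return RoomCodeMap(dict(self.code_map))
        return build_code_map(list(CANONICAL_ROOMS))

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def describe(self) -> list:
        """Human-readable parameter lines for self-describing output headers."""
        d = asdict(self)
        d.pop("code_map", None)
        return [f"{key}={value}" for key, value in d.items()]
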