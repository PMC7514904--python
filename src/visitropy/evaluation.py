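"""Window-level scoring of detections against ground-truth visit intervals.

The evaluation unit is the computation window: a window's truth label is
"visitor" when the fraction of it covered by (the union of) visits reaches
``min_overlap`` percent (default 30).  Flags and labels are tallied into a
standard 2x2 confusion matrix; accuracy, precision, and recall are reported
as percentages, or ``None`` when a denominator is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .detection import DetectionFlag, EntropyWindow, overlap_fraction

__all__ = [
    "VisitInterval",
    "ConfusionCounts",
    "Metrics",
    "merge_intervals",
    "label_windows",
    "confusion",
    "metrics",
    "read_visits_csv",
    "write_visits_csv",
]


@dataclass(frozen=True)
class VisitInterval:
    """Ground-truth visit: a visitor is present in [start, end)."""

    start: datetime
    end: datetime
    visitor_id: str = "visitor"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("visit interval requires start < end")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    """Percentages in [0, 100]; ``None`` marks an undefined ratio."""

    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]


def merge_intervals(
    visits: Sequence[VisitInterval],
) -> List[Tuple[datetime, datetime]]:
    """Union overlapping/touching visit intervals."""
    spans = sorted((v.start, v.end) for v in visits)
    merged: List[Tuple[datetime, datetime]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def label_windows(
    windows: Sequence[EntropyWindow],
    visits: Sequence[VisitInterval],
    min_overlap: float = 30.0,
) -> np.ndarray:
    """Boolean truth label per window: visit coverage >= ``min_overlap`` %."""
    if not 0 <= min_overlap <= 100:
        raise ValueError("min_overlap must lie in [0, 100]")
    merged = merge_intervals(visits)
    labels = np.zeros(len(windows), dtype=bool)
    for i, w in enumerate(windows):
        cover = sum(
            overlap_fraction(s, e, w.start, w.length) for s, e in merged
        )
        labels[i] = cover >= min_overlap
    return labels


def confusion(flags: Sequence[DetectionFlag], truth: Sequence[bool]) -> ConfusionCounts:
    """Tally the per-window 2x2 confusion matrix."""
    if len(flags) != len(truth):
        raise ValueError("flags and truth labels cover different window grids")
    pred = np.array([f.flag for f in flags], dtype=bool)
    t = np.asarray(truth, dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(pred & t)),
        fp=int(np.sum(pred & ~t)),
        tn=int(np.sum(~pred & ~t)),
        fn=int(np.sum(~pred & t)),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, precision, recall as percentages (None on zero denominators)."""
    acc = 100.0 * (c.tp + c.tn) / c.total if c.total else None
    prec = 100.0 * c.tp / (c.tp + c.fp) if (c.tp + c.fp) else None
    rec = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    return Metrics(accuracy=acc, precision=prec, recall=rec)


# ---------------------------------------------------------------------------
# Ground-truth CSV dialect: columns start, end, visitor_id

def read_visits_csv(path) -> List[VisitInterval]:
    df = pd.read_csv(path, comment="#")
    required = {"start", "end"}
    if not required.issubset(df.columns):
        raise ValueError("truth CSV must have columns start, end[, visitor_id]")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            VisitInterval(
                start=pd.Timestamp(row.start).to_pydatetime(),
                end=pd.Timestamp(row.end).to_pydatetime(),
                visitor_id=str(getattr(row, "visitor_id", "visitor")),
            )
        )
    return out


def write_visits_csv(visits: Sequence[VisitInterval], path, header_lines: Sequence[str] = ()) -> None:
    df = pd.DataFrame(
        {
            "start": [v.start.isoformat() for v in visits],
            "end": [v.end.isoformat() for v in visits],
            "visitor_id": [v.visitor_id for v in visits],
        }
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
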