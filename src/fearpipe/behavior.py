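"""Freezing-behavior scoring from body-tracking trajectories.

An animal counts as freezing when no movement is detected for at least
2 s.  "Movement" is operationalized as centroid frame-to-frame displacement
above a pixel threshold; maximal runs of immobile steps lasting at least
``min_duration_s`` become freezing bouts, and per-epoch scores are the
percentage of epoch time covered by bouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import EventTimeline

__all__ = [
    "TrajectorySeries",
    "FreezeParams",
    "FreezingBouts",
    "detect_freezing",
    "score_freezing",
]


@dataclass
class TrajectorySeries:
    """Uniformly sampled centroid track: times (s) and x/y positions (px)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t, x, y must have equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("sampling must be uniform")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")

    @property
    def rate(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])


@dataclass
class FreezeParams:
    """min_duration_s: shortest immobility counted as freezing (2 s rule).
    motion_threshold_px: largest per-frame displacement still counted as
    "no movement" (default calibrated on the simulator: immobility jitter
    stays well below it, locomotion steps well above).
    smoothing_window_s > 0 merges bouts separated by shorter mobile gaps.
    """

    min_duration_s: float = 2.0
    motion_threshold_px: float = 1.0
    smoothing_window_s: float = 0.0

    def validate(self):
        if self.min_duration_s <= 0:
            raise ValueError("min_duration_s must be > 0")
        if self.motion_threshold_px < 0 or self.smoothing_window_s < 0:
            raise ValueError("thresholds must be >= 0")


@dataclass
class FreezingBouts:
    """Ordered, non-overlapping half-open [start, end) freezing intervals (s)."""

    bouts: list[tuple[float, float]] = field(default_factory=list)

    def total_duration(self) -> float:
        return sum(e - s for s, e in self.bouts)

    def __len__(self):
        return len(self.bouts)

    def __iter__(self):
        return iter(self.bouts)


def detect_freezing(traj: TrajectorySeries,
                    params: FreezeParams | None = None) -> FreezingBouts:
    """Detect freezing bouts: runs of immobile steps lasting >= min_duration_s.

    Step i (connecting samples i-1 and i) is immobile when the centroid
    displacement is <= ``motion_threshold_px``.  A maximal run of immobile
    steps spanning samples [i-1 .. j] yields the bout [t[i-1], t[j]).
    """
    params = params or FreezeParams()
    params.validate()
    if traj.t.size < 2:
        raise ValueError("trajectory too short")
    dt = traj.t[1] - traj.t[0]
    if params.min_duration_s / dt < 2:
        raise ValueError(
            f"sampling rate {1/dt:.3g} Hz too low to resolve "
            f"{params.min_duration_s}-s bouts")
    disp = np.hypot(np.diff(traj.x), np.diff(traj.y))
    immobile = disp <= params.motion_threshold_px

    edges = np.flatnonzero(np.diff(np.concatenate(([0], immobile.view(np.int8), [0]))))
    runs = [(i0, i1) for i0, i1 in zip(edges[::2], edges[1::2])]  # step indices [i0, i1)

    if params.smoothing_window_s > 0 and len(runs) > 1:
        merged = [runs[0]]
        for i0, i1 in runs[1:]:
            if (i0 - merged[-1][1]) * dt <= params.smoothing_window_s:
                merged[-1] = (merged[-1][0], i1)
            else:
                merged.append((i0, i1))
        runs = merged

    bouts = []
    for i0, i1 in runs:
        dur = (i1 - i0) * dt
        if dur >= params.min_duration_s:
            bouts.append((float(traj.t[i0]), float(traj.t[i1])))
    return FreezingBouts(bouts)


def score_freezing(bouts: FreezingBouts, timeline: EventTimeline,
                   animal_id: str = "", session: str | None = None
                   ) -> pd.DataFrame:
    """Percent time freezing per epoch (baseline and each CS presentation).

    A bout straddling an epoch boundary contributes only its overlap; every
    score lies in [0, 100].
    """
    epochs = []
    for e in timeline.by_label("baseline"):
        epochs.append(("baseline", e.start, e.end))
    for i, e in enumerate(timeline.by_label("cs"), start=1):
        epochs.append((f"cs_{i}", e.start, e.end))
    if not epochs:
        raise ValueError("timeline has no scorable epochs")
    rows = []
    for label, e0, e1 in epochs:
        overlap = sum(max(0.0, min(b1, e1) - max(b0, e0)) for b0, b1 in bouts)
        rows.append({
            "animal_id": animal_id,
            "session": session or timeline.session_label,
            "epoch": label,
            "freezing_pct": 100.0 * overlap / (e1 - e0),
        })
    return pd.DataFrame(rows)
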