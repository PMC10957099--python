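"""Fear-conditioning session timelines.

A session is described as an ordered set of labeled, half-open intervals
``[start, end)`` in seconds: a baseline epoch, conditioned-stimulus (CS)
presentations built from trains of short tone pips, and — on conditioning
days — an unconditioned stimulus (US, foot shock) delivered back to back
after the last pip of each CS.  Every downstream stage (photometry trial
alignment, miniscope CS classification, freezing scoring) aligns to one of
these timelines, so they are built deterministically from a parameter set
and a seed and serialize losslessly to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

__all__ = [
    "Event",
    "EventTimeline",
    "ProtocolParams",
    "build_timeline",
    "laser_windows",
    "SESSION_LABELS",
]

#: Recognized session labels.  "fc_day1" / "fc_day3" are conditioning
#: sessions (CS paired with US); "retrieval_day2" presents the CS alone;
#: "habituation" is context exposure with no stimuli.
SESSION_LABELS = ("habituation", "fc_day1", "retrieval_day2", "fc_day3")


@dataclass(frozen=True)
class Event:
    """One labeled half-open interval ``[start, end)`` within a session."""

    label: str
    start: float
    end: float
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class EventTimeline:
    session_label: str
    events: list[Event]
    total_duration: float

    def by_label(self, label: str) -> list[Event]:
        return [e for e in self.events if e.label == label]

    def onsets(self, label: str) -> np.ndarray:
        return np.array([e.start for e in self.by_label(label)], dtype=float)

    def validate(self) -> None:
        """Check interval and nesting invariants; raise ``ValueError`` on failure."""
        for e in self.events:
            if not (0.0 <= e.start < e.end <= self.total_duration + 1e-9):
                raise ValueError(
                    f"event {e.label!r} [{e.start}, {e.end}) outside "
                    f"[0, {self.total_duration})"
                )
        labels = {e.label for e in self.events}
        for lab in labels:
            evs = self.by_label(lab)
            for a, b in zip(evs, evs[1:]):
                if b.start < a.end - 1e-12:
                    raise ValueError(f"{lab!r} events overlap or are unordered")
        cs = self.by_label("cs")
        for pip in self.by_label("pip"):
            hosts = [c for c in cs if c.start - 1e-9 <= pip.start and pip.end <= c.end + 1e-9]
            if len(hosts) != 1:
                raise ValueError("every pip must lie within exactly one CS")

    # -- JSON round trip ---------------------------------------------------

    def to_json(self, path=None, indent: int = 2) -> str:
        doc = {
            "session_label": self.session_label,
            "total_duration": self.total_duration,
            "events": [asdict(e) for e in self.events],
        }
        text = json.dumps(doc, indent=indent)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "EventTimeline":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        events = [Event(**e) for e in doc["events"]]
        tl = cls(doc["session_label"], events, float(doc["total_duration"]))
        tl.validate()
        return tl


@dataclass
class ProtocolParams:
    """Constants of the behavioral protocol.

    Defaults reflect the standard auditory fear-conditioning design: 2-min
    baseline; CS = 10-s train of 200-ms pips at 0.9 Hz (7.5-kHz tone on
    days 1/2, 3-kHz on the reconditioning day); on conditioning days a 2-s
    foot shock (0.65 mA DC) starts at the offset of the last pip; five
    CS–US pairings on day 1, eight CS-alone presentations at retrieval with
    inter-trial intervals drawn uniformly from 35–60 s (measured CS offset
    to next CS onset).  Tone frequency and shock current are metadata only —
    nothing is rendered.
    """

    baseline_s: float = 120.0
    n_cs_day1: int = 5
    n_cs_day2: int = 8
    cs_duration_s: float = 10.0
    pip_duration_s: float = 0.2
    pip_rate_hz: float = 0.9
    us_duration_s: float = 2.0
    iti_range_s: tuple[float, float] = (35.0, 60.0)
    post_last_cs_s: float = 60.0
    habituation_s: float = 600.0
    cs_tone_hz: float = 7500.0
    cs2_tone_hz: float = 3000.0
    us_current_ma: float = 0.65
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("baseline_s", "cs_duration_s", "pip_duration_s",
                     "pip_rate_hz", "us_duration_s", "post_last_cs_s",
                     "habituation_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_cs_day1 < 1 or self.n_cs_day2 < 1:
            raise ValueError("CS counts must be >= 1")
        lo, hi = self.iti_range_s
        if not (0 < lo <= hi):
            raise ValueError("iti_range_s must satisfy 0 < min <= max")
        if self.pip_duration_s > 1.0 / self.pip_rate_hz:
            raise ValueError("pips would overlap: pip_duration_s > 1/pip_rate_hz")


def pip_onsets(params: ProtocolParams) -> np.ndarray:
    """Pip onsets relative to CS onset: k / pip_rate while the pip fits in the CS."""
    onsets = []
    k = 0
    while True:
        t = k / params.pip_rate_hz
        if t + params.pip_duration_s > params.cs_duration_s + 1e-12:
            break
        onsets.append(t)
        k += 1
    return np.asarray(onsets)


def _cs_block(start: float, params: ProtocolParams, index: int,
              tone_hz: float, with_us: bool) -> list[Event]:
    """CS event, its pip train, and (optionally) the US after the last pip."""
    events = [Event("cs", start, start + params.cs_duration_s,
                    {"trial": index, "tone_hz": tone_hz})]
    rel = pip_onsets(params)
    for k, t in enumerate(rel):
        events.append(Event("pip", start + t, start + t + params.pip_duration_s,
                            {"trial": index, "pip": k}))
    if with_us:
        us_start = start + rel[-1] + params.pip_duration_s
        events.append(Event("us", us_start, us_start + params.us_duration_s,
                            {"trial": index, "current_ma": params.us_current_ma}))
    return events


def build_timeline(session: str, params: ProtocolParams | None = None) -> EventTimeline:
    """Build the event timeline for one session.

    Deterministic given ``(session, params)``: inter-trial intervals are
    drawn from ``params.iti_range_s`` with ``params.rng_seed``.
    """
    params = params or ProtocolParams()
    params.validate()
    if session not in SESSION_LABELS:
        raise ValueError(f"unknown session label {session!r}; expected one of {SESSION_LABELS}")

    if session == "habituation":
        ev = [Event("baseline", 0.0, params.habituation_s, {"context": "A"})]
        tl = EventTimeline(session, ev, params.habituation_s)
        tl.validate()
        return tl

    rng = np.random.default_rng(params.rng_seed)
    conditioning = session in ("fc_day1", "fc_day3")
    n_cs = params.n_cs_day1 if conditioning else params.n_cs_day2
    tone = params.cs2_tone_hz if session == "fc_day3" else params.cs_tone_hz
    context = "B" if conditioning else "A"

    events: list[Event] = [Event("baseline", 0.0, params.baseline_s, {"context": context})]
    itis = rng.uniform(*params.iti_range_s, size=n_cs - 1)
    t = params.baseline_s
    last_cs_end = t
    for i in range(n_cs):
        events.extend(_cs_block(t, params, i, tone, with_us=conditioning))
        last_cs_end = t + params.cs_duration_s
        if i < n_cs - 1:
            t = last_cs_end + itis[i]
    total = last_cs_end + params.post_last_cs_s
    total = max(total, max(e.end for e in events))
    tl = EventTimeline(session, events, total)
    tl.validate()
    return tl


def laser_windows(timeline: EventTimeline, mode: str, pad: float = 0.0
                  ) -> list[tuple[float, float]]:
    """Optogenetic illumination windows covering the stimuli.

    ``mode="cs_us"`` spans each CS through its paired US (+/- ``pad``);
    ``mode="cs"`` covers each CS alone.  One window per CS.
    """
    if mode not in ("cs_us", "cs"):
        raise ValueError(f"mode must be 'cs_us' or 'cs', got {mode!r}")
    cs_events = timeline.by_label("cs")
    if mode == "cs":
        return [(c.start - pad, c.end + pad) for c in cs_events]
    us_events = timeline.by_label("us")
    if not us_events and cs_events:
        raise ValueError("mode 'cs_us' requires US events in the timeline")
    windows = []
    for c in cs_events:
        paired = [u for u in us_events if u.start >= c.start - 1e-9]
        if not paired:
            raise ValueError(f"no US paired with CS starting at {c.start}")
        u = paired[0]
        windows.append((c.start - pad, u.end + pad))
    return windows
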