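"""Ground-truth simulators for every data modality the pipeline consumes.

Each simulator is a pure function of a timeline, a parameter set, and a
seed, and returns the simulated artifact together with a ``GroundTruth``
record sufficient to compute every downstream recovery metric without
re-simulation:

- photometry: two-exponential photobleaching and shared-channel motion
  artifacts under GCaMP-like CS/US-locked transients (the isosbestic
  correction exploits exactly the shared-artifact structure),
- miniscope movies: disk-like cell footprints of known response class
  (gain-CS / lose-CS / US-only / non-responsive) on a smooth background,
  with rigid random-walk frame drift,
- body tracking with explicitly scheduled immobility bouts,
- cohort freezing tables drawn per group design.

The paper's raw recordings are not deposited, so amplitude and noise
defaults are calibrated targets of the pipeline's recovery properties, not
measurements; the methods note documents the choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .behavior import TrajectorySeries
from .miniscope import Movie
from .photometry import DualChannelRecording, TimeSeries
from .protocol import EventTimeline

__all__ = [
    "GroundTruth",
    "PhotometrySimParams",
    "MiniscopeSimParams",
    "TrackingSimParams",
    "GroupDesign",
    "simulate_photometry",
    "simulate_miniscope",
    "simulate_tracking",
    "simulate_cohort",
    "gcamp_kernel",
    "disynaptic_photometry_params",
    "mono_photometry_params",
    "CELL_CLASSES",
]

CELL_CLASSES = ("gain_cs", "lose_cs", "us_only", "nonresponsive")


@dataclass
class GroundTruth:
    """Everything a recovery test needs about one simulated artifact."""

    true_trial_amplitudes: np.ndarray | None = None
    true_us_amplitude: float | None = None
    true_shifts: np.ndarray | None = None          # (n_frames, 2)
    true_footprints: np.ndarray | None = None      # (n_cells, rows, cols)
    true_traces: np.ndarray | None = None          # (n_cells, n_frames)
    true_class: list[str] | None = None
    true_freeze_bouts: list[tuple[float, float]] | None = None


def gcamp_kernel(rate_hz: float, rise_s: float = 0.2, decay_s: float = 1.5,
                 length_s: float | None = None) -> np.ndarray:
    """Difference-of-exponentials calcium-indicator impulse response, peak 1."""
    if rise_s <= 0 or decay_s <= rise_s:
        raise ValueError("need 0 < rise < decay")
    length_s = length_s or 6.0 * decay_s
    t = np.arange(0.0, length_s, 1.0 / rate_hz)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()


# --------------------------------------------------------------------------
# photometry
# --------------------------------------------------------------------------

@dataclass
class PhotometrySimParams:
    """Dual-channel recording model.

    The returned recording is the raw source stream at
    ``sample_rate_hz * oversample`` (preprocessing decimates it back).
    The 405-nm reference carries baseline + two-exponential bleach +
    motion artifacts + noise; the 465-nm signal carries the same bleach
    and artifacts scaled by ``channel_gain`` plus GCaMP transients at each
    CS onset (amplitude per ``cs_amp_schedule``) and US onset.
    """

    sample_rate_hz: float = 1000.0
    oversample: int = 2
    baseline_level: float = 1.0
    bleach_amps: tuple[float, float] = (0.3, 0.1)
    bleach_taus: tuple[float, float] = (600.0, 120.0)
    channel_gain: float = 1.8
    artifact_rate_hz: float = 0.02
    artifact_amp: float = 0.2
    artifact_decay_s: float = 0.3
    transient_rise_s: float = 0.2
    transient_decay_s: float = 1.5
    cs_amp_schedule: tuple[float, ...] | None = None   # None -> all 1.0
    us_amp: float = 2.0
    noise_sd: float = 0.01
    rng_seed: int = 0

    def validate(self, n_cs: int) -> None:
        if any(tau <= 0 for tau in self.bleach_taus):
            raise ValueError("bleach taus must be > 0")
        if any(a < 0 for a in self.bleach_amps) or self.us_amp < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.cs_amp_schedule is not None and len(self.cs_amp_schedule) != n_cs:
            raise ValueError(
                f"cs_amp_schedule length {len(self.cs_amp_schedule)} != CS count {n_cs}")


def disynaptic_photometry_params(n_cs: int = 5, **kw) -> PhotometrySimParams:
    """Preset emulating the disynaptic population: CS responses that grow
    monotonically across conditioning trials, plus a robust US response."""
    sched = tuple(0.5 + 0.5 * i for i in range(n_cs))
    return PhotometrySimParams(cs_amp_schedule=sched, us_amp=3.0, **kw)


def mono_photometry_params(n_cs: int = 5, rng_seed: int = 0, **kw) -> PhotometrySimParams:
    """Preset emulating the monosynaptic population: strong US response,
    weak heterogeneous CS responses that do not grow with learning."""
    rng = np.random.default_rng(rng_seed)
    sched = tuple(np.abs(rng.normal(0.0, 0.1, n_cs)))
    return PhotometrySimParams(cs_amp_schedule=sched, us_amp=3.0,
                               rng_seed=rng_seed, **kw)


def simulate_photometry(timeline: EventTimeline,
                        params: PhotometrySimParams | None = None
                        ) -> tuple[DualChannelRecording, GroundTruth]:
    params = params or PhotometrySimParams()
    cs_onsets = timeline.onsets("cs")
    us_onsets = timeline.onsets("us")
    params.validate(len(cs_onsets))
    sched = (np.ones(len(cs_onsets)) if params.cs_amp_schedule is None
             else np.asarray(params.cs_amp_schedule, dtype=float))

    rate = params.sample_rate_hz * params.oversample
    n = int(round(timeline.total_duration * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(params.rng_seed)

    bleach = params.baseline_level + sum(
        a * np.exp(-t / tau) for a, tau in zip(params.bleach_amps, params.bleach_taus))

    artifacts = np.zeros(n)
    n_art = rng.poisson(params.artifact_rate_hz * timeline.total_duration)
    if n_art > 0 and params.artifact_amp > 0:
        art_times = rng.uniform(0, timeline.total_duration, n_art)
        art_signs = rng.choice([-1.0, 1.0], n_art)
        impulses = np.zeros(n)
        idx = np.minimum((art_times * rate).astype(int), n - 1)
        np.add.at(impulses, idx, art_signs * params.artifact_amp)
        k_art = np.exp(-np.arange(0, 5 * params.artifact_decay_s, 1 / rate)
                       / params.artifact_decay_s)
        artifacts = signal.fftconvolve(impulses, k_art, mode="full")[:n]

    impulses = np.zeros(n)
    for onset, amp in zip(cs_onsets, sched):
        impulses[min(int(round(onset * rate)), n - 1)] += amp
    for onset in us_onsets:
        impulses[min(int(round(onset * rate)), n - 1)] += params.us_amp
    kern = gcamp_kernel(rate, params.transient_rise_s, params.transient_decay_s)
    transients = signal.fftconvolve(impulses, kern, mode="full")[:n]

    shared = bleach + artifacts
    ref = shared + rng.normal(0, params.noise_sd, n)
    sig = params.channel_gain * shared + transients + rng.normal(0, params.noise_sd, n)

    rec = DualChannelRecording(TimeSeries(0.0, rate, sig),
                               TimeSeries(0.0, rate, ref))
    truth = GroundTruth(true_trial_amplitudes=sched,
                        true_us_amplitude=params.us_amp)
    return rec, truth


# --------------------------------------------------------------------------
# miniscope movies
# --------------------------------------------------------------------------

@dataclass
class MiniscopeSimParams:
    """Movie model: disk footprints x class-dependent transient traces on a
    smooth background, rigid random-walk drift, Gaussian pixel noise with
    sd = transient amplitude / snr."""

    fov: tuple[int, int] = (200, 200)
    frame_rate_hz: float = 20.0
    n_cells: int = 10
    footprint_radius_px: float = 10.0
    shift_walk_sd_px: float = 0.05
    class_fractions: tuple[float, float, float, float] = (0.4, 0.2, 0.2, 0.2)
    snr: float = 10.0
    amp: float = 1.0
    baseline_level: float = 20.0
    background_sigma_px: float = 30.0
    background_amp: float = 2.0
    texture_sigma_px: float = 1.5
    texture_amp: float = 0.5
    transient_rise_s: float = 0.2
    transient_decay_s: float = 1.5
    overlap_free: bool = True
    rng_seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        r = self.footprint_radius_px
        if (self.fov[0] < 6 * r) or (self.fov[1] < 6 * r):
            raise ValueError("field of view too small for the footprint radius")


def _place_cells(params: MiniscopeSimParams, rng) -> np.ndarray:
    """Non-edge (and, by default, non-overlapping) footprint centers."""
    r = params.footprint_radius_px
    margin = 2.5 * r
    lo_r, hi_r = margin, params.fov[0] - margin
    lo_c, hi_c = margin, params.fov[1] - margin
    centers = []
    min_sep = 2.2 * r if params.overlap_free else 0.0
    for _ in range(20_000):
        if len(centers) == params.n_cells:
            break
        cand = np.array([rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c)])
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
            centers.append(cand)
    if len(centers) < params.n_cells:
        raise ValueError(f"cannot place {params.n_cells} cells in fov {params.fov}")
    return np.array(centers)


def _disk_footprint(center, radius, fov) -> np.ndarray:
    rr, cc = np.ogrid[:fov[0], :fov[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    w = np.maximum(1.0 - d2 / radius**2, 0.0)
    return w.astype(np.float32)


def _class_schedule(cls: str, n_cs: int, amp: float) -> tuple[np.ndarray, float]:
    """Per-CS-trial transient amplitudes and US amplitude for a cell class."""
    n_early = max(1, int(np.ceil(0.6 * n_cs)))
    cs = np.zeros(n_cs)
    us = 0.0
    if cls == "gain_cs":
        cs[n_early:] = amp
    elif cls == "lose_cs":
        cs[:n_early] = amp
    elif cls == "us_only":
        us = amp
    return cs, us


def simulate_miniscope(timeline: EventTimeline,
                       params: MiniscopeSimParams | None = None
                       ) -> tuple[Movie, GroundTruth]:
    params = params or MiniscopeSimParams()
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    rate = params.frame_rate_hz
    n_frames = int(round(timeline.total_duration * rate))
    rows, cols = params.fov

    # class assignment: deterministic counts from fractions, shuffled
    counts = np.floor(np.array(params.class_fractions) * params.n_cells).astype(int)
    while counts.sum() < params.n_cells:
        counts[np.argmax(np.array(params.class_fractions) * params.n_cells - counts)] += 1
    classes = [c for c, k in zip(CELL_CLASSES, counts) for _ in range(k)]
    rng.shuffle(classes)

    centers = _place_cells(params, rng)
    footprints = np.stack([_disk_footprint(c, params.footprint_radius_px, params.fov)
                           for c in centers])

    cs_onsets = timeline.onsets("cs")
    us_onsets = timeline.onsets("us")
    kern = gcamp_kernel(rate, params.transient_rise_s, params.transient_decay_s)
    traces = np.zeros((params.n_cells, n_frames), dtype=np.float32)
    for i, cls in enumerate(classes):
        cs_amps, us_amp = _class_schedule(cls, len(cs_onsets), params.amp)
        impulses = np.zeros(n_frames)
        for onset, a in zip(cs_onsets, cs_amps):
            if a > 0:
                impulses[min(int(round(onset * rate)), n_frames - 1)] += a
        if us_amp > 0:
            for onset in us_onsets:
                impulses[min(int(round(onset * rate)), n_frames - 1)] += us_amp
        traces[i] = signal.fftconvolve(impulses, kern, mode="full")[:n_frames]

    # static scene: smooth background plus fine vessel/neuropil-like texture
    # (the texture is what rigid registration locks onto, as in real tissue)
    bg = ndimage.gaussian_filter(
        rng.normal(0, 1, params.fov), params.background_sigma_px, mode="reflect")
    if bg.std() > 0:
        bg = params.background_amp * (bg - bg.min()) / (bg.std() + 1e-12)
    tex = ndimage.gaussian_filter(
        rng.normal(0, 1, params.fov), params.texture_sigma_px, mode="reflect")
    if tex.std() > 0:
        tex = params.texture_amp * tex / tex.std()
    clean0 = (params.baseline_level + bg + tex).astype(np.float32)

    shifts = (np.cumsum(rng.normal(0, params.shift_walk_sd_px, (n_frames, 2)), axis=0)
              if params.shift_walk_sd_px > 0 else np.zeros((n_frames, 2)))

    noise_sd = params.amp / params.snr if params.snr > 0 else 0.0
    frames = np.empty((n_frames, rows, cols), dtype=np.float32)
    active = [i for i in range(params.n_cells)]
    for k in range(n_frames):
        frame = clean0.copy()
        for i in active:
            a = traces[i, k]
            if a != 0:
                frame += a * footprints[i]
        if np.any(shifts[k] != 0):
            frame = ndimage.shift(frame, shifts[k], order=1, mode="nearest")
        if noise_sd > 0:
            frame += rng.normal(0, noise_sd, (rows, cols)).astype(np.float32)
        frames[k] = frame

    truth = GroundTruth(true_shifts=shifts, true_footprints=footprints,
                        true_traces=traces, true_class=classes)
    return Movie(frames, rate), truth


# --------------------------------------------------------------------------
# tracking
# --------------------------------------------------------------------------

@dataclass
class TrackingSimParams:
    sample_rate_hz: float = 20.0
    freeze_bout_schedule: tuple[tuple[float, float], ...] = ()
    move_speed_px_s: float = 40.0
    freeze_jitter_px: float = 0.0
    arena_px: tuple[float, float] = (400.0, 400.0)
    rng_seed: int = 0

    def validate(self, duration: float) -> None:
        bouts = sorted(self.freeze_bout_schedule)
        for (a, b) in bouts:
            if not (0 <= a < b <= duration + 1e-9):
                raise ValueError(f"bout [{a}, {b}) outside session [0, {duration})")
        for (a0, b0), (a1, b1) in zip(bouts, bouts[1:]):
            if a1 < b0:
                raise ValueError("scheduled freeze bouts overlap")


def simulate_tracking(timeline: EventTimeline,
                      params: TrackingSimParams | None = None
                      ) -> tuple[TrajectorySeries, GroundTruth]:
    """Centroid track with scheduled immobility bouts.

    During a scheduled bout the per-step displacement is at most
    ``freeze_jitter_px``; elsewhere the animal moves at
    ``move_speed_px_s`` with a random-heading walk reflected at the arena
    walls.  A step counts as inside a bout only when both of its endpoint
    sample times fall within the bout, so detected bout edges match the
    schedule to within one sample.
    """
    params = params or TrackingSimParams()
    duration = timeline.total_duration
    params.validate(duration)
    rng = np.random.default_rng(params.rng_seed)
    dt = 1.0 / params.sample_rate_hz
    n = int(round(duration * params.sample_rate_hz)) + 1
    t = np.arange(n) * dt
    step_len = params.move_speed_px_s * dt

    x = np.empty(n); y = np.empty(n)
    x[0], y[0] = params.arena_px[0] / 2, params.arena_px[1] / 2
    bouts = sorted(params.freeze_bout_schedule)

    def in_bout(t0, t1):
        return any(a - 1e-9 <= t0 and t1 <= b + 1e-9 for a, b in bouts)

    heading = rng.uniform(0, 2 * np.pi)
    for i in range(1, n):
        if in_bout(t[i - 1], t[i]):
            if params.freeze_jitter_px > 0:
                ang = rng.uniform(0, 2 * np.pi)
                r = rng.uniform(0, params.freeze_jitter_px)
                dx, dy = r * np.cos(ang), r * np.sin(ang)
            else:
                dx = dy = 0.0
        else:
            heading += rng.normal(0, 0.5)
            dx, dy = step_len * np.cos(heading), step_len * np.sin(heading)
        x[i] = x[i - 1] + dx
        y[i] = y[i - 1] + dy
        # reflect at arena walls
        for arr, hi in ((x, params.arena_px[0]), (y, params.arena_px[1])):
            if arr[i] < 0:
                arr[i] = -arr[i]
            elif arr[i] > hi:
                arr[i] = 2 * hi - arr[i]
    traj = TrajectorySeries(t, x, y)
    return traj, GroundTruth(true_freeze_bouts=list(bouts))


# --------------------------------------------------------------------------
# cohort freezing tables
# --------------------------------------------------------------------------

@dataclass
class GroupDesign:
    """One experimental group: per-epoch mean and SD of freezing (%)."""

    name: str
    n: int
    epoch_means: dict
    epoch_sds: dict
    session: str = "retrieval_day2"

    def validate(self):
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        for k, sd in self.epoch_sds.items():
            if sd < 0:
                raise ValueError(f"SD for epoch {k!r} must be >= 0")


def simulate_cohort(design: list[GroupDesign], rng_seed: int = 0) -> pd.DataFrame:
    """Per-animal per-epoch freezing percentages, normal draws clipped to [0, 100]."""
    rng = np.random.default_rng(rng_seed)
    rows = []
    for g in design:
        g.validate()
        for i in range(g.n):
            aid = f"{g.name}_{i:02d}"
            for epoch, mu in g.epoch_means.items():
                sd = g.epoch_sds.get(epoch, 0.0)
                val = float(np.clip(rng.normal(mu, sd) if sd > 0 else mu, 0.0, 100.0))
                rows.append({"animal_id": aid, "group": g.name,
                             "session": g.session, "epoch": epoch, "value": val})
    return pd.DataFrame(rows)
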