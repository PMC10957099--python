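"""Dual-channel fiber-photometry preprocessing and trial-response analysis.

The recording pairs a calcium-dependent GCaMP signal (465-nm excitation)
with an isosbestic reference (405 nm) that carries photobleaching and
movement artifacts but no calcium signal.  Processing follows the usual
population-photometry chain:

1. decimate to the target rate,
2. subtract an affine least-squares fit of the reference from the signal
   (removes bleaching and shared motion artifacts), with a QC report that
   flags large reference-derivative excursions,
3. remove residual slow drift with a Gaussian low-cut filter,
4. z-score by the mean and SE (or SD) of the entire trace,
5. align to stimulus onsets and reduce each trial to a scalar response
   (response-window mean minus pre-event baseline mean).

The low-cut "cutoff" is the half-gain period of the subtract-the-smoothed-
baseline high-pass: a Gaussian smoother with standard deviation
``sigma = cutoff * sqrt(ln 2 / (2 pi^2)) ~= 0.187 * cutoff`` has gain 1/2
at the cutoff frequency, so oscillations slower than the cutoff are
strongly attenuated while a seconds-scale transient passes nearly intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .protocol import EventTimeline

__all__ = [
    "TimeSeries",
    "DualChannelRecording",
    "PhotometryParams",
    "TrialMatrix",
    "QCReport",
    "qc_and_correct_reference",
    "preprocess",
    "align_trials",
    "trial_responses",
    "gaussian_lowcut",
]

#: sigma of the Gaussian smoother whose subtract-high-pass has gain 0.5 at
#: period = cutoff:  1 - exp(-2 pi^2 sigma^2 f^2) = 0.5 at f = 1/cutoff.
LOWCUT_SIGMA_PER_CUTOFF = float(np.sqrt(np.log(2.0) / (2.0 * np.pi**2)))


@dataclass
class TimeSeries:
    """Uniformly sampled trace: start time ``t0`` (s), ``rate`` (Hz), values."""

    t0: float
    rate: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    @property
    def duration(self) -> float:
        return self.n / self.rate


@dataclass
class DualChannelRecording:
    signal: TimeSeries     # 465 nm, calcium-dependent
    reference: TimeSeries  # 405 nm, isosbestic

    def __post_init__(self):
        if (self.signal.n != self.reference.n
                or self.signal.rate != self.reference.rate
                or self.signal.t0 != self.reference.t0):
            raise ValueError("signal and reference must share length, rate and t0")


@dataclass
class PhotometryParams:
    target_rate_hz: float = 1000.0
    lowcut_cutoff_s: float = 180.0          # half-gain period, 2-4 min range
    zscore_mode: str = "se"                 # "se" (SD/sqrt(N)) or "sd"
    artifact_mad_k: float = 8.0
    response_window_s: tuple[float, float] = (0.0, 10.0)   # relative to onset
    baseline_window_s: tuple[float, float] = (-10.0, 0.0)

    def validate(self) -> None:
        if self.target_rate_hz <= 0 or self.lowcut_cutoff_s <= 0:
            raise ValueError("rates and cutoffs must be > 0")
        if self.zscore_mode not in ("se", "sd"):
            raise ValueError("zscore_mode must be 'se' or 'sd'")
        if not (120.0 <= self.lowcut_cutoff_s <= 240.0):
            # stated working range; deliberate overrides are allowed but loud
            import warnings
            warnings.warn(
                f"lowcut_cutoff_s={self.lowcut_cutoff_s} outside the usual 120-240 s range",
                stacklevel=2)


@dataclass
class QCReport:
    """Artifact QC of the isosbestic reference.

    ``flagged_segments`` are (start, end) times (s) where the reference
    derivative exceeded ``artifact_mad_k`` x MAD; ``discard_recommended``
    is set when a flagged segment overlaps a CS or US event.
    """

    flagged_segments: list[tuple[float, float]] = field(default_factory=list)
    discard_recommended: bool = False
    fit_slope: float = 0.0
    fit_intercept: float = 0.0


@dataclass
class TrialMatrix:
    """Event-aligned trials: row k = samples on [onset_k - pre_s, onset_k + post_s)."""

    data: np.ndarray          # (n_trials, n_samples)
    rate: float
    pre_s: float
    post_s: float
    label: str

    @property
    def onset_column(self) -> int:
        return int(round(self.pre_s * self.rate))

    @property
    def time(self) -> np.ndarray:
        return (np.arange(self.data.shape[1]) - self.onset_column) / self.rate


def gaussian_lowcut(values: np.ndarray, rate: float, cutoff_s: float) -> np.ndarray:
    """High-pass by subtracting a Gaussian-smoothed baseline.

    ``cutoff_s`` is the half-gain period; the smoother sigma is
    ``LOWCUT_SIGMA_PER_CUTOFF * cutoff_s`` seconds.  Uses FFT convolution
    with reflect padding so very long sigmas stay O(N log N).
    """
    x = np.asarray(values, dtype=float)
    sigma = LOWCUT_SIGMA_PER_CUTOFF * cutoff_s * rate  # in samples
    if sigma <= 0:
        raise ValueError("cutoff must be > 0")
    half = int(min(np.ceil(4 * sigma), x.size - 1))
    k = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (k / sigma) ** 2)
    kernel /= kernel.sum()
    xp = np.pad(x, half, mode="reflect")
    smooth = signal.fftconvolve(xp, kernel, mode="same")[half:-half]
    return x - smooth


def _decimate(ts: TimeSeries, target_rate: float) -> TimeSeries:
    if ts.rate < target_rate - 1e-9:
        raise ValueError(f"trace rate {ts.rate} Hz below target {target_rate} Hz")
    factor = ts.rate / target_rate
    q = int(round(factor))
    if abs(factor - q) > 1e-6:
        raise ValueError("rate must be an integer multiple of target_rate_hz")
    if q == 1:
        return TimeSeries(ts.t0, ts.rate, ts.values.copy())
    out = signal.decimate(ts.values, q, ftype="fir", zero_phase=True)
    return TimeSeries(ts.t0, ts.rate / q, out)


def qc_and_correct_reference(rec: DualChannelRecording,
                             params: PhotometryParams | None = None,
                             timeline: EventTimeline | None = None
                             ) -> tuple[TimeSeries, QCReport]:
    """Fit the reference to the signal (affine least squares) and subtract it.

    Removes bleaching and motion artifacts shared between channels.  The QC
    report flags reference-derivative excursions beyond
    ``artifact_mad_k x MAD`` and, when a timeline is supplied, recommends
    discarding the recording if a flagged segment overlaps a CS or US event.
    Discard is always a recommendation — nothing is deleted.
    """
    params = params or PhotometryParams()
    sig, ref = rec.signal.values, rec.reference.values
    if np.std(ref) == 0:
        raise ValueError("reference has zero variance; affine fit undefined")
    # trimmed least squares: calcium transients live only in the signal and
    # would bias a plain fit upward, so refit on the lower-residual half
    slope, intercept = np.polyfit(ref, sig, 1)
    for _ in range(3):
        resid = sig - (slope * ref + intercept)
        keep = resid <= np.median(resid)
        if keep.sum() < 2 or np.std(ref[keep]) == 0:
            break
        slope, intercept = np.polyfit(ref[keep], sig[keep], 1)
    corrected = sig - (slope * ref + intercept)

    report = QCReport(fit_slope=float(slope), fit_intercept=float(intercept))
    d = np.diff(ref)
    mad = np.median(np.abs(d - np.median(d)))
    if mad > 0:
        bad = np.abs(d - np.median(d)) > params.artifact_mad_k * mad
        if bad.any():
            edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
            rate, t0 = rec.reference.rate, rec.reference.t0
            for i0, i1 in zip(edges[::2], edges[1::2]):
                report.flagged_segments.append(
                    (t0 + i0 / rate, t0 + (i1 + 1) / rate))
    if timeline is not None and report.flagged_segments:
        stim = timeline.by_label("cs") + timeline.by_label("us")
        for s0, s1 in report.flagged_segments:
            if any(e.start < s1 and s0 < e.end for e in stim):
                report.discard_recommended = True
                break
    return TimeSeries(rec.signal.t0, rec.signal.rate, corrected), report


def preprocess(ts: TimeSeries, params: PhotometryParams | None = None) -> TimeSeries:
    """Decimate, remove slow drift, and z-score a photometry trace.

    The z-score divides the zero-mean detrended trace by its SE
    (``SD/sqrt(N)``, the literal whole-trace convention; note the output
    magnitude then scales with sqrt(N)) or by its SD (``zscore_mode="sd"``).
    """
    params = params or PhotometryParams()
    params.validate()
    out = _decimate(ts, params.target_rate_hz)
    detrended = gaussian_lowcut(out.values, out.rate, params.lowcut_cutoff_s)
    sd = detrended.std()
    scale_floor = 1e-10 * max(np.abs(out.values).max(), 1.0)
    if sd <= scale_floor:
        raise ValueError("zero variance after detrending; z-score undefined")
    scale = sd / np.sqrt(detrended.size) if params.zscore_mode == "se" else sd
    z = (detrended - detrended.mean()) / scale
    return TimeSeries(out.t0, out.rate, z)


def align_trials(ts: TimeSeries, timeline: EventTimeline, label: str,
                 pre_s: float, post_s: float) -> TrialMatrix:
    """Extract one row per ``label`` event: samples on [onset - pre, onset + post)."""
    events = timeline.by_label(label)
    if not events:
        raise ValueError(f"timeline has no {label!r} events")
    n_pre = int(round(pre_s * ts.rate))
    n_post = int(round(post_s * ts.rate))
    rows = []
    for e in events:
        i_on = int(round((e.start - ts.t0) * ts.rate))
        i0, i1 = i_on - n_pre, i_on + n_post
        if i0 < 0 or i1 > ts.n:
            raise ValueError(
                f"window [{e.start - pre_s}, {e.start + post_s}) outside trace")
        rows.append(ts.values[i0:i1])
    return TrialMatrix(np.vstack(rows), ts.rate, pre_s, post_s, label)


def trial_responses(tm: TrialMatrix, params: PhotometryParams | None = None,
                    delta: bool = False, reference_scalar: float | None = None
                    ) -> pd.DataFrame:
    """Reduce each aligned trial to a scalar response.

    response = mean over ``response_window_s`` minus mean over
    ``baseline_window_s`` (both relative to onset).  With ``delta=True``
    the first trial's scalar (or ``reference_scalar``, e.g. day-1 trial 1
    when normalizing a retrieval session) is subtracted from every trial,
    so the reference trial maps to zero.
    """
    params = params or PhotometryParams()
    t = tm.time

    def window_mean(lo, hi):
        m = (t >= lo - 1e-9) & (t < hi - 1e-9)
        if not m.any():
            raise ValueError(f"window [{lo}, {hi}) outside aligned range")
        return tm.data[:, m].mean(axis=1)

    r_lo, r_hi = params.response_window_s
    b_lo, b_hi = params.baseline_window_s
    if r_lo < t[0] or b_lo < t[0] or r_hi > t[-1] + 1 / tm.rate or b_hi > t[-1] + 1 / tm.rate:
        raise ValueError("response/baseline window exceeds the aligned window")
    resp = window_mean(r_lo, r_hi) - window_mean(b_lo, b_hi)
    df = pd.DataFrame({"trial": np.arange(len(resp)), "response": resp})
    if delta:
        ref = resp[0] if reference_scalar is None else reference_scalar
        df["delta"] = resp - ref
    return df
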