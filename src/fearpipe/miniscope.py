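"""Miniscope movie analysis: background subtraction, iterative rigid motion
correction, seeded source extraction, ROI quality filtering, and CS-response
classification.

Motion correction is translational only.  Shift estimation runs on a
background-subtracted copy of the movie (one-photon movies are dominated by
smooth background) inside a user-chosen ROI, using FFT phase correlation
with sub-pixel refinement; the estimated shifts are applied to the *raw*
frames so later trace extraction sees unfiltered data.  A second ROI is
re-registered on the corrected movie as an independent check that no (or
only little) non-rigid motion remains.

Source extraction is deliberately over-inclusive (false positives are cheap
— they are removed by `filter_components`): seeds are local maxima of the
product of a neighbor-correlation image and a peak-to-noise map, and each
seed grows a rank-1 (footprint x trace) factorization of its local patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation

from .photometry import TimeSeries
from .protocol import EventTimeline

__all__ = [
    "Movie",
    "ShiftTrace",
    "Component",
    "RoiFilterParams",
    "ClassifyParams",
    "ExtractionParams",
    "background_subtract",
    "motion_correct",
    "extract_components",
    "filter_components",
    "classify_cs_cells",
    "cs_trial_activity",
]


@dataclass
class Movie:
    frames: np.ndarray   # (n_frames, rows, cols)
    frame_rate: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, rows, cols)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def fov(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class ShiftTrace:
    """Estimated per-frame rigid displacement (d_row, d_col), pixels.

    ``shifts[k]`` is the displacement of frame k relative to the template;
    correction applies ``-shifts[k]``.  ``convergence_history`` holds the
    mean applied shift magnitude per iteration; ``converged`` is True when
    the final iteration's mean applied shift fell below tolerance.
    """

    shifts: np.ndarray                      # (n_frames, 2)
    convergence_history: list[float] = field(default_factory=list)
    converged: bool = True


@dataclass
class Component:
    """One candidate neuron: spatial footprint + activity trace + QC metrics."""

    footprint: np.ndarray          # (rows, cols), weights >= 0
    trace: TimeSeries | None
    snr: float
    _support: np.ndarray | None = None

    @property
    def support(self) -> np.ndarray:
        if self._support is None:
            self._support = self.footprint > 0
        return self._support

    @property
    def area_frac(self) -> float:
        return self.support.sum() / self.footprint.size

    @property
    def eccentricity(self) -> float:
        """Eccentricity of the weighted second-moment ellipse (0 round, ->1 elongated)."""
        w = self.footprint
        total = w.sum()
        if total == 0:
            return 0.0
        r, c = np.nonzero(w)
        ww = w[r, c] / total
        mr, mc = (ww * r).sum(), (ww * c).sum()
        crr = (ww * (r - mr) ** 2).sum()
        ccc = (ww * (c - mc) ** 2).sum()
        crc = (ww * (r - mr) * (c - mc)).sum()
        tr, det = crr + ccc, crr * ccc - crc**2
        disc = max(tr**2 / 4 - det, 0.0)
        l1 = tr / 2 + np.sqrt(disc)
        l2 = tr / 2 - np.sqrt(disc)
        if l1 <= 0:
            return 0.0
        return float(np.sqrt(max(1 - l2 / l1, 0.0)))


# --------------------------------------------------------------------------
# preprocessing and motion correction
# --------------------------------------------------------------------------

def background_subtract(movie: Movie, blur_sigma_px: float = 8.0) -> Movie:
    """Subtract each frame's own Gaussian-blurred copy (removes smooth background)."""
    if blur_sigma_px <= 0:
        raise ValueError("blur_sigma_px must be > 0")
    out = np.empty_like(movie.frames, dtype=np.float32)
    for k in range(movie.n_frames):
        out[k] = movie.frames[k] - ndimage.gaussian_filter(
            movie.frames[k].astype(np.float32), blur_sigma_px, mode="reflect")
    return Movie(out, movie.frame_rate)


def _as_slices(roi, fov) -> tuple[slice, slice]:
    r0, r1, c0, c1 = roi
    if not (0 <= r0 < r1 <= fov[0] and 0 <= c0 < c1 <= fov[1]):
        raise ValueError(f"ROI {roi} outside field of view {fov}")
    return slice(r0, r1), slice(c0, c1)


def _register(template: np.ndarray, frame: np.ndarray, window: np.ndarray,
              upsample: int) -> np.ndarray:
    # mean-subtract before windowing: a DC offset times the fixed window is
    # identical in both images and would bias the peak toward zero shift
    shift, _, _ = phase_cross_correlation(
        (template - template.mean()) * window,
        (frame - frame.mean()) * window,
        upsample_factor=upsample, normalization=None)
    return shift


def _apply_shift(frame: np.ndarray, shift: np.ndarray, fill: float) -> np.ndarray:
    if np.all(shift == 0):
        return frame.astype(np.float32, copy=True)
    return ndimage.shift(frame.astype(np.float32), shift, order=1,
                         mode="constant", cval=fill)


def motion_correct(movie: Movie, roi1, roi2=None, tol_px: float = 0.01,
                   template_frames: int = 100, max_iter: int = 8,
                   blur_sigma_px: float | None = 8.0, upsample: int = 20,
                   roi2_warn_px: float = 0.5
                   ) -> tuple[Movie, ShiftTrace, dict]:
    """Iterative rigid motion correction by FFT phase correlation.

    Each iteration: (a) register the first ``template_frames`` frames
    (within ``roi1``, on the background-subtracted movie) to frame 0,
    (b) take their median as template, (c) register every frame to the
    template and accumulate the corrections; iterate until the mean applied
    shift magnitude drops below ``tol_px`` (typically < 0.01 px) or
    ``max_iter``.  Cumulative corrections are applied to the raw frames,
    filled with the frame median outside the field of view.

    ``roi2`` (optional) is re-registered on the corrected movie as an
    independent rigidity check; the report warns when its mean residual
    shift magnitude exceeds ``roi2_warn_px``.
    """
    n = movie.n_frames
    if template_frames > n:
        raise ValueError("template_frames exceeds frame count")
    sl1 = _as_slices(roi1, movie.fov)
    est_movie = (background_subtract(movie, blur_sigma_px).frames
                 if blur_sigma_px else movie.frames.astype(np.float32))
    patch_shape = est_movie[0][sl1].shape
    win = np.outer(np.hanning(patch_shape[0]),
                   np.hanning(patch_shape[1])).astype(np.float32)

    corrections = np.zeros((n, 2))
    history: list[float] = []
    converged = False
    cur_patches = np.ascontiguousarray(est_movie[:, sl1[0], sl1[1]])
    if cur_patches[0].std() == 0:
        raise ValueError("degenerate (flat) registration template")
    fill_est = float(np.median(est_movie[0]))

    for _ in range(max_iter):
        # (a) align first template_frames patches to patch 0
        head = [cur_patches[0]]
        for k in range(1, template_frames):
            s = _register(cur_patches[0], cur_patches[k], win, upsample)
            head.append(_apply_shift(cur_patches[k], s, fill_est))
        # (b) median template
        template = np.median(np.stack(head), axis=0)
        if template.std() == 0:
            raise ValueError("degenerate (flat) registration template")
        # (c) register all frames to the template; increments below half the
        # sub-pixel quantization step are treated as zero (prevents limit
        # cycles between adjacent quantized estimates)
        inc = np.array([_register(template, cur_patches[k], win, upsample)
                        for k in range(n)])
        inc[np.abs(inc) < 0.5 / upsample] = 0.0
        corrections += inc
        mean_applied = float(np.linalg.norm(inc, axis=1).mean())
        history.append(mean_applied)
        if mean_applied < tol_px:
            converged = True
            break
        cur_patches = np.stack([_apply_shift(est_movie[k][sl1], corrections[k], fill_est)
                                for k in range(n)])

    corrected = np.empty_like(movie.frames, dtype=np.float32)
    for k in range(n):
        fill = float(np.median(movie.frames[k]))
        corrected[k] = _apply_shift(movie.frames[k], corrections[k], fill)

    trace = ShiftTrace(shifts=-corrections, convergence_history=history,
                       converged=converged)

    report = {"roi2_checked": False, "roi2_mean_residual_px": 0.0,
              "roi2_nonrigid_warning": False, "converged": converged}
    if roi2 is not None:
        sl2 = _as_slices(roi2, movie.fov)
        est2 = (background_subtract(Movie(corrected, movie.frame_rate),
                                    blur_sigma_px).frames
                if blur_sigma_px else corrected)
        p2 = est2[:, sl2[0], sl2[1]]
        w2 = np.outer(np.hanning(p2.shape[1]), np.hanning(p2.shape[2])).astype(np.float32)
        t2 = np.median(p2[:template_frames], axis=0)
        res = np.array([_register(t2, p2[k], w2, upsample) for k in range(n)])
        mean_res = float(np.linalg.norm(res, axis=1).mean())
        report.update(roi2_checked=True, roi2_mean_residual_px=mean_res,
                      roi2_nonrigid_warning=mean_res > roi2_warn_px)
    return Movie(corrected, movie.frame_rate), trace, report


# --------------------------------------------------------------------------
# source extraction
# --------------------------------------------------------------------------

@dataclass
class ExtractionParams:
    """Seeded rank-1 extraction; thresholds are permissive by design."""

    patch_radius_px: int = 12
    corr_thresh: float = 0.4
    pnr_thresh: float = 4.0
    min_distance_px: int = 8
    max_components: int = 200
    n_als_iter: int = 5
    weight_floor_frac: float = 0.2   # footprint weights below this x max -> 0


def _neighbor_correlation(frames: np.ndarray) -> np.ndarray:
    x = frames - frames.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.inf
    xn = x / sd
    corr = np.zeros(frames.shape[1:])
    cnt = np.zeros(frames.shape[1:])
    right = (xn[:, :, :-1] * xn[:, :, 1:]).mean(axis=0)
    down = (xn[:, :-1, :] * xn[:, 1:, :]).mean(axis=0)
    corr[:, :-1] += right; cnt[:, :-1] += 1
    corr[:, 1:] += right;  cnt[:, 1:] += 1
    corr[:-1, :] += down;  cnt[:-1, :] += 1
    corr[1:, :] += down;   cnt[1:, :] += 1
    return corr / cnt


def _pnr(frames: np.ndarray) -> np.ndarray:
    med = np.median(frames, axis=0)
    mad = np.median(np.abs(frames - med), axis=0) * 1.4826
    mad[mad == 0] = np.inf
    return (frames.max(axis=0) - med) / mad


def _trace_snr(trace: np.ndarray) -> float:
    med = np.median(trace)
    mad = np.median(np.abs(trace - med)) * 1.4826
    if mad == 0:
        return np.inf if trace.max() > med else 0.0
    return float((trace.max() - med) / mad)


def extract_components(movie: Movie,
                       params: ExtractionParams | None = None
                       ) -> list[Component]:
    """Over-inclusive seeded source extraction.

    Seeds are local maxima of (neighbor-correlation x peak-to-noise); each
    seed's local patch is factorized as footprint x trace by a few rounds
    of non-negative alternating least squares.  Expect false positives —
    `filter_components` removes them.
    """
    params = params or ExtractionParams()
    if movie.n_frames == 0:
        raise ValueError("empty movie")
    frames = movie.frames.astype(np.float32)
    score = _neighbor_correlation(frames) * _pnr(frames)
    thresh = params.corr_thresh * params.pnr_thresh
    seeds = peak_local_max(score, min_distance=params.min_distance_px,
                           threshold_abs=thresh, num_peaks=params.max_components)
    rows, cols = movie.fov
    rad = params.patch_radius_px
    comps: list[Component] = []
    for (sr, sc) in seeds:
        r0, r1 = max(0, sr - rad), min(rows, sr + rad + 1)
        c0, c1 = max(0, sc - rad), min(cols, sc + rad + 1)
        patch = frames[:, r0:r1, c0:c1].reshape(movie.n_frames, -1)
        patch = patch - np.median(patch, axis=0)
        t = patch[:, (sr - r0) * (c1 - c0) + (sc - c0)].copy()
        f = None
        for _ in range(params.n_als_iter):
            denom = float(t @ t)
            if denom == 0:
                break
            f = np.maximum(patch.T @ t / denom, 0.0)
            f[f < params.weight_floor_frac * f.max()] = 0.0
            denom_f = float(f @ f)
            if denom_f == 0:
                break
            t = patch @ f / denom_f
        if f is None or f.max() == 0:
            continue
        full = np.zeros((rows, cols), dtype=np.float32)
        full[r0:r1, c0:c1] = f.reshape(r1 - r0, c1 - c0)
        comps.append(Component(
            footprint=full,
            trace=TimeSeries(0.0, movie.frame_rate, t),
            snr=_trace_snr(t)))
    return comps


# --------------------------------------------------------------------------
# ROI quality filtering
# --------------------------------------------------------------------------

@dataclass
class RoiFilterParams:
    """ROI exclusion rules.

    Size bounds are fractions of field-of-view pixels (reject < 0.6% or
    > 1.4%); ``edge_margin_px=None`` uses each component's equivalent
    radius; the shape rule bounds eccentricity (round or slightly
    elongated contours pass); pairs overlapping >= ``overlap_frac`` (of the
    smaller support) drop the lower-SNR member when its SNR is below
    ``snr_min``.
    """

    min_area_frac: float = 0.006
    max_area_frac: float = 0.014
    edge_margin_px: float | None = None
    overlap_frac: float = 0.60
    snr_min: float = 5.0
    eccentricity_max: float = 0.95


def _touches_edge(support: np.ndarray, margin: float) -> bool:
    r, c = np.nonzero(support)
    rows, cols = support.shape
    return bool((r < margin).any() or (c < margin).any()
                or (r >= rows - margin).any() or (c >= cols - margin).any())


def filter_components(components: list[Component], fov: tuple[int, int],
                      params: RoiFilterParams | None = None
                      ) -> tuple[list[Component], list[tuple[Component, str]]]:
    """Apply the ROI exclusion rules; every rejection carries a reason code.

    Order: size ("too_small"/"too_big"), edge ("edge"), shape ("shape"),
    then the pairwise overlap/SNR rule ("overlap_low_snr") resolved in
    descending-SNR order, and finally a standalone SNR floor ("low_snr")
    that removes any remaining component below ``snr_min`` — extraction is
    deliberately over-inclusive, and a noise-driven candidate need not
    overlap a real cell.  Overlap = |A∩B| / min(|A|, |B|).
    """
    params = params or RoiFilterParams()
    survivors: list[Component] = []
    rejected: list[tuple[Component, str]] = []
    for comp in components:
        if comp.footprint.shape != tuple(fov):
            raise ValueError("component footprint does not match field of view")
        af = comp.area_frac
        if af < params.min_area_frac:
            rejected.append((comp, "too_small")); continue
        if af > params.max_area_frac:
            rejected.append((comp, "too_big")); continue
        margin = (params.edge_margin_px if params.edge_margin_px is not None
                  else np.sqrt(comp.support.sum() / np.pi))
        if _touches_edge(comp.support, margin):
            rejected.append((comp, "edge")); continue
        if comp.eccentricity > params.eccentricity_max:
            rejected.append((comp, "shape")); continue
        survivors.append(comp)

    # overlap/SNR rule: visit candidates from lowest SNR up; reject a
    # low-SNR member that overlaps any higher-SNR survivor.
    order = sorted(range(len(survivors)), key=lambda i: survivors[i].snr)
    alive = {i: True for i in range(len(survivors))}
    for i in order:
        ci = survivors[i]
        if ci.snr >= params.snr_min:
            continue
        for j in range(len(survivors)):
            if j == i or not alive[j]:
                continue
            cj = survivors[j]
            if cj.snr < ci.snr or (cj.snr == ci.snr and j > i):
                continue
            inter = np.logical_and(ci.support, cj.support).sum()
            denom = min(ci.support.sum(), cj.support.sum())
            if denom > 0 and inter / denom >= params.overlap_frac:
                alive[i] = False
                rejected.append((ci, "overlap_low_snr"))
                break
    for i in range(len(survivors)):
        if alive[i] and survivors[i].snr < params.snr_min:
            alive[i] = False
            rejected.append((survivors[i], "low_snr"))
    kept = [survivors[i] for i in range(len(survivors)) if alive[i]]
    return kept, rejected


# --------------------------------------------------------------------------
# CS-plasticity classification
# --------------------------------------------------------------------------

@dataclass
class ClassifyParams:
    """CS-response plasticity criterion.

    Conditioning: a cell is "up" when its mean CS activity over the late
    trials reaches at least ``threshold_sd`` reference SDs above the mean
    of the early trials (SD pooled over the per-sample activity values of
    the reference trials; configurable to the SD of per-trial means).
    "down" mirrors the rule.  Retrieval compares the mean of trials 1-5
    against the baseline period.  Trial numbers are 1-based.
    """

    threshold_sd: float = 2.0
    fc_early_trials: tuple[int, ...] = (1, 2, 3)
    fc_late_trials: tuple[int, ...] = (4, 5)
    retrieval_trials: tuple[int, ...] = (1, 2, 3, 4, 5)
    sd_over: str = "samples"   # "samples" | "trial_means"


def cs_trial_activity(trace: TimeSeries, timeline: EventTimeline,
                      label: str = "cs") -> list[np.ndarray]:
    """Per-trial arrays of trace samples within each ``label`` event window."""
    out = []
    for e in timeline.by_label(label):
        i0 = int(round((e.start - trace.t0) * trace.rate))
        i1 = int(round((e.end - trace.t0) * trace.rate))
        i0, i1 = max(i0, 0), min(i1, trace.n)
        if i1 <= i0:
            raise ValueError(f"event [{e.start}, {e.end}) outside trace")
        out.append(trace.values[i0:i1])
    return out


def baseline_activity(trace: TimeSeries, timeline: EventTimeline) -> np.ndarray:
    bl = timeline.by_label("baseline")
    if not bl:
        raise ValueError("timeline has no baseline event")
    e = bl[0]
    i0 = int(round((e.start - trace.t0) * trace.rate))
    i1 = min(int(round((e.end - trace.t0) * trace.rate)), trace.n)
    return trace.values[max(i0, 0):i1]


def classify_cs_cells(trial_activity: list[np.ndarray], session: str,
                      params: ClassifyParams | None = None,
                      baseline_samples: np.ndarray | None = None
                      ) -> tuple[str, dict]:
    """Classify one cell's CS-response plasticity: "up", "down", or "none".

    ``trial_activity[k]`` holds the activity samples of trial k+1's CS
    window.  Conditioning sessions compare late-trial to early-trial CS
    activity; retrieval compares CS activity of trials 1-5 to the baseline
    period (``baseline_samples`` required).  A zero reference SD is
    degenerate: the cell is "none" and the flag is set.
    """
    params = params or ClassifyParams()
    conditioning = session in ("fc_day1", "fc_day3")

    def trial_means(indices):
        out = []
        for i in indices:
            if i - 1 >= len(trial_activity):
                raise ValueError(f"trial {i} missing (have {len(trial_activity)})")
            out.append(float(np.mean(trial_activity[i - 1])))
        return np.array(out)

    if conditioning:
        ref_idx, test_idx = params.fc_early_trials, params.fc_late_trials
        ref_samples = np.concatenate([trial_activity[i - 1] for i in ref_idx])
        ref_mean = float(trial_means(ref_idx).mean())
    else:
        if baseline_samples is None:
            raise ValueError("retrieval classification requires baseline_samples")
        test_idx = params.retrieval_trials
        ref_samples = np.asarray(baseline_samples, dtype=float)
        ref_mean = float(ref_samples.mean())
    test_mean = float(trial_means(test_idx).mean())

    if params.sd_over == "trial_means" and conditioning:
        sd = float(trial_means(ref_idx).std(ddof=1))
    else:
        sd = float(np.std(ref_samples, ddof=1)) if ref_samples.size > 1 else 0.0

    flags = {"zero_reference_sd": sd == 0, "excess_sd": np.nan}
    if sd == 0:
        return "none", flags
    excess = (test_mean - ref_mean) / sd
    flags["excess_sd"] = excess
    # the threshold itself counts as responsive (boundary inclusive)
    if excess >= params.threshold_sd:
        return "up", flags
    if excess <= -params.threshold_sd:
        return "down", flags
    return "none", flags
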