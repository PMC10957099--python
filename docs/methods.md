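# Methods

This note documents the models, parameter choices, and numerical decisions
behind `fearpipe`, and what the synthetic-data experiments do and do not
establish about real recordings.

## Session timelines

A session is an ordered list of labeled half-open intervals `[start, end)`
in seconds. The conditioning day consists of a 120-s baseline followed by
five CS–US pairings; retrieval presents eight CS alone after the baseline.
Each CS is a 10-s pip train: pip onsets at `k / 0.9` s for all `k` with
`onset + 0.2 ≤ 10`, i.e. nine 200-ms pips. The US (2 s, 0.65 mA, metadata
only — nothing is rendered) starts exactly at the offset of the last pip.
Inter-trial intervals are drawn uniformly from 35–60 s, measured CS offset
to next CS onset; the reference points are a package choice, as is
continuous (rather than discretized) sampling. Timelines are pure functions
of `(session, params)` including the seed, and serialize to JSON
byte-identically across runs. Optogenetic laser windows cover CS or CS+US
with a configurable pad (default 0 s — the protocol requires only that the
stimuli be covered).

## Photometry

**Model.** The 465-nm channel carries GCaMP signal plus bleaching and
movement artifacts; the 405-nm isosbestic channel carries the same
bleaching/artifacts but no calcium signal. Correction fits the reference to
the signal by affine least squares and subtracts the fit. Two details
matter:

- *Trimmed fit.* Calcium transients are present only in the signal and
  would bias a plain regression upward. The fit is therefore iterated three
  times, each round refitting on the samples whose residual lies at or
  below the median. With sparse transients this converges onto
  transient-free samples; in the noiseless affine case the recovery is
  exact up to an additive constant.
- *QC, not deletion.* Reference-derivative excursions beyond
  `artifact_mad_k × MAD` (default 8) are flagged as segments; if any
  segment overlaps a CS or US event the recording is marked
  discard-recommended. Nothing is silently dropped.

**Low-cut detrending.** Slow drift is removed by subtracting a
Gaussian-smoothed copy of the trace. The user-facing `lowcut_cutoff_s`
(default 180 s, working range 120–240 s) is the *half-gain period* of the
resulting high-pass: the smoother's standard deviation is
`σ = cutoff · sqrt(ln 2 / (2π²)) ≈ 0.187 · cutoff` (≈ 33.7 s at the
default), chosen so that the filter's gain `1 − exp(−2π²σ²f²)` equals 1/2
at `f = 1/cutoff`. This is the standard reading of a filter "cutoff"; with
it, a 20-min oscillation is attenuated by ≈ 98 % while a 10-s transient
keeps > 80 % of its peak. (Interpreting the cutoff directly as σ would
attenuate the same oscillation by only ~36 % and would not act as a low-cut
filter at these time scales.) Smoothing uses FFT convolution with reflect
padding; edge segments within ~4σ of the trace ends carry boundary
artifacts, so quantitative statements are made about interior samples.

**Z-scoring.** The detrended trace is centred and divided by its SE
(`SD/√N`, the literal whole-trace convention) by default, with `sd` mode
available. SE normalization makes the output magnitude grow with `√N`;
this is flagged in the API docs and does not affect trial *comparisons*,
which are ratios/differences within one trace.

**Trial analysis.** Rows of the trial matrix are nearest-sample aligned to
event onsets. The per-trial scalar is the response-window mean (default:
the full 10-s CS interval) minus the pre-event baseline mean (default 10 s
before onset, matching the visualization convention of baselining to the
10 s preceding the CS). Delta mode subtracts the first trial's scalar
(or an explicit day-1 trial-1 reference), so the reference trial maps to 0.

## Miniscope

**Background subtraction.** Each frame minus its own Gaussian-blurred copy
(default σ = 8 px). One-photon movies are dominated by smooth background;
this flattens it while preserving cell-scale structure.

**Motion correction.** Translational only. Shifts are estimated on the
background-subtracted movie inside a user ROI and applied to the *raw*
frames (extraction must see unfiltered data). Each iteration (a) registers
the first `template_frames` (default 100) ROI patches to frame 0, (b) takes
their median as template, (c) registers every frame to the template with
`skimage.registration.phase_cross_correlation` (upsample factor 20 →
0.05-px quantization) and accumulates the corrections, stopping when the
mean applied shift magnitude falls below `tol_px` (default 0.01 px).
Numerical details:

- patches are mean-subtracted and Hann-windowed before the FFT: a DC
  offset times the fixed window is identical in both images and biases the
  correlation peak toward zero shift; the window also suppresses the
  spectral leakage of the non-periodic patch boundary.
- increments smaller than half the sub-pixel quantization step are treated
  as zero, which prevents limit cycles between adjacent quantized
  estimates and lets the iteration genuinely converge.
- out-of-frame pixels after shifting are filled with the frame median and
  the filled margin is irrelevant to the central registration ROI.
- a second ROI is re-registered on the corrected movie as an independent
  rigidity check; a mean residual above `roi2_warn_px` (default 0.5 px)
  raises a non-rigid-motion warning. No non-rigid correction is attempted.

On simulated rigid random walks (integer and sub-pixel, 500-frame
200×200 movies) recovery error is ≈ 0.02–0.03 px RMS, and converged runs
end below 0.01 px mean applied shift.

**Source extraction.** A deliberately over-inclusive seeded method (a full
constrained-NMF pipeline is out of scope): seeds are local maxima of the
product of a 4-neighbor temporal-correlation image and a peak-to-noise map
(`(max − median)/MAD`); each seed's patch is factorized as footprint ×
trace by five rounds of non-negative alternating least squares, with
footprint weights below 20 % of the patch maximum zeroed. Trace SNR is
`(peak − median)/(1.4826 · MAD)`. False positives are expected and removed
downstream.

**ROI filtering.** Rules applied in order, each rejection carrying a reason
code: area fraction outside [0.6 %, 1.4 %] of pixels (`too_small` /
`too_big`); any support pixel within `edge_margin_px` of the border
(default: the component's equivalent radius — the protocol gives no
number) (`edge`); eccentricity of the weighted second-moment ellipse above
0.95, standing in for manual inspection of "round or slightly elongated"
contours (`shape`); for pairs overlapping ≥ 60 % (denominator: the smaller
support), the lower-SNR member is rejected when its SNR is below the floor,
resolved in descending-SNR order (`overlap_low_snr`); finally any remaining
component below the SNR floor is rejected outright (`low_snr`) — with an
over-inclusive extractor, noise-driven candidates need not overlap a real
cell, and without this last rule they would survive. The floor defaults to
5.0: a pure-Gaussian-noise trace has peak/MAD ≈ 3.5 nearly independent of
length, while genuine transients sit far above; the filter equals a
brute-force restatement of these rules on 1000 randomized component sets.

**CS-plasticity classification.** Activity = mean trace value inside each
CS window. Conditioning: a cell is *up* when `mean(trials 4–5) ≥
mean(trials 1–3) + 2 × SD(reference)`; *down* by the mirror rule (the down
rule is symmetric by construction; only the up criterion is printed in the
protocol this mirrors). Retrieval compares the mean of trials 1–5 against
the baseline period. The reference SD is computed over the per-sample
activity values pooled across the reference trials' CS windows
(`sd_over="samples"`), configurable to the SD of per-trial means
(`"trial_means"`). The boundary is inclusive: an excess of exactly the
threshold counts as responsive, making the stated threshold the infimum of
the responsive set. Zero reference SD is degenerate → `none`, flagged. Note
an asymmetry that the simulations make visible: cells that *lose* a CS
response have large transients inside their own reference trials, so the
pooled-sample SD is large and the mirror rule rarely fires in `samples`
mode; `trial_means` mode resolves them.

## Freezing

A step between consecutive samples is immobile when the centroid
displacement is ≤ `motion_threshold_px` (default 1.0 px — the tracker's
movement metric is not specified by the protocol; the default is calibrated
on the simulator, where immobility jitter is well below and locomotion
steps well above it). Maximal runs of immobile steps lasting ≥ 2.0 s become
bouts, with boundaries at the first/last immobile sample; a 1.9-s run is
not freezing. No gap merging by default (`smoothing_window_s = 0`,
configurable). Per-epoch scores are `100 × |bout ∩ epoch| / |epoch|`; a
bout straddling an epoch boundary contributes only its overlap.

## Statistics

- **Rank sum**: exact two-sided permutation null (full enumeration,
  ≤ C(12,6) = 924 arrangements) when the combined sample is ≤ 12 and
  tie-free; otherwise mid-ranks with the tie-corrected normal
  approximation (`scipy.stats.mannwhitneyu`). The method tag records the
  path taken. p is invariant under strictly monotone transforms.
- **Paired t**: classical two-sided test on differences, n−1 df;
  zero-variance differences are an error, not a silent p = 1.
- **Dunnett**: pooled-variance many-to-one t statistics; adjusted p =
  `P(max_j |T_j| ≥ |t_i|)` under the joint equicorrelated multivariate-t
  null, evaluated by seeded Monte Carlo (default 200,000 draws in chunks;
  replicate-seed SD of p < 0.002). At k = 1 it reduces to the plain pooled
  t within Monte Carlo tolerance; against an independent quadrature-based
  reference it agrees within 0.005.
- **Bootstrap**: resampling within groups with replacement. The p-value is
  studentized (bootstrap-t): resampled differences are centered at the
  observed difference and scaled by their own SE, and p is the fraction of
  |t*| at or beyond the observed |t|. The naive percentile-sign p
  (2·min(frac ≤ 0, ≥ 0)) is anti-conservative at these group sizes
  (measured type-I ≈ 0.08 at nominal 0.05 for n = 10 + 10) because the
  bootstrap SE underestimates by √((n−1)/n) and implies normal rather than
  t quantiles; it is reported in `TestResult.extra` for reference. The CI
  is the percentile 2.5–97.5 interval of the bootstrap differences. The
  studentized test's type-I error at n = 10 + 10 lies within [0.03, 0.07]
  over 2000 null replicates.

All tests behave sanely at the smallest group sizes in scope (n = 4):
the rank-sum switches to exact enumeration, Dunnett and bootstrap require
n ≥ 2 per group and fail loudly below that.

## Synthetic data: what it emulates, and what it does not

Every simulator is a pure function of (timeline, params, seed), and the
returned ground truth suffices to compute all recovery metrics without
re-simulation. Because the original recordings are not publicly deposited,
amplitude and noise defaults are *calibration targets for the pipeline's
recovery properties*, not measurements:

- **Photometry**: baseline 1 a.u.; two-exponential bleach (amplitudes
  0.3/0.1, taus 600/120 s); motion artifacts as Poisson-timed (0.02 Hz)
  signed exponential transients (amplitude 0.2, decay 0.3 s) added
  *identically* to both channels before the 465-channel gain (1.8×) — this
  shared-artifact structure is exactly what the isosbestic correction
  exploits; GCaMP kernel = difference of exponentials (rise 0.2 s, decay
  1.5 s, peak-normalized — no kernel is specified by the protocol);
  Gaussian noise SD 0.01. The "disynaptic-like" preset uses a strictly
  increasing CS amplitude schedule (0.5…2.5) with US amplitude 3; the
  "mono-like" preset uses small random CS amplitudes with the same US.
- **Miniscope**: static scene = smooth background (σ = 30 px) + fine
  vessel/neuropil-like texture (σ = 1.5 px, amplitude 0.5) + disk
  footprints (radius 10 px on a 200×200 field, i.e. ≈ 0.8 % of pixels,
  inside the filter's size band). The fine static texture is essential and
  realistic: it is what rigid registration locks onto once the smooth
  background is subtracted. Cell classes: gain-CS (CS transients on late
  trials only), lose-CS (early trials only), US-only, non-responsive;
  per-pixel noise SD = transient amplitude / SNR (default SNR 10). Drift is
  a global rigid random walk (default step SD 0.05 px), matching the
  translational-only correction.
- **Tracking**: explicitly scheduled immobility bouts (exact truth) rather
  than a stochastic state model; during bouts per-step displacement ≤
  `freeze_jitter_px` (default 0), elsewhere a random-heading walk at
  40 px/s reflected at the arena walls. A step counts as inside a bout only
  when both endpoint times are, so detected bout edges match the schedule
  to within one sample.
- **Cohort**: per-animal per-epoch freezing percentages as normal draws
  clipped to [0, 100].

Passing recovery tests on these simulations establishes that the
implementation performs its stated computation correctly and recovers known
structure under the stated noise model. It does *not* establish performance
on real recordings, which additionally contain non-rigid tissue motion,
neuropil contamination, overlapping and drifting cells, non-Gaussian and
correlated noise, and tracking artifacts that these generators deliberately
omit. The in-vivo effect sizes of the original study are likewise not
reproduced here — the raw data are not deposited — so all quantitative
claims are about procedure fidelity and parameter recovery, never about the
biology.

## Problem sizes used in the checked experiments

Tests and analysis drivers scale the simulations so each stage still runs
its full algorithm: photometry recovery at 100-Hz processing rate (the
pipeline defaults to 1 kHz; rank recovery is rate-independent), 20 seeds ×
5 trials; motion-correction recovery on 500-frame 200×200 movies × 10
seeds; the end-to-end single-cell chain on a compressed conditioning
session (20-s baseline, 8–12-s ITIs) with 8 cells on a 120×120 field at
20 Hz; statistical calibration with 2000 replicates (bootstrap n_boot =
1000 per replicate). These sizes are package choices documented here so the
experiments are exactly reproducible.
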