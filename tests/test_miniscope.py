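"""Miniscope analysis: background subtraction, motion correction, extraction,
ROI filtering, and CS-plasticity classification."""

import numpy as np
import pytest
from scipy import ndimage

from fearpipe.miniscope import (ClassifyParams, Component, ExtractionParams,
                                Movie, RoiFilterParams, background_subtract,
                                classify_cs_cells, extract_components,
                                filter_components, motion_correct)
from oracle_utils import (brute_force_filter, ellipse_mask, make_component,
                          random_component_set)


def textured_scene(rng, shape=(120, 120)):
    smooth = ndimage.gaussian_filter(rng.normal(0, 1, shape), 20) * 3
    fine = ndimage.gaussian_filter(rng.normal(0, 1, shape), 1.5)
    return (20.0 + smooth + fine / fine.std()).astype(np.float32)


class TestBackgroundSubtract:
    def test_uniform_frame_maps_to_zero(self):
        movie = Movie(np.full((3, 40, 40), 5.0, dtype=np.float32), 20.0)
        out = background_subtract(movie, blur_sigma_px=4.0)
        assert np.abs(out.frames).max() < 1e-5

    def test_gradient_removed_peak_retained(self):
        grad = np.linspace(0, 10, 60)[None, :] * np.ones((60, 1))
        frame = grad.copy()
        frame[30, 30] += 5.0
        out = background_subtract(Movie(frame[None], 20.0), blur_sigma_px=3.0)
        interior = out.frames[0][5:-5, 5:-5].copy()
        peak = interior[25, 25]
        interior[20:31, 20:31] = 0.0
        assert np.abs(interior).max() < 0.05 * 10.0   # gradient gone
        assert peak > 0.5 * 5.0                        # peak mostly retained

    def test_larger_sigma_retains_more_energy(self, rng):
        frame = ndimage.gaussian_filter(rng.normal(0, 1, (80, 80)), 3.0)
        movie = Movie(frame[None].astype(np.float32), 20.0)
        energies = [np.sum(background_subtract(movie, s).frames ** 2)
                    for s in (1.0, 3.0, 9.0)]
        assert energies[0] < energies[1] < energies[2]

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            background_subtract(Movie(np.zeros((1, 8, 8)), 20.0), 0.0)


class TestMotionCorrect:
    def make_shifted_movie(self, rng, shifts, shape=(120, 120)):
        scene = textured_scene(rng, (shape[0] + 20, shape[1] + 20))
        frames = np.stack([
            ndimage.shift(scene, s, order=3, mode="nearest")[10:-10, 10:-10]
            for s in shifts]).astype(np.float32)
        return Movie(frames, 20.0)

    def test_integer_shifts_recovered_exactly(self, rng):
        true = np.array([[0, 0], [1, 0], [0, -2], [2, 1], [-1, 1]] * 8, dtype=float)
        movie = self.make_shifted_movie(rng, true)
        _, st, _ = motion_correct(movie, roi1=(10, 110, 10, 110),
                                  template_frames=10, blur_sigma_px=None)
        assert np.abs(st.shifts - true).max() < 0.1
        assert np.abs(np.round(st.shifts) - true).max() == 0

    def test_subpixel_walk_recovered_within_tolerance(self, rng):
        true = np.cumsum(rng.normal(0, 0.3, (40, 2)), axis=0)
        movie = self.make_shifted_movie(rng, true)
        _, st, _ = motion_correct(movie, roi1=(10, 110, 10, 110),
                                  template_frames=10, blur_sigma_px=None)
        rel_true = true - true[0]
        rel_est = st.shifts - st.shifts[0]
        rms = np.sqrt(np.mean((rel_est - rel_true) ** 2))
        assert rms < 0.05

    def test_already_registered_movie_converges_immediately(self, rng):
        movie = self.make_shifted_movie(rng, np.zeros((30, 2)))
        _, st, _ = motion_correct(movie, roi1=(10, 110, 10, 110),
                                  template_frames=10, blur_sigma_px=None)
        assert st.converged
        assert len(st.convergence_history) == 1
        assert st.convergence_history[0] < 0.01

    def test_roi2_residual_reported_small_for_rigid_motion(self, rng):
        true = np.cumsum(rng.normal(0, 0.2, (30, 2)), axis=0)
        movie = self.make_shifted_movie(rng, true)
        _, _, report = motion_correct(movie, roi1=(10, 110, 10, 110),
                                      roi2=(0, 60, 0, 60),
                                      template_frames=10, blur_sigma_px=None)
        assert report["roi2_checked"]
        assert report["roi2_mean_residual_px"] < 0.5
        assert not report["roi2_nonrigid_warning"]

    def test_flat_template_rejected(self):
        movie = Movie(np.zeros((10, 40, 40), dtype=np.float32), 20.0)
        with pytest.raises(ValueError, match="template"):
            motion_correct(movie, roi1=(5, 35, 5, 35), template_frames=5,
                           blur_sigma_px=None)

    def test_bad_roi_rejected(self, rng):
        movie = self.make_shifted_movie(rng, np.zeros((3, 2)))
        with pytest.raises(ValueError, match="ROI"):
            motion_correct(movie, roi1=(0, 500, 0, 500), template_frames=2)


class TestExtraction:
    def cell_movie(self, rng, centers, n_frames=300, shape=(80, 80), noise=0.0):
        scene = textured_scene(rng, shape) * 0  # flat; cells only
        footprints = [ellipse_mask(shape, c, 5, 5).astype(np.float32)
                      for c in centers]
        traces = np.zeros((len(centers), n_frames))
        for i in range(len(centers)):
            for start in range(20 + 30 * i, n_frames - 40, 90):
                traces[i, start:start + 40] += np.exp(-np.arange(40) / 12.0)
        frames = np.repeat(scene[None], n_frames, axis=0).astype(np.float32)
        for f, tr in zip(footprints, traces):
            frames += f[None] * tr[:, None, None].astype(np.float32)
        if noise:
            frames += rng.normal(0, noise, frames.shape).astype(np.float32)
        return Movie(frames, 20.0), footprints, traces

    def test_single_cell_recovered(self, rng):
        movie, footprints, _ = self.cell_movie(rng, [(40, 40)], noise=0.01)
        comps = extract_components(movie, ExtractionParams(patch_radius_px=10))
        assert len(comps) >= 1
        best = max(comps, key=lambda c: c.snr)
        inter = np.logical_and(best.support, footprints[0] > 0).sum()
        union = np.logical_or(best.support, footprints[0] > 0).sum()
        assert inter / union > 0.6

    def test_two_cells_traces_match_truth(self, rng):
        movie, footprints, traces = self.cell_movie(rng, [(25, 25), (55, 55)],
                                                    noise=0.01)
        comps = extract_components(movie, ExtractionParams(patch_radius_px=10))
        top = sorted(comps, key=lambda c: -c.snr)[:2]
        assert len(top) == 2
        for c in top:
            corrs = [np.corrcoef(c.trace.values, tr)[0, 1] for tr in traces]
            assert max(corrs) > 0.9

    def test_pure_noise_candidates_fall_below_snr_floor(self, rng):
        movie = Movie(rng.normal(0, 1, (300, 60, 60)).astype(np.float32), 20.0)
        comps = extract_components(movie)
        assert all(c.snr < RoiFilterParams().snr_min for c in comps)

    def test_empty_movie_rejected(self):
        with pytest.raises(ValueError):
            extract_components(Movie(np.zeros((0, 10, 10)), 20.0))


class TestFilterRules:
    FOV = (100, 100)   # 10,000 px: 0.6% = 60 px, 1.4% = 140 px

    def blob(self, n_px, center=(50, 50)):
        rr, cc = np.mgrid[:self.FOV[0], :self.FOV[1]]
        d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
        order = np.argsort(d2.ravel())
        mask = np.zeros(self.FOV, dtype=bool).ravel()
        mask[order[:n_px]] = True
        return mask.reshape(self.FOV)

    def test_too_small_rejected(self):
        comp = make_component(self.blob(50), snr=20.0)      # 0.5% < 0.6%
        kept, rej = filter_components([comp], self.FOV)
        assert not kept and rej[0][1] == "too_small"

    def test_mid_band_round_component_kept(self):
        comp = make_component(self.blob(100), snr=20.0)     # 1.0%
        kept, rej = filter_components([comp], self.FOV)
        assert len(kept) == 1 and not rej

    def test_too_big_rejected(self):
        comp = make_component(self.blob(150), snr=20.0)     # 1.5% > 1.4%
        _, rej = filter_components([comp], self.FOV)
        assert rej[0][1] == "too_big"

    def test_edge_touching_rejected(self):
        comp = make_component(self.blob(100, center=(2, 50)), snr=20.0)
        _, rej = filter_components([comp], self.FOV)
        assert rej[0][1] == "edge"

    def test_elongated_rejected_by_shape_rule(self):
        mask = ellipse_mask(self.FOV, (50, 50), 28.0, 1.2)
        comp = make_component(mask, snr=20.0)
        assert 0.006 <= comp.area_frac <= 0.014
        _, rej = filter_components([comp], self.FOV)
        assert rej[0][1] == "shape"

    def test_overlapping_low_snr_member_rejected(self):
        a = make_component(self.blob(100, (50, 48.5)), snr=20.0)
        b_mask = self.blob(100, (50, 51.5))
        b = make_component(b_mask, snr=1.0)
        inter = np.logical_and(a.support, b_mask).sum()
        assert inter / 100 >= 0.60
        kept, rej = filter_components([a, b], self.FOV)
        assert kept == [a]
        assert {(id(c), r) for c, r in rej} == {(id(b), "overlap_low_snr")}

    def test_isolated_low_snr_rejected_by_floor(self):
        c = make_component(self.blob(100), snr=1.0)
        _, rej = filter_components([c], self.FOV)
        assert rej[0][1] == "low_snr"

    def test_empty_input_passes_through(self):
        kept, rej = filter_components([], self.FOV)
        assert kept == [] and rej == []

    def test_matches_brute_force_oracle_on_random_sets(self):
        rng = np.random.default_rng(42)
        params = RoiFilterParams(min_area_frac=0.01, max_area_frac=0.06,
                                 snr_min=5.0)
        for _ in range(200):
            comps = random_component_set(rng)
            kept, rej = filter_components(comps, (50, 50), params)
            kept_ids = {id(c) for c in kept}
            oracle_alive, oracle_reasons = brute_force_filter(comps, (50, 50), params)
            assert kept_ids == {id(comps[i]) for i in oracle_alive}
            got_reasons = {id(c): r for c, r in rej}
            assert got_reasons == {id(comps[i]): r for i, r in oracle_reasons.items()}


class TestClassifier:
    def trials(self, early_vals, late_vals):
        return [np.asarray(v, dtype=float) for v in early_vals + late_vals]

    def test_three_sd_excess_is_up(self):
        t = self.trials([[-1, 0, 1]] * 3, [[0.0]] * 2)
        sd = np.std(np.array([-1, 0, 1] * 3), ddof=1)
        t[3] = t[4] = np.array([3.0 * sd])
        label, flags = classify_cs_cells(t, "fc_day1")
        assert label == "up" and flags["excess_sd"] == pytest.approx(3.0)

    def test_one_sd_excess_is_none(self):
        t = self.trials([[-1, 0, 1]] * 3, [[0.0]] * 2)
        sd = np.std(np.array([-1, 0, 1] * 3), ddof=1)
        t[3] = t[4] = np.array([1.0 * sd])
        assert classify_cs_cells(t, "fc_day1")[0] == "none"

    def test_down_mirror_rule(self):
        t = self.trials([[-1, 0, 1]] * 3, [[0.0]] * 2)
        sd = np.std(np.array([-1, 0, 1] * 3), ddof=1)
        t[3] = t[4] = np.array([-3.0 * sd])
        assert classify_cs_cells(t, "fc_day1")[0] == "down"

    def test_identical_trials_flagged_degenerate(self):
        t = self.trials([[2.0, 2.0]] * 3, [[2.0, 2.0]] * 2)
        label, flags = classify_cs_cells(t, "fc_day1")
        assert label == "none" and flags["zero_reference_sd"]

    def test_retrieval_compares_against_baseline(self):
        baseline = np.array([-1.0, 0.0, 1.0] * 10)
        sd = np.std(baseline, ddof=1)
        t = [np.array([3.0 * sd])] * 5
        label, _ = classify_cs_cells(t, "retrieval_day2",
                                     baseline_samples=baseline)
        assert label == "up"

    def test_retrieval_requires_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            classify_cs_cells([np.zeros(3)] * 5, "retrieval_day2")

    def test_missing_trials_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            classify_cs_cells([np.zeros(3)] * 3, "fc_day1")

    def test_trial_mean_sd_mode(self):
        t = self.trials([[0.0], [0.1], [0.2]], [[5.0], [5.0]])
        params = ClassifyParams(sd_over="trial_means")
        assert classify_cs_cells(t, "fc_day1", params)[0] == "up"
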