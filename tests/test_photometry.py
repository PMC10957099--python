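"""Photometry preprocessing: reference correction, drift removal, trial analysis."""

import numpy as np
import pytest

from fearpipe.photometry import (DualChannelRecording, PhotometryParams,
                                 TimeSeries, align_trials, gaussian_lowcut,
                                 preprocess, qc_and_correct_reference,
                                 trial_responses)
from fearpipe.protocol import ProtocolParams, build_timeline


def make_rec(sig, ref, rate=100.0):
    return DualChannelRecording(TimeSeries(0.0, rate, sig),
                                TimeSeries(0.0, rate, ref))


class TestReferenceCorrection:
    def test_affine_relation_recovers_transients_exactly(self, rng):
        # signal = 2*ref + transients, noiseless -> residual == transients + const
        n = 5000
        ref = 1.0 + 0.5 * np.exp(-np.arange(n) / 2000.0) + 0.1 * np.sin(np.arange(n) / 50.0)
        transients = np.zeros(n)
        for i in range(200, n, 600):
            transients[i:i + 80] += np.exp(-np.arange(80) / 25.0)
        sig = 2.0 * ref + transients
        out, _ = qc_and_correct_reference(make_rec(sig, ref))
        resid = out.values - transients
        assert np.ptp(resid) < 1e-9 * transients.max()

    def test_identical_channels_give_constant_zero(self):
        ref = np.sin(np.arange(1000) / 30.0) + 2.0
        out, _ = qc_and_correct_reference(make_rec(ref.copy(), ref))
        assert np.allclose(out.values, 0.0, atol=1e-10)

    def test_step_artifact_flagged_at_its_time(self, rng):
        n = 4000
        ref = rng.normal(0, 0.01, n) + 1.0
        ref[2000:] += 1.0       # step at t = 20 s (rate 100 Hz)
        sig = 1.5 * ref + rng.normal(0, 0.01, n)
        _, qc = qc_and_correct_reference(make_rec(sig, ref))
        assert any(s0 <= 20.0 <= s1 for s0, s1 in qc.flagged_segments)

    def test_discard_recommended_when_artifact_hits_stimulus(self):
        tl = build_timeline("fc_day1", ProtocolParams(baseline_s=20.0,
                                                      iti_range_s=(8.0, 12.0),
                                                      post_last_cs_s=8.0))
        rate = 50.0
        n = int(tl.total_duration * rate)
        ref = np.ones(n)
        cs0 = tl.by_label("cs")[0]
        ref[int((cs0.start + 2.0) * rate)] += 5.0    # artifact inside CS 1
        rng = np.random.default_rng(0)
        ref += rng.normal(0, 0.005, n)
        _, qc = qc_and_correct_reference(make_rec(2 * ref, ref, rate=rate),
                                         timeline=tl)
        assert qc.discard_recommended

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            qc_and_correct_reference(make_rec(np.ones(100), np.ones(100)))


class TestLowcutAndZscore:
    def test_constant_input_raises_zero_variance(self):
        ts = TimeSeries(0.0, 100.0, np.full(10000, 3.0))
        with pytest.raises(ValueError, match="zero variance"):
            preprocess(ts, PhotometryParams(target_rate_hz=100.0))

    def test_slow_sinusoid_attenuated_over_90pct(self):
        # 20-min period vs 180-s cutoff: drift should be nearly removed
        rate = 10.0
        t = np.arange(0, 3600.0, 1 / rate)
        x = np.sin(2 * np.pi * t / 1200.0)
        out = gaussian_lowcut(x, rate, 180.0)
        core = slice(int(600 * rate), int(3000 * rate))   # avoid edges
        assert np.abs(out[core]).max() < 0.10

    def test_fast_transient_preserved_over_80pct(self):
        rate = 20.0
        t = np.arange(0, 600.0, 1 / rate)
        x = np.zeros_like(t)
        m = (t >= 300) & (t < 310)
        x[m] = np.exp(-(t[m] - 300) / 3.0)        # 10-s transient
        out = gaussian_lowcut(x, rate, 180.0)
        assert out.max() > 0.80 * x.max()

    def test_detrending_nearly_idempotent(self, rng):
        # a transient-dominated trace, as produced by the pipeline itself
        rate = 20.0
        n = int(600 * rate)
        x = rng.normal(0, 0.1, n)
        for i in range(100, n - 100, 400):
            x[i:i + 60] += np.exp(-np.arange(60) / 20.0)
        x += np.linspace(0, 3, n)      # slow drift removed by the first pass
        once = gaussian_lowcut(x, rate, 180.0)
        twice = gaussian_lowcut(once, rate, 180.0)
        # interior samples: reflect-padding edge transients are excluded
        core = slice(int(150 * rate), int(450 * rate))
        rms = (np.sqrt(np.mean((twice - once)[core] ** 2))
               / np.sqrt(np.mean(once[core] ** 2)))
        assert rms < 0.01

    def test_output_mean_near_zero_and_se_scaling(self, rng):
        rate = 100.0
        x = rng.normal(0, 1, 20000) + np.linspace(0, 5, 20000)
        ts = TimeSeries(0.0, rate, x)
        z_se = preprocess(ts, PhotometryParams(target_rate_hz=100.0))
        z_sd = preprocess(ts, PhotometryParams(target_rate_hz=100.0, zscore_mode="sd"))
        assert abs(z_se.values.mean()) < 1e-8
        ratio = z_se.values.std() / z_sd.values.std()
        assert ratio == pytest.approx(np.sqrt(z_se.n), rel=1e-6)

    def test_decimation_halves_rate(self, rng):
        ts = TimeSeries(0.0, 200.0, rng.normal(0, 1, 40000).cumsum())
        out = preprocess(ts, PhotometryParams(target_rate_hz=100.0))
        assert out.rate == 100.0
        assert out.n == 20000


class TestTrialAlignment:
    def test_column_count_is_window_times_rate(self, short_day1):
        # trace extends past the session so the post-window always fits
        n = int((short_day1.total_duration + 30) * 20)
        ts = TimeSeries(0.0, 20.0, np.zeros(n))
        tm = align_trials(ts, short_day1, "cs", pre_s=10.0, post_s=20.0)
        assert tm.data.shape == (5, 600)

    def test_impulse_at_onset_lands_at_onset_column(self, short_day1):
        rate = 20.0
        n = int(short_day1.total_duration * rate) + 1
        x = np.zeros(n)
        onset = short_day1.by_label("cs")[0].start
        x[int(round(onset * rate))] = 1.0
        tm = align_trials(TimeSeries(0.0, rate, x), short_day1, "cs", 5.0, 5.0)
        assert tm.data[0, tm.onset_column] == 1.0

    def test_window_outside_trace_rejected(self, short_day1):
        ts = TimeSeries(0.0, 20.0, np.zeros(100))
        with pytest.raises(ValueError, match="outside"):
            align_trials(ts, short_day1, "cs", 10.0, 20.0)

    def test_missing_label_rejected(self, short_day1):
        ts = TimeSeries(0.0, 20.0, np.zeros(10000))
        with pytest.raises(ValueError, match="no 'laser'"):
            align_trials(ts, short_day1, "laser", 1.0, 1.0)


class TestTrialResponses:
    def params(self):
        return PhotometryParams(response_window_s=(0.0, 10.0),
                                baseline_window_s=(-5.0, 0.0))

    def test_delta_mode_zeroes_first_trial(self, short_day1):
        rate = 20.0
        n = int(short_day1.total_duration * rate) + 1
        rng = np.random.default_rng(1)
        ts = TimeSeries(0.0, rate, rng.normal(0, 1, n))
        tm = align_trials(ts, short_day1, "cs", 5.0, 12.0)
        df = trial_responses(tm, self.params(), delta=True)
        assert df["delta"].iloc[0] == 0.0
        assert np.allclose(df["delta"], df["response"] - df["response"].iloc[0])

    def test_constant_trace_gives_zero_responses(self, short_day1):
        rate = 20.0
        n = int(short_day1.total_duration * rate) + 1
        tm = align_trials(TimeSeries(0.0, rate, np.full(n, 7.0)),
                          short_day1, "cs", 5.0, 12.0)
        df = trial_responses(tm, self.params())
        assert np.allclose(df["response"], 0.0)

    def test_out_of_range_window_rejected(self, short_day1):
        rate = 20.0
        n = int(short_day1.total_duration * rate) + 1
        tm = align_trials(TimeSeries(0.0, rate, np.zeros(n)),
                          short_day1, "cs", 2.0, 12.0)
        with pytest.raises(ValueError):
            trial_responses(tm, PhotometryParams(baseline_window_s=(-10.0, 0.0)))
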