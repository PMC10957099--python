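"""Statistical procedures: rank sum, paired t, Dunnett, bootstrap."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fearpipe.stats import bootstrap_diff, dunnett, paired_t, rank_sum


def exact_ranksum_oracle(x, y):
    """Full enumeration of rank assignments (tie-free data only)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx = len(x)
    w = ranks[:nx].sum()
    sums = [sum(c) for c in combinations(ranks, nx)]
    p_low = sum(s <= w + 1e-9 for s in sums) / len(sums)
    p_high = sum(s >= w - 1e-9 for s in sums) / len(sums)
    return min(1.0, 2.0 * min(p_low, p_high))


class TestRankSum:
    def test_textbook_example(self):
        res = rank_sum([1, 2, 3], [4, 5, 6])
        assert res.p_two_sided == pytest.approx(0.1)
        assert res.method == "exact_permutation"

    def test_identical_samples_p_one(self):
        res = rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_two_sided >= 0.99

    def test_exact_matches_enumeration_all_small_sizes(self, rng):
        for nx in range(1, 7):
            for ny in range(1, 7):
                x = rng.normal(0, 1, nx)
                y = rng.normal(0.5, 1, ny)
                res = rank_sum(x, y)
                assert res.method == "exact_permutation"
                assert res.p_two_sided == pytest.approx(
                    exact_ranksum_oracle(x, y), abs=1e-12)

    def test_large_samples_use_tie_corrected_approximation(self, rng):
        x, y = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
        res = rank_sum(x, y)
        assert res.method == "normal_approx_tie_corrected"
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p_two_sided == pytest.approx(ref.pvalue)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-50, 50), min_size=2, max_size=6, unique=True))
    def test_invariant_under_monotone_transform(self, pooled):
        nx = len(pooled) // 2
        x = np.array(pooled[:nx], dtype=float)
        y = np.array(pooled[nx:], dtype=float)
        p0 = rank_sum(x, y).p_two_sided
        p1 = rank_sum(np.exp(x / 10.0), np.exp(y / 10.0)).p_two_sided
        assert p0 == pytest.approx(p1, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([], [1.0])


class TestPairedT:
    def test_three_pair_closed_form(self):
        x = np.array([3.0, 5.0, 9.0])
        y = np.array([1.0, 6.0, 4.0])
        d = x - y
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        p_manual = 2 * sps.t.sf(abs(t_manual), 2)
        res = paired_t(x, y)
        assert res.statistic == pytest.approx(t_manual, abs=1e-10)
        assert res.p_two_sided == pytest.approx(p_manual, abs=1e-10)

    def test_swapping_samples_flips_sign_keeps_p(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        a, b = paired_t(x, y), paired_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_identical_samples_hit_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0], [1.0, 2.0, 3.0])


class TestDunnett:
    def test_single_treatment_reduces_to_pooled_t(self, rng):
        ctrl = rng.normal(0, 1, 8)
        trt = rng.normal(1, 1, 6)
        res = dunnett([ctrl, trt], control_index=0, seed=1)[0]
        df = 12
        p_plain = 2 * sps.t.sf(abs(res.statistic), df)
        assert res.p_two_sided == pytest.approx(p_plain, abs=0.005)
        assert res.adjusted

    def test_adjusted_at_least_unadjusted(self, rng):
        groups = [rng.normal(m, 1, 6) for m in (0.0, 0.5, 1.0, 1.5)]
        for r in dunnett(groups, control_index=0, seed=2):
            assert r.p_two_sided >= r.extra["p_unadjusted"] - 0.004

    def test_matches_scipy_reference_k2(self, rng):
        ctrl = rng.normal(0, 1.0, 7)
        t1 = rng.normal(0.8, 1.0, 7)
        t2 = rng.normal(-0.4, 1.0, 7)
        mine = dunnett([ctrl, t1, t2], control_index=0, seed=3)
        ref = sps.dunnett(t1, t2, control=ctrl)
        for r, p_ref in zip(mine, ref.pvalue):
            assert r.p_two_sided == pytest.approx(p_ref, abs=0.005)

    def test_monte_carlo_replicate_sd_below_2e3(self, rng):
        ctrl = rng.normal(0, 1, 6)
        trt = rng.normal(0.9, 1, 6)
        ps = [dunnett([ctrl, trt], seed=s)[0].p_two_sided for s in range(6)]
        assert np.std(ps) < 0.002

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            dunnett([[1.0, 2.0]])
        with pytest.raises(ValueError, match="pooled variance"):
            dunnett([[1.0, 1.0], [1.0, 1.0]])


class TestBootstrap:
    def test_identical_constant_groups(self):
        res = bootstrap_diff([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p_two_sided == 1.0
        assert res.ci_95 == (0.0, 0.0)

    def test_same_seed_reproducible(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        a = bootstrap_diff(x, y, seed=7)
        b = bootstrap_diff(x, y, seed=7)
        assert a.p_two_sided == b.p_two_sided and a.ci_95 == b.ci_95

    def test_clear_separation_gives_small_p_and_positive_ci(self, rng):
        x = rng.normal(5, 0.5, 12)
        y = rng.normal(0, 0.5, 12)
        res = bootstrap_diff(x, y, seed=0)
        assert res.p_two_sided < 0.001
        assert res.ci_95[0] > 0

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_diff([1.0], [1.0, 2.0])
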