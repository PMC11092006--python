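import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm, spearmanr

from neuromse.entropy import (
    EntropyConfig,
    coarse_grain,
    mse_auc,
    mse_curve,
    mse_stability,
    sample_entropy,
    valid_segments,
)
from neuromse.synthetic import generate_ten_second_series


def brute_force_counts(segments, m, r):
    """Independent triple-loop oracle for the pooled-count convention."""
    A = B = 0
    for seg in segments:
        seg = list(seg)
        n = len(seg)
        for i in range(n - m):
            for j in range(i + 1, n - m):
                ok = True
                for k in range(m):
                    if abs(seg[i + k] - seg[j + k]) > r:
                        ok = False
                        break
                if ok:
                    B += 1
                    if abs(seg[i + m] - seg[j + m]) <= r:
                        A += 1
    return A, B


class TestCoarseGrain:
    @pytest.mark.parametrize(
        "series,tau,expected",
        [
            ([1, 2, 3, 4, 5, 6], 2, [1.5, 3.5, 5.5]),
            ([1, 2, 3, 4, 5, 6], 4, [2.5]),
            ([3.0, 1.0, 4.0], 1, [3.0, 1.0, 4.0]),
        ],
    )
    def test_block_averaging(self, series, tau, expected):
        np.testing.assert_allclose(coarse_grain(series, tau), expected)

    def test_short_series_gives_empty(self):
        assert coarse_grain([1.0, 2.0], 4).size == 0


class TestSampleEntropy:
    def test_constant_segment_has_zero_entropy(self):
        s, counts = sample_entropy(np.full(100, 5.0), m=2, r=0.1)
        assert s == 0.0
        assert counts.A == counts.B > 0

    def test_matches_brute_force_on_multi_segment_instances(self, rng):
        for _ in range(15):
            n_seg = rng.integers(1, 5)
            segments = [
                rng.standard_normal(rng.integers(5, 120)) for _ in range(n_seg)
            ]
            r = float(rng.uniform(0.1, 0.5))
            _, counts = sample_entropy(segments, m=2, r=r)
            A, B = brute_force_counts(segments, 2, r)
            assert (counts.A, counts.B) == (A, B)

    def test_iid_gaussian_closed_form(self):
        # iid data: conditional match probability equals the one-step
        # marginal 2*Phi(r/(sigma*sqrt(2))) - 1
        rng = np.random.default_rng(7)
        x = rng.standard_normal(8000)
        s, _ = sample_entropy(x, m=2, r=0.15 * x.std())
        expected = -np.log(2 * norm.cdf(0.15 / np.sqrt(2)) - 1)
        assert s == pytest.approx(expected, abs=0.1)

    def test_templates_never_span_gaps(self, rng):
        a = rng.standard_normal(50)
        b = rng.standard_normal(50)
        _, split = sample_entropy([a, b], m=2, r=0.3)
        _, joined = sample_entropy(np.concatenate([a, b]), m=2, r=0.3)
        # joining the segments adds cross-boundary templates and pairs
        assert joined.n_templates == split.n_templates + 2
        assert joined.B >= split.B

    def test_exact_scale_invariance_power_of_two(self, rng):
        x = rng.standard_normal(300)
        r = 0.2 * x.std()
        _, c1 = sample_entropy(x, 2, r)
        _, c2 = sample_entropy(4.0 * x, 2, 4.0 * r)
        assert (c1.A, c1.B) == (c2.A, c2.B)

    def test_affine_invariance_via_relative_tolerance(self, rng):
        x = rng.standard_normal(400)
        y = 3.7 * x + 11.0
        s1, _ = sample_entropy(x, 2, 0.15 * x.std())
        s2, _ = sample_entropy(y, 2, 0.15 * y.std())
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_undefined_when_no_matches(self):
        s, counts = sample_entropy(np.arange(20.0), m=2, r=1e-6)
        assert np.isnan(s) and counts.B == 0

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-5, 5), min_size=10, max_size=80),
           st.floats(0.05, 1.0))
    def test_entropy_nonnegative_and_counts_ordered(self, values, r):
        s, counts = sample_entropy(np.asarray(values), m=2, r=r)
        assert 0 <= counts.A <= counts.B
        if not np.isnan(s):
            assert s >= 0.0


class TestMseCurve:
    def test_white_noise_follows_per_scale_closed_form(self):
        # coarse-grained white noise stays iid with SD sigma/sqrt(tau)
        # while r is fixed from scale 1
        x = generate_ten_second_series(0.0, 20000, seed=3)
        res = mse_curve(x, EntropyConfig())
        for tau in (1, 5, 10, 20):
            expected = -np.log(2 * norm.cdf(0.15 * np.sqrt(tau / 2)) - 1)
            assert res.values[tau - 1] == pytest.approx(expected, abs=0.1)

    def test_white_noise_curve_strictly_decreasing(self):
        x = generate_ten_second_series(0.0, 20000, seed=11)
        res = mse_curve(x, EntropyConfig())
        rho = spearmanr(res.scales, res.values).statistic
        assert rho <= -0.9

    def test_short_segments_dropped(self):
        cfg = EntropyConfig(min_segment_windows=60)
        x = np.concatenate([np.random.default_rng(0).standard_normal(50),
                            [np.nan],
                            np.random.default_rng(1).standard_normal(500)])
        res = mse_curve(x, cfg)
        assert res.n_windows_used == 500

    def test_gap_structure_respected_in_segments(self):
        x = np.arange(25.0)
        x[10] = np.nan
        segs = valid_segments(x, min_length=5)
        assert [len(s) for s in segs] == [10, 14]

    def test_undefined_scale_blocks_auc_only(self):
        x = generate_ten_second_series(0.0, 400, seed=5)
        cfg = EntropyConfig(r_mode="absolute", r_factor=0.01)
        res = mse_curve(x, cfg)
        assert np.isnan(res.auc)
        assert np.isfinite(res.values[0]) or np.isnan(res.values[0])


class TestMseAuc:
    @pytest.mark.parametrize(
        "curve,expected",
        [
            (np.full(20, 1.0), 19.0),
            (np.linspace(2.0, 1.0, 20), 28.5),
            (np.zeros(20), 0.0),
        ],
    )
    def test_trapezoid_values(self, curve, expected):
        assert mse_auc(curve) == pytest.approx(expected)

    def test_missing_scale_gives_nan(self):
        curve = np.full(20, 1.0)
        curve[7] = np.nan
        assert np.isnan(mse_auc(curve))


class TestStability:
    def test_full_duration_equals_direct_curve(self):
        x = generate_ten_second_series(0.5, 1440, seed=9)
        cfg = EntropyConfig()
        per = mse_stability(x, durations_h=[2, 4], config=cfg)
        direct = mse_curve(x, cfg)
        assert per[4.0].auc == pytest.approx(direct.auc)

    def test_below_minimum_duration_missing(self):
        x = generate_ten_second_series(0.0, 720, seed=2)
        cfg = EntropyConfig(min_segment_windows=60)
        per = mse_stability(x, durations_h=[0.1, 2], config=cfg)
        assert np.isnan(per[0.1].auc)

    def test_longer_prefixes_converge_on_average(self):
        # estimator variance shrinks with duration for a stationary signal
        cfg = EntropyConfig()
        diffs_1h, diffs_4h = [], []
        for seed in range(12):
            x = generate_ten_second_series(0.3, 2880, seed=100 + seed)
            per = mse_stability(x, durations_h=[1, 4, 8], config=cfg)
            ref = per[8.0].auc
            if all(np.isfinite(per[d].auc) for d in (1.0, 4.0, 8.0)):
                diffs_1h.append(abs(per[1.0].auc - ref))
                diffs_4h.append(abs(per[4.0].auc - ref))
        assert np.mean(diffs_4h) < np.mean(diffs_1h)
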