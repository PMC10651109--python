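import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import antennascan as ans
from antennascan.spatial import bootstrap_mean_interval


def _coords_from_points(pts, frame_rate=100.0):
    """NormalizedCoords with both antennae at the given (n, 3) positions."""
    pts = np.asarray(pts, float)
    ok = np.ones(len(pts), bool)
    return ans.NormalizedCoords(
        xyz_L=pts.copy(), xyz_R=pts.copy(), valid_L=ok, valid_R=ok.copy(),
        axis_scale_mm=np.array([50.0, 50.0, 50.0]), scale_factor_mm=50.0,
        frame_rate=frame_rate)


class TestOccupancyMap:
    def test_single_bin_gets_all_mass(self):
        coords = _coords_from_points(np.tile([0.3, 0.3, 0.0], (50, 1)))
        m = ans.occupancy_map(coords, slice(None), "xy")
        assert m.values.max() == pytest.approx(1.0)
        assert m.values.sum() == pytest.approx(1.0)

    def test_uniform_scatter_is_flat(self, rng):
        pts = np.column_stack([rng.uniform(-1, 1, 60000),
                               rng.uniform(-1, 1, 60000),
                               np.zeros(60000)])
        m = ans.occupancy_map(_coords_from_points(pts), slice(None), "xy")
        # 120000 observations over 576 bins: multinomial max well below 2x mean
        assert m.values.max() < 2 / 576
        assert m.values.sum() == pytest.approx(1.0)

    def test_empty_window_errors(self):
        coords = _coords_from_points(np.zeros((10, 3)))
        with pytest.raises(ValueError):
            ans.occupancy_map(coords, slice(0, 0), "xy")

    def test_pooled_mass_conserved(self, rng):
        pts = np.column_stack([rng.uniform(-1, 1, (100, 2)), np.zeros((100, 1))])
        m1 = ans.occupancy_map(_coords_from_points(pts), slice(None), "xz")
        assert m1.values.sum() == pytest.approx(1.0)


class TestDensityCurve:
    def test_integrates_to_one(self, rng):
        x, d = ans.density_curve(rng.standard_normal(500), bandwidth=0.2)
        assert np.trapezoid(d, x) == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_input_symmetric_curve(self):
        vals = np.array([-2.0, -1.0, 1.0, 2.0])
        g = np.linspace(-4, 4, 201)
        _, d = ans.density_curve(vals, bandwidth=0.5, grid=g)
        np.testing.assert_allclose(d, d[::-1], atol=1e-12)

    def test_matches_bruteforce_kernel_sum(self, rng):
        vals = rng.uniform(-1, 1, 40)
        bw = 0.15
        q = np.linspace(-1.5, 1.5, 10)
        _, d = ans.density_curve(vals, bandwidth=bw, grid=q)
        brute = np.array([
            np.mean(np.exp(-0.5 * ((qi - vals) / bw) ** 2))
            / (bw * np.sqrt(2 * np.pi)) for qi in q])
        np.testing.assert_allclose(d, brute, rtol=1e-6)

    def test_degenerate_input_requires_bandwidth(self):
        with pytest.raises(ValueError, match="bandwidth"):
            ans.density_curve(np.ones(10))
        x, d = ans.density_curve(np.ones(10), bandwidth=0.1)
        assert np.trapezoid(d, x) == pytest.approx(1.0, abs=1e-3)


class TestDistanceToStream:
    def test_on_centre_line_zero(self):
        coords = _coords_from_points(np.tile([0.0, 0.5, 0.0], (10, 1)))
        proto = ans.StimulusProtocol(onset_s=0.01, offset_s=0.05,
                                     stream_x=[(0.0, 0.0)], stream_z_mm=0.0)
        d = ans.distance_to_stream(coords, proto)
        np.testing.assert_allclose(d["L"], 0.0, atol=1e-12)

    def test_static_lateral_offset(self):
        coords = _coords_from_points(np.tile([1.0, 0.5, 0.0], (10, 1)))
        proto = ans.StimulusProtocol(onset_s=0.01, offset_s=0.05,
                                     stream_x=[(0.0, 0.0)])
        d = ans.distance_to_stream(coords, proto)
        np.testing.assert_allclose(d["L"], 1.0)

    def test_moving_stream_closed_form(self):
        n = 200
        t = np.arange(n) / 100.0
        tip_x = np.full(n, 0.2)
        coords = _coords_from_points(
            np.column_stack([tip_x, np.full(n, 0.5), np.zeros(n)]))
        proto = ans.StimulusProtocol(onset_s=0.1, offset_s=1.0,
                                     stream_x=[(0.0, 0.0), (2.0, 60.0)])
        d = ans.distance_to_stream(coords, proto)
        expected = np.abs(tip_x - np.interp(t, [0, 2], [0, 60]) / 50.0)
        np.testing.assert_allclose(d["L"], expected, atol=1e-12)


class TestRanges:
    def test_constant_zero_and_forced_value(self):
        assert ans.antennal_range(np.full(10, 0.4)) == 0.0
        assert ans.antennal_range(np.array([-0.3, 0.5, 0.1])) == pytest.approx(0.8)

    def test_overall_combines_both(self):
        xl = np.linspace(-0.9, -0.1, 20)
        xr = np.linspace(0.1, 0.9, 20)
        assert ans.overall_range(xl, xr) == pytest.approx(1.8)
        assert ans.overall_range(xl, xl) == pytest.approx(ans.antennal_range(xl))

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-1, 1), min_size=2, max_size=30))
    def test_matches_bruteforce_pairwise_max(self, xs):
        x = np.array(xs)
        brute = max(abs(a - b) for a in x for b in x)
        assert ans.antennal_range(x) == pytest.approx(brute)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-1, 1), min_size=2, max_size=20),
           st.lists(st.floats(-1, 1), min_size=2, max_size=20))
    def test_overall_dominates_individual(self, xl, xr):
        xl, xr = np.array(xl), np.array(xr)
        ov = ans.overall_range(xl, xr)
        assert ov >= ans.antennal_range(xl) - 1e-12
        assert ov >= ans.antennal_range(xr) - 1e-12

    def test_translation_and_scale_behaviour(self, rng):
        x = rng.uniform(-1, 1, 50)
        r = ans.antennal_range(x)
        assert ans.antennal_range(x + 0.37) == pytest.approx(r)
        assert ans.antennal_range(3.0 * x) == pytest.approx(3.0 * r)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            ans.antennal_range(np.array([0.5]))


class TestBaselineChange:
    proto = ans.StimulusProtocol(onset_s=2.0, offset_s=4.0)

    def test_constant_metric_is_zero(self):
        t = np.arange(0, 6, 0.01)
        ch = ans.baseline_change(np.full(t.size, 7.0), t, self.proto)
        np.testing.assert_allclose(ch.change, 0.0, atol=1e-12)
        assert ch.window_means["odour"] == pytest.approx(0.0, abs=1e-12)

    def test_step_change_recovered(self):
        t = np.arange(0, 6, 0.01)
        metric = np.where(t >= 2.0, 2.0, 0.0)
        ch = ans.baseline_change(metric, t, self.proto)
        assert ch.window_means["pre"] == pytest.approx(0.0, abs=1e-12)
        assert ch.window_means["odour"] == pytest.approx(2.0, abs=1e-12)

    def test_ramp_pre_mean_exactly_zero(self):
        t = np.arange(0, 6, 0.01)
        ch = ans.baseline_change(3.0 * t, t, self.proto)
        assert ch.window_means["pre"] == pytest.approx(0.0, abs=1e-9)

    def test_truncated_pre_window_errors(self):
        t = np.arange(1.0, 6, 0.01)  # trial starts after onset - duration
        with pytest.raises(ValueError, match="truncated"):
            ans.baseline_change(t, t, self.proto)

    def test_idempotent_on_pre_window(self, rng):
        t = np.arange(0, 6, 0.01)
        metric = rng.standard_normal(t.size).cumsum()
        ch1 = ans.baseline_change(metric, t, self.proto)
        ch2 = ans.baseline_change(ch1.change, t, self.proto)
        np.testing.assert_allclose(ch1.change, ch2.change, atol=1e-9)


class TestShamCorrect:
    proto = ans.StimulusProtocol(onset_s=2.0, offset_s=4.0)

    def _change(self, metric, t):
        return ans.baseline_change(metric, t, self.proto)

    def test_identical_trials_cancel(self, rng):
        t = np.arange(0, 6, 0.01)
        metric = rng.standard_normal(t.size).cumsum()
        corr = ans.sham_correct(self._change(metric, t), self._change(metric, t))
        np.testing.assert_allclose(corr.change, 0.0, atol=1e-12)

    def test_zero_sham_is_identity(self, rng):
        t = np.arange(0, 6, 0.01)
        metric = rng.standard_normal(t.size)
        ch = self._change(metric, t)
        corr = ans.sham_correct(ch, self._change(np.zeros(t.size), t))
        np.testing.assert_allclose(corr.change, ch.change, atol=1e-12)

    def test_artifact_plus_effect_decomposition(self, rng):
        t = np.arange(0, 6, 0.01)
        win = (t >= 2.0) & (t < 4.0)
        noise = 0.05 * rng.standard_normal(t.size)
        sham = 1.0 * win + noise
        odour = 4.0 * win + 0.05 * rng.standard_normal(t.size)
        corr = ans.sham_correct(self._change(odour, t), self._change(sham, t))
        assert np.nanmean(corr.change[win]) == pytest.approx(3.0, abs=0.1)

    def test_length_mismatch_errors(self):
        t1 = np.arange(0, 6, 0.01)
        t2 = np.arange(0, 5, 0.01)
        with pytest.raises(ValueError, match="beyond tolerance"):
            ans.sham_correct(self._change(t1 * 0, t1), self._change(t2 * 0, t2))


class TestLabelResponsive:
    def _dist_change(self, odour_mean, n=600, onset=2.0):
        t = np.arange(n) / 100.0
        proto = ans.StimulusProtocol(onset_s=onset, offset_s=onset + 2.0)
        metric = np.where(t >= onset, odour_mean, 0.0)
        return ans.baseline_change(metric, t, proto)

    def test_strongest_decrease_wins(self):
        lab = ans.label_responsive(self._dist_change(-0.2),
                                   self._dist_change(+0.1), "t1")
        assert lab.responsive == "L"
        lab = ans.label_responsive(self._dist_change(+0.1),
                                   self._dist_change(-0.2), "t1")
        assert lab.responsive == "R"

    def test_tie_breaks_left_with_warning(self):
        with pytest.warns(UserWarning, match="tie"):
            lab = ans.label_responsive(self._dist_change(-0.1),
                                       self._dist_change(-0.1), "t1")
        assert lab.responsive == "L"
        assert lab.tied


class TestStreamFollowing:
    def test_perfect_following(self, rng):
        s = rng.standard_normal(100).cumsum()
        assert ans.stream_following_correlation(s, s) == pytest.approx(1.0)
        assert ans.stream_following_correlation(-s, s) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x, y = rng.standard_normal((2, 200))
        r = ans.stream_following_correlation(x, y)
        num = np.mean((x - x.mean()) * (y - y.mean()))
        assert r == pytest.approx(num / (x.std() * y.std()), abs=1e-12)

    def test_constant_series_is_missing(self):
        assert np.isnan(ans.stream_following_correlation(
            np.ones(10), np.arange(10.0)))


def test_bootstrap_interval_contains_mean(rng):
    vals = rng.standard_normal(50) + 2.0
    mean, lo, hi = bootstrap_mean_interval(vals, n_boot=500, seed=0)
    assert lo < mean < hi
    assert mean == pytest.approx(vals.mean())
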