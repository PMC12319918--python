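"""Percent-change normalization, binning, trial averaging, curve
normalization, correlation maps, and the inclusion filter."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fusnpx
from fusnpx.config import TrialTimeline
from fusnpx.preprocess import (
    InvalidTraceError,
    bin_spikes,
    compute_delta,
    correlation_map,
    include_session,
    normalize_curve_max,
    rescale_unit,
    stimulus_regressor,
    trial_average,
)
from fusnpx.trajectory import ProbeTrajectory


class TestBinSpikes:
    def test_twenty_contacts_make_four_depth_bins(self, timeline):
        times = [np.array([]) for _ in range(20)]
        counts = bin_spikes(times, timeline)
        assert counts.shape == (4, 170)
        assert counts.sum() == 0

    def test_half_open_windows_hand_count(self, timeline):
        times = [np.array([0.05, 0.15, 0.25])] + [np.array([])] * 4
        counts = bin_spikes(times, timeline)
        assert list(counts[0, :3]) == [2, 1, 0]

    def test_partial_contact_group_dropped_with_warning(self, timeline):
        times = [np.array([1.0])] * 7
        with pytest.warns(UserWarning, match="dropping 2 trailing"):
            counts = bin_spikes(times, timeline)
        assert counts.shape[0] == 1

    def test_total_count_conservation(self, timeline, rng):
        times = [np.sort(rng.uniform(0, 34, size=rng.integers(0, 30)))
                 for _ in range(10)]
        counts = bin_spikes(times, timeline)
        assert counts.sum() == sum(len(t) for t in times)


class TestComputeDelta:
    def test_constant_trace_is_zero(self, timeline):
        out = compute_delta(np.full(170, 7.0), timeline)
        np.testing.assert_allclose(out, 0.0)

    def test_direct_formula(self, timeline):
        trace = np.full(170, 10.0)
        trace[60] = 12.0
        out = compute_delta(trace, timeline)
        assert out[60] == pytest.approx(20.0)

    def test_zero_baseline_raises(self, timeline):
        trace = np.zeros(170)
        trace[100:] = 1.0
        with pytest.raises(InvalidTraceError):
            compute_delta(trace, timeline)

    def test_baseline_window_mean_is_zero(self, timeline, rng):
        trace = rng.uniform(5, 15, 170)
        out = compute_delta(trace, timeline)
        assert abs(out[timeline.baseline_frames].mean()) < 1e-9

    @given(k=st.floats(1e-3, 1e3))
    @settings(max_examples=30, deadline=None)
    def test_invariance_to_baseline_scale(self, k):
        tl = TrialTimeline()
        rng = np.random.default_rng(7)
        trace = rng.uniform(5, 15, tl.n_frames)
        a = compute_delta(trace, tl)
        b = compute_delta(k * trace, tl)
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestTrialAverage:
    def test_identical_trials_zero_ci(self):
        traces = np.tile(np.arange(10.0), (5, 1))
        mean, ci = trial_average(traces)
        np.testing.assert_allclose(mean, np.arange(10.0))
        np.testing.assert_allclose(ci, 0.0)

    def test_two_trial_mean(self):
        mean, ci = trial_average(np.array([[0.0, 2.0], [2.0, 0.0]]))
        np.testing.assert_allclose(mean, [1.0, 1.0])

    def test_single_trial_has_no_ci(self):
        mean, ci = trial_average(np.arange(5.0)[None, :])
        assert ci is None

    def test_ci_shrinks_with_sqrt_n(self, rng):
        n = 400
        traces = rng.standard_normal((2 * n, 50))
        _, ci_half = trial_average(traces[:n])
        _, ci_full = trial_average(traces)
        ratio = (ci_full / ci_half).mean()
        assert ratio == pytest.approx(1.0 / np.sqrt(2.0), rel=0.10)


class TestNormalizeCurveMax:
    def test_single_linear_curve_maps_to_unit_steps(self):
        out, kept = normalize_curve_max(np.array([[1.0, 2, 3, 4, 5, 6]]))
        np.testing.assert_allclose(out[0], [0, 0.2, 0.4, 0.6, 0.8, 1.0], atol=1e-12)

    def test_pooled_range_is_unit_interval(self, rng):
        curves = rng.uniform(0, 50, size=(7, 6))
        out, _ = normalize_curve_max(curves)
        assert out.min() == pytest.approx(0.0)
        assert out.max() == pytest.approx(1.0)

    def test_identical_curves_identical_outputs(self):
        c = np.array([1.0, 3.0, 4.0, 9.0])
        out, _ = normalize_curve_max(np.stack([c, c]))
        np.testing.assert_allclose(out[0], out[1])

    def test_constant_curve_excluded_with_warning(self):
        curves = np.array([[1.0, 2, 3], [5.0, 5, 5]])
        with pytest.warns(UserWarning, match="constant curve"):
            out, kept = normalize_curve_max(curves)
        assert list(kept) == [0]

    def test_unit_rescale_is_idempotent(self, rng):
        vals = rescale_unit(rng.standard_normal((4, 6)))
        np.testing.assert_allclose(rescale_unit(vals), vals, atol=1e-12)


class TestCorrelationMap:
    def test_voxel_equal_to_regressor_scores_one(self, timeline):
        reg = stimulus_regressor(timeline)
        movie = np.stack([np.stack([reg, -reg]), np.stack([0 * reg, 2 * reg])])
        r2 = correlation_map(movie, reg)
        assert r2[0, 0] == pytest.approx(1.0)
        assert r2[0, 1] == pytest.approx(1.0)  # sign-blind
        assert r2[1, 0] == 0.0  # zero-variance voxel
        assert r2[1, 1] == pytest.approx(1.0)

    def test_white_noise_null_level(self, timeline, rng):
        # E[r^2] for one regressor and T=170 frames is 1/(T-1)
        movie = rng.standard_normal((40, 50, timeline.n_frames))
        r2 = correlation_map(movie, stimulus_regressor(timeline))
        assert r2.mean() == pytest.approx(1.0 / 169.0, rel=0.15)


class TestIncludeSession:
    def test_responsive_session_kept(self, small_session):
        keep, reason = include_session(small_session, small_session.trajectory)
        assert keep, reason

    def test_zero_contrast_only_session_dropped(self):
        cfg = fusnpx.sc_config(n_trials=4, contrasts=(0.0,))
        s = fusnpx.gen_session(cfg, seed=21)
        keep, reason = include_session(s, s.trajectory)
        assert not keep

    def test_trajectory_outside_region_dropped(self, small_session):
        far = ProbeTrajectory(tip_col=10, tip_row=120, slope=0.0, n_bins=30)
        keep, reason = include_session(small_session, far)
        assert not keep
        assert "region" in reason
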