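"""Monte-Carlo candidate sampling, trajectory voxel extraction, correlation
alignment, and trajectory-based region averaging."""

import dataclasses

import numpy as np
import pytest

import fusnpx
from fusnpx.alignment import (
    CandidateSet,
    align,
    band_mask,
    region_average,
    sample_candidates,
)
from fusnpx.preprocess import compute_delta
from fusnpx.synthetic import RegionMask
from fusnpx.trajectory import ProbeTrajectory, trajectory_voxels

GRID = (143, 128)


def _identity_session(sigma_mm=0.0, seed=17):
    """Noiseless session with an identity temporal kernel: dI is exactly
    proportional to dSR along the true trajectory when sigma is 0."""
    cfg = fusnpx.sc_config(
        n_trials=2, contrasts=(0.0, 100.0), deterministic_rates=True
    )
    gt = dataclasses.replace(
        cfg.ground_truth, noise_sd=0.0, sigma_mm=sigma_mm, gamma_taps=(1.0,)
    )
    return fusnpx.gen_session(cfg.replace(ground_truth=gt), seed=seed)


def _session_deltas(session):
    tl = session.timeline
    hi = int(np.argmax(session.contrasts))
    rates = session.spike_counts.mean(axis=2) / tl.frame_s
    delta_sr = compute_delta(rates[:, :, hi], tl)
    delta_i = compute_delta(np.asarray(session.doppler_mean[hi], float), tl)
    return delta_i, delta_sr


class TestSampleCandidates:
    def test_candidate_count_and_bounds(self):
        initial = ProbeTrajectory(64, 85, 0.05, 30)
        cand = sample_candidates(initial, GRID, n=2000, seed=0)
        assert len(cand) == 2000
        assert cand.delta.min() >= -5 and cand.delta.max() <= 5
        assert cand.theta.min() >= -5 and cand.theta.max() <= 5
        assert np.all(np.abs(cand.eps) <= 0.2)

    def test_candidate_zero_is_unperturbed_initial(self):
        initial = ProbeTrajectory(64, 85, 0.05, 30)
        cand = sample_candidates(initial, GRID, n=10, seed=0)
        assert cand.trajectory(0) == initial

    def test_seed_reproducibility(self):
        initial = ProbeTrajectory(64, 85, 0.05, 30)
        a = sample_candidates(initial, GRID, n=500, seed=3)
        b = sample_candidates(initial, GRID, n=500, seed=3)
        np.testing.assert_array_equal(a.delta, b.delta)
        np.testing.assert_array_equal(a.eps, b.eps)

    def test_border_initial_resamples_until_candidates_stay_in_grid(self):
        # a tip on the left edge forbids negative column shifts; rejection
        # sampling must still return only in-grid candidates
        initial = ProbeTrajectory(0, 85, 0.0, 30)
        cand = sample_candidates(initial, GRID, n=300, seed=0)
        coords = cand.coords(GRID)
        assert coords[..., 1].min() >= 0
        assert np.all(cand.delta[1:] >= 0)


class TestTrajectoryVoxels:
    def test_slope_rounding_hand_check(self):
        traj = ProbeTrajectory(tip_col=10, tip_row=50, slope=0.5, n_bins=6)
        coords = trajectory_voxels(traj)
        # bin 4: col = round(10 + 4*0.5) = 12
        assert coords[4, 1] == 12
        assert coords[4, 0] == 46


class TestAlign:
    def test_noiseless_self_consistency_selects_truth(self):
        s = _identity_session(sigma_mm=0.0)
        delta_i, delta_sr = _session_deltas(s)
        cand = sample_candidates(s.trajectory, s.config.grid_shape, n=500, seed=1)
        best, score, _ = align(cand, delta_i, delta_sr, mode="concat")
        assert best == s.trajectory
        assert score > 0.999

    @pytest.mark.parametrize(
        "sigma_mm,delta,theta",
        [
            # depth displacements: discriminated even through the
            # hemodynamic blur (the depth profile shifts against the bins)
            (0.15, [0, 0, 0], [0, 2, -2]),
            # lateral displacements: the Gaussian point-spread itself erases
            # most lateral contrast, so strict dominance is only guaranteed
            # for an unblurred field
            (0.0, [0, 2, -2], [0, 0, 0]),
        ],
    )
    def test_true_trajectory_beats_two_voxel_displacements(
        self, sigma_mm, delta, theta
    ):
        for seed in range(5):
            s = _identity_session(sigma_mm=sigma_mm, seed=100 + seed)
            delta_i, delta_sr = _session_deltas(s)
            cand = CandidateSet(
                initial=s.trajectory,
                delta=np.array(delta),
                theta=np.array(theta),
                eps=np.zeros(len(delta)),
                seed=None,
            )
            _, _, scores = align(cand, delta_i, delta_sr, mode="concat")
            assert np.all(scores[0] > scores[1:])

    def test_uniform_field_ties_resolve_to_initial(self):
        tl = fusnpx.sc_config().timeline
        delta_i = np.ones((143, 128, tl.n_frames))
        rng = np.random.default_rng(0)
        delta_sr = rng.standard_normal((30, tl.n_frames))
        initial = ProbeTrajectory(64, 85, 0.05, 30)
        cand = sample_candidates(initial, GRID, n=200, seed=5)
        best, score, scores = align(cand, delta_i, delta_sr, mode="concat")
        assert best == initial  # zero-variance extraction scores 0 everywhere
        assert np.allclose(scores, 0.0)

    def test_candidate_order_permutation_only_affects_exact_ties(self):
        s = _identity_session(sigma_mm=0.15)
        delta_i, delta_sr = _session_deltas(s)
        cand = sample_candidates(s.trajectory, s.config.grid_shape, n=300, seed=2)
        _, score_a, scores = align(cand, delta_i, delta_sr)
        perm = np.random.default_rng(0).permutation(len(cand))
        cand_p = CandidateSet(
            initial=cand.initial,
            delta=cand.delta[perm],
            theta=cand.theta[perm],
            eps=cand.eps[perm],
            seed=None,
        )
        _, score_b, _ = align(cand_p, delta_i, delta_sr)
        assert score_b == pytest.approx(score_a, abs=1e-12)


class TestRegionAverage:
    def _mask(self):
        labels = np.zeros(GRID, dtype=np.int16)
        labels[40:100, 50:90] = 1
        return RegionMask(labels=labels, region_names={1: "SC"})

    def test_constant_field_gives_constant_trace(self):
        mask = self._mask()
        traj = ProbeTrajectory(64, 85, 0.0, 30)
        movie = np.full((*GRID, 10), 3.5)
        trace = region_average(traj, mask, movie, 1, kind="fus")
        np.testing.assert_allclose(trace, 3.5)

    def test_band_mask_is_seven_voxel_strip_in_region(self):
        mask = self._mask()
        traj = ProbeTrajectory(64, 85, 0.0, 30)
        bm = band_mask(traj, mask, 1, GRID, band=3)
        rows = np.arange(85, 55, -1)
        expected = np.zeros(GRID, dtype=bool)
        for r in rows:
            expected[r, 61:68] = True
        expected &= mask.labels == 1
        np.testing.assert_array_equal(bm, expected)

    def test_default_contrast_set_yields_one_trace_each(self, rng):
        mask = self._mask()
        traj = ProbeTrajectory(64, 85, 0.0, 30)
        movies = rng.standard_normal((6, *GRID, 8))
        traces = [region_average(traj, mask, m, 1, kind="fus") for m in movies]
        assert len(traces) == 6
        assert all(t.shape == (8,) for t in traces)

    def test_empty_intersection_raises(self):
        mask = self._mask()
        traj = ProbeTrajectory(10, 130, 0.0, 20)
        movie = np.zeros((*GRID, 5))
        with pytest.raises(ValueError):
            region_average(traj, mask, movie, 1, kind="fus")
        with pytest.raises(ValueError):
            region_average(traj, mask, np.zeros((20, 5)), 1, kind="spikes")
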