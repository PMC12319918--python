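"""Monte-Carlo probe alignment and trajectory-based signal extraction.

The probe trajectory estimated from structural imaging carries voxel-scale
error (wide shank echoes, binning jitter, off-plane tip). The alignment
perturbs the initial estimate — integer tip shifts (delta, theta) in
[-5, 5] voxels and a real slope offset epsilon in [-0.2, 0.2] — over many
random candidates and keeps the one maximizing the Pearson correlation
between the Doppler voxels extracted along the candidate and the matched
spike-rate bins (tip-first order).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import RegionMask
from .trajectory import ProbeTrajectory, TrajectoryOutOfGrid, trajectory_voxels

__all__ = [
    "CandidateSet",
    "sample_candidates",
    "trajectory_voxels",
    "align",
    "band_mask",
    "region_average",
]


@dataclass(frozen=True)
class CandidateSet:
    """Perturbed trajectory candidates around an initial estimate.

    Candidate 0 is always the unperturbed initial trajectory, so the selected
    score can never fall below the initial's score.
    """

    initial: ProbeTrajectory
    delta: np.ndarray  # integer column shifts
    theta: np.ndarray  # integer row shifts
    eps: np.ndarray  # real slope offsets
    seed: int | None

    def __len__(self) -> int:
        return len(self.delta)

    def trajectory(self, i: int) -> ProbeTrajectory:
        return ProbeTrajectory(
            tip_col=self.initial.tip_col + self.delta[i],
            tip_row=self.initial.tip_row + self.theta[i],
            slope=self.initial.slope + self.eps[i],
            n_bins=self.initial.n_bins,
        )

    def coords(self, grid_shape: tuple[int, int] | None = None) -> np.ndarray:
        """(n_candidates, n_bins, 2) voxel coordinates, tip first."""
        k = np.arange(self.initial.n_bins)
        rows = (
            int(round(self.initial.tip_row)) + self.theta[:, None] - k[None, :]
        )
        cols = np.rint(
            self.initial.tip_col
            + self.delta[:, None]
            + k[None, :] * (self.initial.slope + self.eps[:, None])
        ).astype(int)
        out = np.stack([rows, cols], axis=-1)
        if grid_shape is not None:
            h, w = grid_shape
            if (
                rows.min() < 0
                or rows.max() >= h
                or cols.min() < 0
                or cols.max() >= w
            ):
                raise TrajectoryOutOfGrid("candidate leaves the grid")
        return out


def sample_candidates(
    initial: ProbeTrajectory,
    grid_shape: tuple[int, int],
    n: int = 10_000,
    seed: int | None = None,
    tip_range: int = 5,
    eps_range: float = 0.2,
    max_resample: int = 1000,
) -> CandidateSet:
    """Sample ``n`` candidate trajectories around ``initial``.

    Tip shifts are uniform integers in [-tip_range, tip_range]; the slope
    offset is uniform in [-eps_range, eps_range]. Candidates whose bins leave
    the grid are rejected and resampled. Candidate 0 is the unperturbed
    initial (which must itself be valid).
    """
    trajectory_voxels(initial, grid_shape)  # initial must be in-grid
    rng = np.random.default_rng(seed)
    delta = np.zeros(n, dtype=int)
    theta = np.zeros(n, dtype=int)
    eps = np.zeros(n, dtype=float)

    def valid(d: int, t: int, e: float) -> bool:
        try:
            trajectory_voxels(
                ProbeTrajectory(
                    tip_col=initial.tip_col + d,
                    tip_row=initial.tip_row + t,
                    slope=initial.slope + e,
                    n_bins=initial.n_bins,
                ),
                grid_shape,
            )
            return True
        except TrajectoryOutOfGrid:
            return False

    for i in range(1, n):
        for _ in range(max_resample):
            d = int(rng.integers(-tip_range, tip_range + 1))
            t = int(rng.integers(-tip_range, tip_range + 1))
            e = float(rng.uniform(-eps_range, eps_range))
            if valid(d, t, e):
                delta[i], theta[i], eps[i] = d, t, e
                break
        else:
            raise TrajectoryOutOfGrid(
                "could not sample a valid candidate; initial trajectory is "
                "too close to the grid border"
            )
    return CandidateSet(initial=initial, delta=delta, theta=theta, eps=eps, seed=seed)


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between each row of ``a`` and the vector ``b``."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean()
    an = np.sqrt(np.sum(ac**2, axis=1))
    bn = np.sqrt(np.sum(bc**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = ac @ bc / (an * bn)
    return np.where((an == 0) | (bn == 0), 0.0, r)


def align(
    candidates: CandidateSet,
    delta_i: np.ndarray,
    delta_sr: np.ndarray,
    mode: str = "concat",
    chunk: int = 2048,
    spike_window: slice | None = None,
    fus_window: slice | None = None,
    psf_sigma_bins: float = 1.5,
    hp_sigma_bins: float = 3.0,
    hp_weight: float = 2.0,
) -> tuple[ProbeTrajectory, float, np.ndarray]:
    """Select the candidate maximizing fUS-spike Pearson correlation.

    ``delta_i`` is the trial-averaged (highest-contrast) dI movie (H, W, T);
    ``delta_sr`` the matched trial-averaged dSR bins (n_bins, T).

    Modes:

    * ``"concat"`` (default): correlation over the full bin x time
      concatenation of raw traces — the plain reading of the method.
    * ``"binmean"``: correlation of per-bin time means (depth profiles).
    * ``"profile"``: a refined depth-profile score built for voxel-scale
      tip localization. The Doppler movie is temporally reduced over
      ``fus_window`` (the stimulus period extended by the hemodynamic lag)
      and averaged over the immediate lateral neighbours (the evoked field
      is smooth at the PSF scale, the noise is not); the spike profile is
      reduced over ``spike_window`` (spiking carries no post-stimulus
      signal) and smoothed by ``psf_sigma_bins`` to match the hemodynamic
      blur. The score sums the Pearson correlation of these matched
      profiles and ``hp_weight`` times the correlation of their high-pass
      residuals, which isolate the fine-scale coupling texture that carries
      the lateral information.

    Ties are broken by the lowest candidate index, so exact ties fall back
    to the (injected) initial trajectory. Returns
    ``(best_trajectory, best_score, all_scores)``.
    """
    from scipy.ndimage import gaussian_filter1d

    if len(candidates) == 0:
        raise ValueError("candidate set is empty")
    H, W, T = delta_i.shape
    if delta_sr.shape != (candidates.initial.n_bins, T):
        raise ValueError("delta_sr must be (n_bins, n_frames) matching the movie")
    coords = candidates.coords(grid_shape=(H, W))
    n = len(candidates)
    scores = np.empty(n)

    if mode == "concat":
        target = delta_sr.ravel()
    elif mode == "binmean":
        target = delta_sr.mean(axis=1)
    elif mode == "profile":
        sw = spike_window if spike_window is not None else slice(None)
        fw = fus_window if fus_window is not None else slice(None)
        resp_map = delta_i[:, :, fw].mean(axis=2)
        resp_map = 0.5 * resp_map + 0.25 * (
            np.roll(resp_map, 1, axis=1) + np.roll(resp_map, -1, axis=1)
        )
        prof_sr = delta_sr[:, sw].mean(axis=1)
        target = gaussian_filter1d(prof_sr, psf_sigma_bins, mode="nearest")
        target_hp = target - gaussian_filter1d(target, hp_sigma_bins, mode="nearest")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    for s in range(0, n, chunk):
        sl = slice(s, min(s + chunk, n))
        if mode == "profile":
            flat = resp_map[coords[sl, :, 0], coords[sl, :, 1]]
            flat_hp = flat - gaussian_filter1d(
                flat, hp_sigma_bins, axis=1, mode="nearest"
            )
            scores[sl] = _pearson_rows(flat, target) + hp_weight * _pearson_rows(
                flat_hp, target_hp
            )
        else:
            block = delta_i[coords[sl, :, 0], coords[sl, :, 1], :]
            flat = (
                block.reshape(block.shape[0], -1)
                if mode == "concat"
                else block.mean(axis=2)
            )
            scores[sl] = _pearson_rows(flat, target)
    best = int(np.argmax(scores))  # argmax returns the first maximal index
    return candidates.trajectory(best), float(scores[best]), scores


def band_mask(
    traj: ProbeTrajectory,
    mask: RegionMask,
    region_id: int,
    grid_shape: tuple[int, int],
    band: int = 3,
) -> np.ndarray:
    """Boolean voxel mask: within ``band`` voxels laterally of the trajectory
    AND inside the labelled region."""
    coords = trajectory_voxels(traj, grid_shape)
    out = np.zeros(grid_shape, dtype=bool)
    w = grid_shape[1]
    for r, c in coords:
        out[r, max(c - band, 0) : min(c + band + 1, w)] = True
    return out & mask.in_region(region_id)


def region_average(
    traj: ProbeTrajectory,
    mask: RegionMask,
    field: np.ndarray,
    region_id: int,
    kind: str = "fus",
    band: int = 3,
) -> np.ndarray:
    """Average a modality over the trajectory-region intersection.

    ``kind="fus"``: ``field`` is a dI movie (H, W, T); voxels within the
    3-voxel lateral band around the trajectory and inside the region are
    averaged into one temporal trace. ``kind="spikes"``: ``field`` is a
    (n_bins, T) block; trajectory bins whose voxel lies in the region are
    averaged. Raises if the intersection is empty (this drives the
    session-exclusion rule).
    """
    if kind == "fus":
        bm = band_mask(traj, mask, region_id, field.shape[:2], band=band)
        if not bm.any():
            raise ValueError("trajectory band does not intersect the region")
        return field[bm].mean(axis=0)
    if kind == "spikes":
        coords = trajectory_voxels(traj, mask.labels.shape)
        in_region = mask.labels[coords[:, 0], coords[:, 1]] == region_id
        if not in_region.any():
            raise ValueError("no trajectory bin lies in the region")
        return field[np.flatnonzero(in_region)].mean(axis=0)
    raise ValueError(f"unknown kind {kind!r}")
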