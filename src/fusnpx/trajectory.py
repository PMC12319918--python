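"""Probe trajectory geometry on the Doppler voxel grid.

A trajectory is parameterized by its tip voxel ``(tip_col, tip_row)``, a
dimensionless slope (lateral voxel offset per depth step), and the number of
100-um depth bins ``n_bins``. Bin 0 sits at the tip; successive bins walk
upward (decreasing row), one voxel row per bin, with the column rounded to
the nearest integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ProbeTrajectory:
    tip_col: float
    tip_row: float
    slope: float
    n_bins: int

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")


class TrajectoryOutOfGrid(ValueError):
    """Raised when a trajectory leaves the voxel grid."""


def trajectory_voxels(
    traj: ProbeTrajectory, grid_shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Ordered ``(n_bins, 2)`` array of (row, col) voxel coordinates, tip first.

    Bin k maps to row ``round(tip_row) - k`` and column
    ``round(tip_col + k * slope)``. If ``grid_shape`` is given, a
    :class:`TrajectoryOutOfGrid` error is raised when any bin falls outside.
    """
    k = np.arange(traj.n_bins)
    rows = int(round(traj.tip_row)) - k
    cols = np.rint(traj.tip_col + k * traj.slope).astype(int)
    coords = np.stack([rows, cols], axis=1)
    if grid_shape is not None:
        h, w = grid_shape
        ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        if not ok.all():
            bad = int(np.flatnonzero(~ok)[0])
            raise TrajectoryOutOfGrid(
                f"bin {bad} at (row={rows[bad]}, col={cols[bad]}) is outside "
                f"the {h}x{w} grid"
            )
    return coords


def gen_trajectory(
    grid_shape: tuple[int, int],
    tip: tuple[float, float],
    slope: float,
    n_bins: int,
) -> ProbeTrajectory:
    """Build a trajectory from a tip ``(col, row)``, validating grid bounds."""
    traj = ProbeTrajectory(tip_col=tip[0], tip_row=tip[1], slope=slope, n_bins=n_bins)
    trajectory_voxels(traj, grid_shape)  # raises if the line exits the grid
    return traj
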