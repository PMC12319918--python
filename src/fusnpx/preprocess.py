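"""Raw-signal conditioning: spike binning, percent-change normalization,
trial averaging, curve-max normalization, correlation maps, and the
session-inclusion filter.

Both modalities are expressed as percent change relative to the pre-stimulus
baseline mean (dI for Power-Doppler intensity, dSR for spike rate), which
removes the arbitrary absolute scale of each instrument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import TrialTimeline
from .synthetic import SyntheticSession
from .trajectory import ProbeTrajectory, trajectory_voxels

__all__ = [
    "SpikeBlock",
    "InvalidTraceError",
    "bin_spikes",
    "compute_delta",
    "trial_average",
    "normalize_curve_max",
    "correlation_map",
    "include_session",
]


class InvalidTraceError(ValueError):
    """A trace whose baseline mean is zero cannot be baseline-normalized."""


@dataclass(frozen=True)
class SpikeBlock:
    """Spike counts per depth bin x time bin x trial x contrast."""

    counts: np.ndarray  # (n_bins, n_frames, n_trials, n_contrasts)
    bin_size_um: float = 100.0
    bin_size_s: float = 0.2

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be >= 0")

    @property
    def rates(self) -> np.ndarray:
        """Counts converted to spikes/s."""
        return self.counts / self.bin_size_s


def bin_spikes(
    spike_times: list[np.ndarray],
    timeline: TrialTimeline,
    n_contacts_per_bin: int = 5,
    bin_s: float = 0.2,
) -> np.ndarray:
    """Bin per-contact spike event times into (depth bin, time bin) counts.

    Contacts are ordered by depth (deepest first, matching the tip-first bin
    order); every ``n_contacts_per_bin`` consecutive contacts are pooled into
    one 100-um depth bin, and events are counted in half-open time windows
    ``[t, t + bin_s)``. A trailing partial contact group is dropped with a
    warning. Returns an ``(n_bins, n_time_bins)`` count array for one trial.
    """
    n_contacts = len(spike_times)
    n_bins = n_contacts // n_contacts_per_bin
    if n_bins == 0:
        raise ValueError(
            f"need at least {n_contacts_per_bin} contacts, got {n_contacts}"
        )
    if n_contacts % n_contacts_per_bin:
        warnings.warn(
            f"dropping {n_contacts % n_contacts_per_bin} trailing contacts that "
            f"do not fill a {n_contacts_per_bin}-contact depth bin",
            stacklevel=2,
        )
    n_time = int(round(timeline.trial_s / bin_s))
    edges = np.arange(n_time + 1) * bin_s
    counts = np.zeros((n_bins, n_time), dtype=np.int64)
    for b in range(n_bins):
        group = spike_times[b * n_contacts_per_bin : (b + 1) * n_contacts_per_bin]
        ev = np.concatenate([np.asarray(g, dtype=float) for g in group]) if group else []
        if len(ev):
            if np.any((np.asarray(ev) < 0) | (np.asarray(ev) > timeline.trial_s)):
                raise ValueError("spike times outside trial bounds")
            # half-open [t, t+bin_s): right edge goes to the later bin
            counts[b] = np.histogram(ev, bins=edges)[0]
            at_end = np.sum(np.asarray(ev) == edges[-1])
            if at_end:  # events exactly at trial end have no later bin
                counts[b, -1] += at_end
    return counts


def compute_delta(trace: np.ndarray, timeline: TrialTimeline) -> np.ndarray:
    """Percent change relative to the pre-stimulus baseline mean.

    ``delta = 100 * (trace - basal) / basal`` where ``basal`` is the mean over
    frames from trial start to stimulus onset, taken along the last axis.
    A 1-D trace with zero baseline mean raises :class:`InvalidTraceError`;
    for multidimensional input, zero-baseline entries become NaN with a
    warning (flagged invalid, to be excluded downstream).
    """
    trace = np.asarray(trace, dtype=float)
    basal = trace[..., timeline.baseline_frames].mean(axis=-1, keepdims=True)
    if trace.ndim == 1:
        if basal.ravel()[0] == 0:
            raise InvalidTraceError("baseline mean is zero; trace is invalid")
        return 100.0 * (trace - basal) / basal
    bad = basal == 0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} traces have zero baseline mean; set to NaN",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (trace - basal) / basal
    out = np.where(np.broadcast_to(bad, out.shape), np.nan, out)
    return out


def trial_average(
    traces: np.ndarray, ci: float = 0.95
) -> tuple[np.ndarray, np.ndarray | None]:
    """Pointwise mean across trials with a Student-t confidence half-width.

    ``traces`` is (n_trials, n_frames). With a single trial the mean is
    returned and the CI is ``None`` (undefined).
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2:
        raise ValueError("traces must be (n_trials, n_frames)")
    n = traces.shape[0]
    mean = traces.mean(axis=0)
    if n < 2:
        return mean, None
    sem = traces.std(axis=0, ddof=1) / np.sqrt(n)
    tq = stats.t.ppf(0.5 + ci / 2.0, df=n - 1)
    return mean, tq * sem


def rescale_unit(values: np.ndarray) -> np.ndarray:
    """Affine rescale of a pooled value set to the [0, 1] interval.

    Idempotent: applying it to an already [0, 1]-spanning set is the
    identity.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("cannot rescale a constant value set")
    return (values - lo) / (hi - lo)


def normalize_curve_max(
    curves: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-step normalization of per-session contrast-maximum curves.

    Step 1: each curve (row) is z-scored across contrasts, removing
    inter-session and inter-region scale. Step 2: one affine rescale of all
    pooled values to the [0, 1] interval. Constant curves (sd = 0) are
    excluded with a warning. Returns ``(normalized, kept_row_indices)``.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    if curves.shape[1] < 2:
        raise ValueError("need at least 2 contrast points per curve")
    sd = curves.std(axis=1)
    kept = np.flatnonzero(sd > 0)
    if len(kept) < curves.shape[0]:
        warnings.warn(
            f"excluding {curves.shape[0] - len(kept)} constant curve(s)",
            stacklevel=2,
        )
    if len(kept) == 0:
        raise ValueError("all curves are constant")
    z = (curves[kept] - curves[kept].mean(axis=1, keepdims=True)) / sd[
        kept, None
    ]
    return rescale_unit(z), kept


def correlation_map(delta_i: np.ndarray, regressor: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of each voxel's dI trace with a stimulus
    regressor (default usage: a boxcar over the stimulus frames).

    ``delta_i`` is (H, W, T); returns (H, W) r-squared in [0, 1], with
    zero-variance voxels reported as 0.
    """
    delta_i = np.asarray(delta_i, dtype=float)
    regressor = np.asarray(regressor, dtype=float)
    if delta_i.shape[-1] != regressor.shape[0]:
        raise ValueError("regressor length must equal the frame count")
    x = regressor - regressor.mean()
    xn = np.sqrt(np.sum(x**2))
    if xn == 0:
        raise ValueError("regressor has zero variance")
    v = delta_i - delta_i.mean(axis=-1, keepdims=True)
    vn = np.sqrt(np.sum(v**2, axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.tensordot(v, x, axes=([-1], [0])) / (vn * xn)
    r = np.where(vn == 0, 0.0, r)
    return r**2


def stimulus_regressor(timeline: TrialTimeline) -> np.ndarray:
    """Boxcar regressor: 1 during stimulus frames, 0 elsewhere."""
    reg = np.zeros(timeline.n_frames)
    reg[timeline.stim_frames] = 1.0
    return reg


def _window_means(traces: np.ndarray, timeline: TrialTimeline):
    base = traces[:, timeline.baseline_frames].mean(axis=1)
    stim = traces[:, timeline.stim_frames].mean(axis=1)
    return base, stim


def include_session(
    session: SyntheticSession,
    trajectory: ProbeTrajectory,
    alpha: float = 0.05,
    response_window_s: float | None = None,
) -> tuple[bool, str]:
    """Session-inclusion filter.

    Keep iff (a) at the highest contrast both modalities show a significant
    stimulus response — one-sided paired t-test across trials of the
    stimulus-window mean versus the baseline-window mean of the region-mean
    trace, at level ``alpha`` — and (b) at least one trajectory bin lies in
    the target region.

    ``response_window_s`` optionally extends the tested fUS window beyond the
    stimulus offset to cover the lagged hemodynamic peak (default: the
    stimulus window itself).
    """
    tl = session.timeline
    region_id = session.config.region_id
    coords = trajectory_voxels(trajectory, session.config.grid_shape)
    in_region = session.mask.labels[coords[:, 0], coords[:, 1]] == region_id
    if not in_region.any():
        return False, "trajectory does not cross the target region"

    ci = int(np.argmax(session.contrasts))
    if session.contrasts[ci] == 0:
        return False, "no non-zero contrast condition"

    # spikes: per-trial region-mean rate traces (n_trials, T)
    bins = np.flatnonzero(in_region)
    rate_traces = (
        session.spike_counts[bins, :, :, ci].mean(axis=0).T / tl.frame_s
    )
    base, stim = _window_means(rate_traces, tl)
    if np.allclose(stim - base, 0):
        return False, "no spiking response at highest contrast"
    p_spk = stats.ttest_rel(stim, base, alternative="greater").pvalue
    if not p_spk < alpha:
        return False, f"no significant spiking response (p={p_spk:.3g})"

    # fUS: per-trial region-mean intensity traces from the ROI window
    r0, c0 = session.roi_origin
    roi_rows = coords[in_region, 0] - r0
    roi_cols = coords[in_region, 1] - c0
    h, w = session.doppler_roi.shape[2:4]
    ok = (roi_rows >= 0) & (roi_rows < h) & (roi_cols >= 0) & (roi_cols < w)
    if not ok.any():
        return False, "trajectory outside the stored Doppler window"
    fus_traces = session.doppler_roi[ci][:, roi_rows[ok], roi_cols[ok], :].mean(axis=1)
    tl_fus = tl
    base_f = fus_traces[:, tl_fus.baseline_frames].mean(axis=1)
    end = tl.stim_end_frame
    if response_window_s is not None:
        end = min(tl.n_frames, tl.onset_frame + int(round(response_window_s / tl.frame_s)))
    stim_f = fus_traces[:, tl.onset_frame : end].mean(axis=1)
    if np.allclose(stim_f - base_f, 0):
        return False, "no fUS response at highest contrast"
    p_fus = stats.ttest_rel(stim_f, base_f, alternative="greater").pvalue
    if not p_fus < alpha:
        return False, f"no significant fUS response (p={p_fus:.3g})"
    return True, "significant response in both modalities; trajectory in region"
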