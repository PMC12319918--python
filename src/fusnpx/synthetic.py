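"""Synthetic fUS + Neuropixels session generator.

Simulates a full joint recording with known ground truth so that every
downstream stage (alignment, calibration, transfer-function and spatial
estimation) can be validated by parameter recovery:

* spiking — Poisson counts per 100-um depth bin and 200-ms time bin, with a
  basal rate plus a stimulus-locked, contrast-dependent increment whose
  spatial footprint is an anisotropic Gaussian blob sampled along the true
  probe trajectory;
* hemodynamics — the noiseless percent spike-rate change field pushed through
  the spatiotemporal forward model (2-D Gaussian spatial spread, causal gamma
  temporal kernel), scaled so that the peak dSR / peak dI ratio equals the
  configured calibration slope, with additive Gaussian voxel noise;
* geometry — the true trajectory plus an elliptical region label mask.

Power-Doppler intensity is reconstructed as ``I_basal * (1 + dI/100)``; the
absolute level is arbitrary and cancels in the percent-change normalization.

Because the Doppler noise is additive and Gaussian, the per-contrast
trial-mean movie can be simulated exactly (noise sd divided by sqrt(n)); the
generator always stores those trial means plus full per-trial movies on a
window around the region (for per-trial statistics), and keeps whole-grid
per-trial movies only on request.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.ndimage import gaussian_filter

from .config import CRFParams, GroundTruth, SessionConfig, TrialTimeline
from .trajectory import ProbeTrajectory, gen_trajectory, trajectory_voxels

__all__ = [
    "RegionMask",
    "SyntheticSession",
    "contrast_response",
    "gen_session",
    "gen_trajectory",
    "save_session",
    "load_session",
]


@dataclass(frozen=True)
class RegionMask:
    """Integer region labels per voxel (0 = background)."""

    labels: np.ndarray
    region_names: dict[int, str] = field(default_factory=dict)

    def in_region(self, region_id: int) -> np.ndarray:
        return self.labels == region_id


def contrast_response(c: float | np.ndarray, crf: CRFParams) -> float | np.ndarray:
    """Stimulus-driven rate increment (spikes/s) for contrast ``c`` in %.

    Naka-Rushton form ``r_max * c^n / (c^n + c50^n)``: zero at zero contrast
    and monotone saturating, the canonical visual contrast-response shape.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("contrast must be >= 0")
    cn = c_arr**crf.n
    out = crf.r_max_hz * cn / (cn + crf.c50**crf.n)
    return float(out) if np.isscalar(c) else out


@dataclass
class SyntheticSession:
    """Generated session: spikes, Doppler movies, geometry, and truths."""

    config: SessionConfig
    seed: int
    # spike counts, shape (n_bins, n_frames, n_trials, n_contrasts)
    spike_counts: np.ndarray
    # trial-mean Power-Doppler intensity, shape (n_contrasts, H, W, T)
    doppler_mean: np.ndarray
    # per-trial intensity on the ROI window, shape (n_contrasts, n_trials, h, w, T)
    doppler_roi: np.ndarray
    roi_origin: tuple[int, int]  # (row, col) of the ROI window corner
    mask: RegionMask
    trajectory: ProbeTrajectory
    # noiseless truths for recovery scoring
    delta_sr_true: np.ndarray  # (n_contrasts, n_bins, T), in %
    delta_i_true_scale: float  # forward-model output scale factor
    smoothed_blob: np.ndarray  # (H, W) spatially smoothed activation footprint
    drive_conv: np.ndarray  # (T,) envelope convolved with the gamma kernel
    # full per-trial movies, (n_contrasts, n_trials, H, W, T); only if keep_trials
    doppler_trials: np.ndarray | None = None

    @property
    def timeline(self) -> TrialTimeline:
        return self.config.timeline

    @property
    def ground_truth(self) -> GroundTruth:
        return self.config.ground_truth

    @property
    def contrasts(self) -> np.ndarray:
        return np.asarray(self.config.contrasts, dtype=float)

    def delta_i_true(self, contrast_index: int) -> np.ndarray:
        """Noiseless dI movie (H, W, T) for one contrast, in %."""
        gt = self.ground_truth
        amp = 100.0 * contrast_response(self.contrasts[contrast_index], gt.crf)
        amp /= gt.basal_rate_hz
        field_ = self.smoothed_blob[..., None] * self.drive_conv[None, None, :]
        return self.delta_i_true_scale * amp * field_

    def roi_slices(self) -> tuple[slice, slice]:
        r0, c0 = self.roi_origin
        h, w = self.doppler_roi.shape[2:4]
        return slice(r0, r0 + h), slice(c0, c0 + w)


def _elliptical_mask(
    grid_shape: tuple[int, int],
    center: tuple[float, float],
    semi_row: float,
    semi_col: float,
) -> np.ndarray:
    rows = (np.arange(grid_shape[0])[:, None] - center[0]) / semi_row
    cols = (np.arange(grid_shape[1])[None, :] - center[1]) / semi_col
    return rows**2 + cols**2 <= 1.0


def gen_session(config: SessionConfig, seed: int) -> SyntheticSession:
    """Generate one fully specified synthetic session.

    Identical ``(config, seed)`` pairs produce bit-identical output.
    """
    tl = config.timeline
    gt = config.ground_truth
    rng = np.random.default_rng(seed)
    contrasts = np.asarray(config.contrasts, dtype=float)
    n_contrasts, n_trials = len(contrasts), config.n_trials
    T = tl.n_frames
    H, W = config.grid_shape

    traj = gen_trajectory(
        config.grid_shape,
        tip=(gt.true_trajectory.tip_col, gt.true_trajectory.tip_row),
        slope=gt.true_trajectory.slope,
        n_bins=gt.true_trajectory.n_bins,
    )
    coords = trajectory_voxels(traj, config.grid_shape)

    blob = gt.blob.field(config.grid_shape, config.pitch_mm)
    # coupling-gain texture: smooth log-normal field, unit median, drawn
    # first so the spatial structure is fixed before any per-trial sampling
    if gt.texture_sd > 0:
        z = gaussian_filter(
            rng.standard_normal(config.grid_shape),
            sigma=(
                gt.texture_len_mm / config.pitch_mm[0],
                gt.texture_len_mm / config.pitch_mm[1],
            ),
            mode="reflect",
        )
        z /= z.std()
        blob = blob * np.exp(gt.texture_sd * z)
    env = gt.envelope.evaluate(tl)  # (T,), peaks at 1 during the stimulus
    blob_on_traj = blob[coords[:, 0], coords[:, 1]]  # (n_bins,)
    rate_inc = np.array([contrast_response(c, gt.crf) for c in contrasts])  # Hz

    # --- spiking ------------------------------------------------------------
    # rate(bin, t, contrast) = basal + r(c) * blob(bin) * envelope(t)
    rates = gt.basal_rate_hz + (
        rate_inc[None, None, :] * blob_on_traj[:, None, None] * env[None, :, None]
    )
    lam = np.broadcast_to(
        (rates * tl.frame_s)[:, :, None, :],
        (traj.n_bins, T, n_trials, n_contrasts),
    )
    if config.deterministic_rates:
        spike_counts = np.ascontiguousarray(lam)
    else:
        spike_counts = rng.poisson(lam).astype(np.int64)

    # --- noiseless forward model (separable in space and time) ---------------
    sigma_vox = (
        gt.sigma_mm / config.pitch_mm[0],
        gt.sigma_mm / config.pitch_mm[1],
    )
    smoothed = (
        gaussian_filter(blob, sigma=sigma_vox, mode="constant")
        if gt.sigma_mm > 0
        else blob.copy()
    )
    taps = (
        np.asarray(gt.gamma_taps, dtype=float)
        if gt.gamma_taps is not None
        else gt.gamma.sample(n_taps=21, dt=tl.frame_s)
    )
    drive_conv = np.convolve(env, taps, mode="full")[:T]

    amp = 100.0 * rate_inc / gt.basal_rate_hz  # peak dSR (%) per contrast
    delta_sr_true = (
        amp[:, None, None] * blob_on_traj[None, :, None] * env[None, None, :]
    )

    # --- region mask ----------------------------------------------------------
    labels = np.zeros(config.grid_shape, dtype=np.int16)
    ell = _elliptical_mask(
        config.grid_shape,
        center=(gt.blob.center_row, gt.blob.center_col),
        semi_row=18.0,
        semi_col=12.0,
    )
    labels[ell] = config.region_id
    mask = RegionMask(labels=labels, region_names={config.region_id: config.region})

    # --- calibration scale ----------------------------------------------------
    # the calibration slope is defined on the measured curves: peak of the
    # noiseless region-averaged dSR trace over peak of the noiseless
    # region-averaged dI trace along the true trajectory equals slope_amp
    in_region = ell[coords[:, 0], coords[:, 1]]
    sel = in_region if in_region.any() else np.ones(len(coords), dtype=bool)
    mean_sr_space = float(blob_on_traj[sel].mean())
    mean_di_space = float(smoothed[coords[sel, 0], coords[sel, 1]].mean())
    peak_sr_trace = float(np.max(amp) * mean_sr_space * env.max())
    peak_di_unscaled = float(np.max(amp) * mean_di_space * drive_conv.max())
    if peak_sr_trace > 0 and peak_di_unscaled > 0 and gt.slope_amp > 0:
        scale = peak_sr_trace / (gt.slope_amp * peak_di_unscaled)
    else:
        scale = 0.0

    # --- Doppler movies -------------------------------------------------------
    # ROI window: region bounding box dilated by roi_margin voxels
    rr, cc = np.nonzero(ell)
    m = config.roi_margin
    r0, r1 = max(rr.min() - m, 0), min(rr.max() + m + 1, H)
    c0, c1 = max(cc.min() - m, 0), min(cc.max() + m + 1, W)
    roi_h, roi_w = r1 - r0, c1 - c0

    signal_space = scale * smoothed  # (H, W), per unit of amp * drive_conv
    doppler_mean = np.empty((n_contrasts, H, W, T), dtype=np.float32)
    doppler_roi = np.empty((n_contrasts, n_trials, roi_h, roi_w, T), dtype=np.float32)
    doppler_trials = (
        np.empty((n_contrasts, n_trials, H, W, T), dtype=np.float32)
        if config.keep_trials
        else None
    )
    i_basal = config.i_basal
    for ci in range(n_contrasts):
        di_sig = amp[ci] * signal_space[..., None] * drive_conv[None, None, :]
        if config.keep_trials:
            for tr in range(n_trials):
                noise = (
                    rng.standard_normal((H, W, T)) * gt.noise_sd
                    if gt.noise_sd > 0
                    else 0.0
                )
                movie = i_basal * (1.0 + (di_sig + noise) / 100.0)
                doppler_trials[ci, tr] = movie
                doppler_roi[ci, tr] = movie[r0:r1, c0:c1]
            doppler_mean[ci] = doppler_trials[ci].mean(axis=0)
        else:
            # exact trial-level noise on the ROI window ...
            roi_noise = (
                rng.standard_normal((n_trials, roi_h, roi_w, T)) * gt.noise_sd
                if gt.noise_sd > 0
                else np.zeros((n_trials, roi_h, roi_w, T))
            )
            doppler_roi[ci] = i_basal * (
                1.0 + (di_sig[None, r0:r1, c0:c1, :] + roi_noise) / 100.0
            )
            # ... and an exact sqrt(n)-reduced draw for the whole-grid mean,
            # spliced so the ROI of the mean equals the mean of the ROI trials
            mean_noise = (
                rng.standard_normal((H, W, T)) * (gt.noise_sd / np.sqrt(n_trials))
                if gt.noise_sd > 0
                else np.zeros((H, W, T))
            )
            mean_noise[r0:r1, c0:c1] = roi_noise.mean(axis=0)
            doppler_mean[ci] = i_basal * (1.0 + (di_sig + mean_noise) / 100.0)

    if not np.any(blob_on_traj > 1e-6) and np.any(rate_inc > 0):
        warnings.warn(
            "true trajectory does not intersect the active region; "
            "spiking carries no stimulus drive",
            stacklevel=2,
        )

    return SyntheticSession(
        config=config,
        seed=seed,
        spike_counts=spike_counts,
        doppler_mean=doppler_mean,
        doppler_roi=doppler_roi,
        roi_origin=(r0, c0),
        mask=mask,
        trajectory=traj,
        delta_sr_true=delta_sr_true,
        delta_i_true_scale=scale,
        smoothed_blob=smoothed,
        drive_conv=drive_conv,
        doppler_trials=doppler_trials,
    )


# --- HDF5 container ----------------------------------------------------------


def save_session(session: SyntheticSession, path) -> None:
    """Write a session to HDF5 (one file per session)."""
    cfg, gt = session.config, session.ground_truth
    with h5py.File(path, "w") as f:
        f.create_dataset("spikes", data=session.spike_counts, compression="gzip")
        f.create_dataset("doppler_mean", data=session.doppler_mean)
        f.create_dataset("doppler_roi", data=session.doppler_roi)
        if session.doppler_trials is not None:
            f.create_dataset("doppler", data=session.doppler_trials)
        f.create_dataset("mask", data=session.mask.labels)
        f.create_dataset("delta_sr_true", data=session.delta_sr_true)
        f.create_dataset("smoothed_blob", data=session.smoothed_blob)
        f.create_dataset("drive_conv", data=session.drive_conv)
        tgrp = f.create_group("trajectory")
        tgrp.attrs.update(
            tip_col=session.trajectory.tip_col,
            tip_row=session.trajectory.tip_row,
            slope=session.trajectory.slope,
            n_bins=session.trajectory.n_bins,
        )
        ggrp = f.create_group("ground_truth")
        ggrp.attrs.update(
            slope_amp=gt.slope_amp,
            sigma_mm=gt.sigma_mm,
            basal_rate_hz=gt.basal_rate_hz,
            noise_sd=gt.noise_sd,
            gamma_shape=gt.gamma.shape,
            gamma_scale_s=gt.gamma.scale_s,
            gamma_delay_s=gt.gamma.delay_s,
            gamma_amplitude=gt.gamma.amplitude,
            crf_r_max_hz=gt.crf.r_max_hz,
            crf_c50=gt.crf.c50,
            crf_n=gt.crf.n,
            delta_i_true_scale=session.delta_i_true_scale,
        )
        meta = {
            "region": cfg.region,
            "region_id": cfg.region_id,
            "region_names": {str(k): v for k, v in session.mask.region_names.items()},
            "contrasts": list(map(float, cfg.contrasts)),
            "n_trials": cfg.n_trials,
            "seed": session.seed,
            "i_basal": cfg.i_basal,
            "roi_origin": [int(v) for v in session.roi_origin],
            "grid_shape": [int(v) for v in cfg.grid_shape],
            "pitch_mm": list(cfg.pitch_mm),
            "timeline": {
                "frame_rate_hz": cfg.timeline.frame_rate_hz,
                "baseline_s": cfg.timeline.baseline_s,
                "stim_s": cfg.timeline.stim_s,
                "post_s": cfg.timeline.post_s,
            },
            "blob": {
                "center_row": gt.blob.center_row,
                "center_col": gt.blob.center_col,
                "depth_fwhm_mm": gt.blob.depth_fwhm_mm,
                "lateral_fwhm_mm": gt.blob.lateral_fwhm_mm,
                "tilt_deg": gt.blob.tilt_deg,
            },
            "envelope": {
                "sustained": gt.envelope.sustained,
                "transient": gt.envelope.transient,
                "adapt_tau_s": gt.envelope.adapt_tau_s,
            },
            "deterministic_rates": cfg.deterministic_rates,
            "gamma_taps": list(gt.gamma_taps) if gt.gamma_taps is not None else None,
        }
        f.create_dataset("meta", data=json.dumps(meta))


def load_session(path) -> SyntheticSession:
    """Read a session written by :func:`save_session`."""
    from .config import (
        ActivationBlob,
        DriveEnvelope,
        GammaParams,
        TrueTrajectory,
    )

    with h5py.File(path, "r") as f:
        meta = json.loads(f["meta"][()])
        g = dict(f["ground_truth"].attrs)
        t = dict(f["trajectory"].attrs)
        gt = GroundTruth(
            slope_amp=float(g["slope_amp"]),
            sigma_mm=float(g["sigma_mm"]),
            gamma=GammaParams(
                amplitude=float(g["gamma_amplitude"]),
                shape=float(g["gamma_shape"]),
                scale_s=float(g["gamma_scale_s"]),
                delay_s=float(g["gamma_delay_s"]),
            ),
            basal_rate_hz=float(g["basal_rate_hz"]),
            crf=CRFParams(
                r_max_hz=float(g["crf_r_max_hz"]),
                c50=float(g["crf_c50"]),
                n=float(g["crf_n"]),
            ),
            noise_sd=float(g["noise_sd"]),
            true_trajectory=TrueTrajectory(
                tip_col=int(t["tip_col"]),
                tip_row=int(t["tip_row"]),
                slope=float(t["slope"]),
                n_bins=int(t["n_bins"]),
            ),
            blob=ActivationBlob(**meta["blob"]),
            envelope=DriveEnvelope(**meta["envelope"]),
            gamma_taps=(
                tuple(meta["gamma_taps"]) if meta.get("gamma_taps") else None
            ),
        )
        cfg = SessionConfig(
            region=meta["region"],
            timeline=TrialTimeline(**meta["timeline"]),
            ground_truth=gt,
            contrasts=tuple(meta["contrasts"]),
            n_trials=int(meta["n_trials"]),
            grid_shape=tuple(meta["grid_shape"]),
            pitch_mm=tuple(meta["pitch_mm"]),
            region_id=int(meta["region_id"]),
            i_basal=float(meta["i_basal"]),
            deterministic_rates=bool(meta["deterministic_rates"]),
            keep_trials="doppler" in f,
        )
        traj = ProbeTrajectory(
            tip_col=float(t["tip_col"]),
            tip_row=float(t["tip_row"]),
            slope=float(t["slope"]),
            n_bins=int(t["n_bins"]),
        )
        mask = RegionMask(
            labels=f["mask"][()],
            region_names={int(k): v for k, v in meta["region_names"].items()},
        )
        return SyntheticSession(
            config=cfg,
            seed=int(meta["seed"]),
            spike_counts=f["spikes"][()],
            doppler_mean=f["doppler_mean"][()],
            doppler_roi=f["doppler_roi"][()],
            roi_origin=tuple(meta["roi_origin"]),
            mask=mask,
            trajectory=traj,
            delta_sr_true=f["delta_sr_true"][()],
            delta_i_true_scale=float(g["delta_i_true_scale"]),
            smoothed_blob=f["smoothed_blob"][()],
            drive_conv=f["drive_conv"][()],
            doppler_trials=f["doppler"][()] if "doppler" in f else None,
        )
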