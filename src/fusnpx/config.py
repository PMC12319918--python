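"""Study-condition configuration: trial timeline, generator ground truth, region presets.

The defaults encode the experimental design this package emulates: 5-Hz
Power-Doppler imaging of a 143 x 128 voxel coronal plane, 34-s trials
(10-s baseline, 4-s visual stimulus, 20-s post-stimulus), six stimulus
contrasts presented 50 times each, and a linear probe whose spiking is
binned at 100 um / 200 ms. Region presets (superior colliculus, lateral
geniculate nucleus, primary visual cortex) carry the region-specific
coupling truths: amplitude calibration slope, basal firing rate, and the
temporal gamma kernel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

DEFAULT_CONTRASTS = (0.0, 5.0, 10.0, 30.0, 50.0, 100.0)
GRID_SHAPE = (143, 128)  # rows (depth) x cols (lateral)
PITCH_MM = (0.1, 0.1)  # in-plane voxel pitch used for all spatial metrics


@dataclass(frozen=True)
class TrialTimeline:
    """Trial structure shared by both modalities.

    All durations are in seconds; frames are sampled at ``frame_rate_hz``
    (default 5 Hz, i.e. one frame / spike bin every 200 ms).
    """

    frame_rate_hz: float = 5.0
    baseline_s: float = 10.0
    stim_s: float = 4.0
    post_s: float = 20.0

    def __post_init__(self) -> None:
        for name in ("frame_rate_hz", "baseline_s", "stim_s", "post_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def frame_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    @property
    def trial_s(self) -> float:
        return self.baseline_s + self.stim_s + self.post_s

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate_hz * self.trial_s))

    @property
    def onset_frame(self) -> int:
        """First frame of the stimulus period."""
        return int(round(self.frame_rate_hz * self.baseline_s))

    @property
    def stim_end_frame(self) -> int:
        """First frame after the stimulus period."""
        return int(round(self.frame_rate_hz * (self.baseline_s + self.stim_s)))

    @property
    def baseline_frames(self) -> slice:
        return slice(0, self.onset_frame)

    @property
    def stim_frames(self) -> slice:
        return slice(self.onset_frame, self.stim_end_frame)

    def times(self) -> np.ndarray:
        """Frame times (s) relative to trial start."""
        return np.arange(self.n_frames) * self.frame_s


@dataclass(frozen=True)
class GammaParams:
    """Gamma-shaped temporal kernel a * ((t-d)/tau)^(k-1) * exp(-(t-d)/tau).

    The kernel is zero for t < d and peaks at ``d + (k-1) * tau`` seconds.
    """

    amplitude: float = 1.0
    shape: float = 3.0
    scale_s: float = 0.4
    delay_s: float = 0.0

    def __post_init__(self) -> None:
        if self.shape <= 1:
            raise ValueError("shape k must be > 1 for a peaked kernel")
        if self.scale_s <= 0:
            raise ValueError("scale tau must be > 0")
        if self.delay_s < 0:
            raise ValueError("delay d must be >= 0")

    @property
    def time_to_peak_s(self) -> float:
        return self.delay_s + (self.shape - 1.0) * self.scale_s

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        m = t > self.delay_s
        x = (t[m] - self.delay_s) / self.scale_s
        out[m] = self.amplitude * x ** (self.shape - 1.0) * np.exp(-x)
        return out

    def sample(self, n_taps: int = 21, dt: float = 0.2) -> np.ndarray:
        """Kernel sampled at ``dt`` steps on lags 0..n_taps-1."""
        return self.evaluate(np.arange(n_taps) * dt)


@dataclass(frozen=True)
class CRFParams:
    """Naka-Rushton contrast-response parameters r_max * c^n / (c^n + c50^n)."""

    r_max_hz: float = 9.0
    c50: float = 20.0
    n: float = 2.0

    def __post_init__(self) -> None:
        if self.r_max_hz < 0 or self.c50 <= 0 or self.n <= 0:
            raise ValueError("invalid contrast-response parameters")


@dataclass(frozen=True)
class ActivationBlob:
    """Spatial footprint of the stimulus-driven population on the voxel grid.

    An anisotropic Gaussian bump (peak value 1) whose long axis is tilted by
    ``tilt_deg`` away from the probe axis; a nucleus is generally not aligned
    with the shank, and the tilt gives the alignment objective genuine
    sensitivity to lateral tip displacements.
    """

    center_row: float = 70.0
    center_col: float = 65.0
    depth_fwhm_mm: float = 1.4
    lateral_fwhm_mm: float = 0.6
    tilt_deg: float = 10.0

    def field(self, grid_shape: tuple[int, int], pitch_mm: tuple[float, float]) -> np.ndarray:
        rows = np.arange(grid_shape[0])[:, None] - self.center_row
        cols = np.arange(grid_shape[1])[None, :] - self.center_col
        y = rows * pitch_mm[0]
        x = cols * pitch_mm[1]
        f = 2.0 * np.sqrt(2.0 * np.log(2.0))
        sd, sl = self.depth_fwhm_mm / f, self.lateral_fwhm_mm / f
        th = np.deg2rad(self.tilt_deg)
        # rotate into the blob's principal frame
        u = np.cos(th) * y - np.sin(th) * x
        v = np.sin(th) * y + np.cos(th) * x
        return np.exp(-0.5 * ((u / sd) ** 2 + (v / sl) ** 2))


@dataclass(frozen=True)
class DriveEnvelope:
    """Temporal envelope of the stimulus-locked rate increment.

    Sustained component plus an adapting onset transient, matching the
    canonical evoked spike-rate shape (sharp onset peak, slow decay, fast
    offset). The envelope peaks at 1 at stimulus onset.
    """

    sustained: float = 0.5
    transient: float = 0.5
    adapt_tau_s: float = 0.8

    def evaluate(self, timeline: TrialTimeline) -> np.ndarray:
        t = timeline.times()
        onset_t = timeline.onset_frame * timeline.frame_s
        env = np.zeros(timeline.n_frames)
        stim = np.zeros(timeline.n_frames, dtype=bool)
        stim[timeline.stim_frames] = True
        rel = t[stim] - onset_t
        env[stim] = self.sustained + self.transient * np.exp(-rel / self.adapt_tau_s)
        return env


@dataclass(frozen=True)
class TrueTrajectory:
    """Ground-truth probe geometry (tip voxel, slope, number of 100-um bins)."""

    tip_col: int = 64
    tip_row: int = 85
    slope: float = 0.05
    n_bins: int = 30


@dataclass(frozen=True)
class GroundTruth:
    """Generator truths against which recovery error is measured."""

    slope_amp: float = 21.4  # % dSR per % dI
    sigma_mm: float = 0.15  # spatial Gaussian SD of the hemodynamic spread
    gamma: GammaParams = field(default_factory=GammaParams)
    basal_rate_hz: float = 4.50
    crf: CRFParams = field(default_factory=CRFParams)
    noise_sd: float = 1.0  # additive voxel noise on dI, in % per frame
    true_trajectory: TrueTrajectory = field(default_factory=TrueTrajectory)
    blob: ActivationBlob = field(default_factory=ActivationBlob)
    envelope: DriveEnvelope = field(default_factory=DriveEnvelope)
    # explicit temporal kernel taps overriding the gamma kernel (e.g. (1.0,)
    # for an identity temporal coupling in oracle conditions)
    gamma_taps: tuple[float, ...] | None = None
    # multiplicative log-normal gain texture on the stimulus-driven field:
    # coupling heterogeneity across the plane (Power Doppler amplitude is
    # dominated by discrete vessels, so evoked-response gain varies strongly
    # at the 100-300 um scale). Without it the synthetic field is exactly
    # separable in space and time and lateral probe displacements would be
    # unidentifiable in principle.
    texture_sd: float = 0.8
    texture_len_mm: float = 0.2

    def __post_init__(self) -> None:
        if self.sigma_mm < 0:
            raise ValueError("sigma_mm must be >= 0")
        if self.basal_rate_hz <= 0:
            raise ValueError("basal_rate_hz must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def peak_delta_i(self, contrast: float = 100.0) -> float:
        """Noiseless peak |dI| (%) implied by the calibration slope."""
        from .synthetic import contrast_response

        peak_dsr = 100.0 * contrast_response(contrast, self.crf) / self.basal_rate_hz
        return peak_dsr / self.slope_amp if self.slope_amp else 0.0


@dataclass(frozen=True)
class SessionConfig:
    """Full specification of one synthetic recording session."""

    region: str = "SC"
    timeline: TrialTimeline = field(default_factory=TrialTimeline)
    ground_truth: GroundTruth = field(default_factory=GroundTruth)
    contrasts: tuple[float, ...] = DEFAULT_CONTRASTS
    n_trials: int = 50
    grid_shape: tuple[int, int] = GRID_SHAPE
    pitch_mm: tuple[float, float] = PITCH_MM
    region_id: int = 1
    i_basal: float = 1000.0  # arbitrary positive Power-Doppler baseline level
    deterministic_rates: bool = False  # replace Poisson by its mean
    keep_trials: bool = False  # retain full per-trial movies (memory heavy)
    roi_margin: int = 9  # voxels around the region box kept per trial

    def __post_init__(self) -> None:
        if len(self.contrasts) == 0:
            raise ValueError("contrast list must not be empty")
        if any(c < 0 or c > 100 for c in self.contrasts):
            raise ValueError("contrasts must lie in [0, 100]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    def replace(self, **kw) -> "SessionConfig":
        return dataclasses.replace(self, **kw)


# Gamma presets solved so that the analytic peak d + (k-1)*tau is 0.8 s and the
# continuous FWHM matches the regional means (short 0.8 s, long 1.5 s).
GAMMA_SHORT = GammaParams(amplitude=1.0, shape=6.621560, scale_s=0.142309, delay_s=0.0)
GAMMA_LONG = GammaParams(amplitude=1.0, shape=2.652156, scale_s=0.484216, delay_s=0.0)


def sc_config(**overrides) -> SessionConfig:
    """Superior-colliculus-like session: low basal rate, steep calibration."""
    gt = GroundTruth(
        slope_amp=21.4,
        basal_rate_hz=4.50,
        gamma=GAMMA_LONG,
        crf=CRFParams(r_max_hz=9.0),
        true_trajectory=TrueTrajectory(n_bins=30, tip_row=85),
    )
    return SessionConfig(region="SC", ground_truth=gt).replace(**overrides)


def lgn_config(**overrides) -> SessionConfig:
    """Lateral-geniculate-like session: high basal rate, shallow calibration, short kernel."""
    gt = GroundTruth(
        slope_amp=7.7,
        basal_rate_hz=10.36,
        gamma=GAMMA_SHORT,
        crf=CRFParams(r_max_hz=8.0),
        true_trajectory=TrueTrajectory(n_bins=25, tip_row=82),
    )
    return SessionConfig(region="LGN", ground_truth=gt).replace(**overrides)


def v1_config(**overrides) -> SessionConfig:
    """Primary-visual-cortex-like session."""
    gt = GroundTruth(
        slope_amp=10.5,
        basal_rate_hz=6.79,
        gamma=GAMMA_LONG,
        crf=CRFParams(r_max_hz=7.0),
        true_trajectory=TrueTrajectory(n_bins=25, tip_row=82),
    )
    return SessionConfig(region="V1", ground_truth=gt).replace(**overrides)


REGION_CONFIGS = {"SC": sc_config, "LGN": lgn_config, "V1": v1_config}
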