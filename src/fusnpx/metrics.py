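"""Summary statistics: temporal shape metrics with the outlier rule,
amplitude-calibration regression, spatial peak-aligned comparison, and
group tests across regions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SessionResult",
    "time_to_peak",
    "fwhm",
    "drop_outliers",
    "amplitude_regression",
    "spatial_compare",
    "group_compare",
]


def time_to_peak(
    trace: np.ndarray,
    onset_frame: int = 0,
    dt: float = 0.2,
    mode: str = "peak",
    min_prominence: float = 0.5,
) -> float:
    """Latency (s) from onset to the first local maximum of the signal.

    ``mode="peak"`` (default) returns the time of the first post-onset local
    maximum whose amplitude reaches ``min_prominence`` times the post-onset
    maximum (so a small early noise ripple does not masquerade as the
    response peak; the default floor of half the maximum mirrors the
    half-maximum convention of the width metric). Plateaus count once, at
    their first sample, so equal maxima resolve to the earlier one.
    ``mode="inflexion"`` returns the first post-onset zero crossing of the
    second difference (strict curvature-change reading). A trace that never
    turns down is reported as NaN (peak undefined).
    """
    trace = np.asarray(trace, dtype=float)
    post = trace[onset_frame:]
    if len(post) < 1:
        raise ValueError("trace has no post-onset samples")
    if mode == "inflexion":
        d2 = np.diff(post, 2)
        sign = np.sign(d2)
        flips = np.flatnonzero((sign[:-1] != 0) & (sign[1:] != 0) & (sign[:-1] != sign[1:]))
        return float((flips[0] + 1) * dt) if len(flips) else float("nan")
    if mode != "peak":
        raise ValueError(f"unknown mode {mode!r}")
    if len(post) == 1:
        return 0.0
    floor = min_prominence * post.max()
    for i in range(len(post) - 1):
        if post[i] > post[i + 1] and post[i] >= floor:
            # first sample of the plateau ending here
            j = i
            while j > 0 and post[j - 1] == post[i]:
                j -= 1
            return float(j * dt)
    return float("nan")


def fwhm(signal: np.ndarray, step: float, interpolate: bool = False) -> float:
    """Full width at half maximum of a sampled signal.

    Default rule: the length of the longest run of consecutive samples
    strictly above half the peak amplitude, times the sample ``step`` (no
    sub-sample interpolation; a single-sample spike has width one step).
    ``interpolate=True`` instead locates the half-maximum crossings of that
    run by linear interpolation. Raises if the signal has no positive peak.
    """
    signal = np.asarray(signal, dtype=float)
    peak = signal.max()
    if peak <= 0:
        raise ValueError("signal has no positive peak")
    above = signal > peak / 2.0
    # longest run of consecutive True
    best_len, best_start, cur, start = 0, 0, 0, 0
    for i, a in enumerate(above):
        if a:
            if cur == 0:
                start = i
            cur += 1
            if cur > best_len:
                best_len, best_start = cur, start
        else:
            cur = 0
    if not interpolate:
        return best_len * step
    lo, hi = best_start, best_start + best_len - 1
    half = peak / 2.0
    left = float(lo)
    if lo > 0:
        left = lo - (signal[lo] - half) / (signal[lo] - signal[lo - 1])
    right = float(hi)
    if hi < len(signal) - 1:
        right = hi + (signal[hi] - half) / (signal[hi] - signal[hi + 1])
    return (right - left) * step


def drop_outliers(values: np.ndarray) -> np.ndarray:
    """Remove collection outliers above ``mean + 2 * sd`` (population sd)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        return values
    thresh = values.mean() + 2.0 * values.std()
    return values[values <= thresh]


def amplitude_regression(
    max_i: np.ndarray, max_sr: np.ndarray
) -> tuple[float, float, float]:
    """Ordinary least squares of per-contrast max dSR on max dI.

    Returns ``(slope, intercept, r_squared)``; the slope is the percent
    spike-rate change associated with a 1% rise in peak Doppler signal (the
    region's calibration factor).
    """
    max_i = np.asarray(max_i, dtype=float)
    max_sr = np.asarray(max_sr, dtype=float)
    if len(max_i) != len(max_sr) or len(max_i) < 3:
        raise ValueError("need >= 3 matched contrast points")
    if np.ptp(max_i) == 0:
        raise ValueError("max dI has zero variance")
    res = stats.linregress(max_i, max_sr)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def spatial_compare(
    i_profile: np.ndarray,
    sr_profile: np.ndarray,
    pitch_mm: float = 0.1,
    interpolate_fwhm: bool = False,
) -> tuple[float, float]:
    """Peak-aligned comparison of matched spatial depth profiles.

    The spike-rate profile is shifted by an integer number of bins so its
    peak coincides with the Doppler peak; the Pearson correlation is computed
    on the overlapping support, and the width difference is
    ``FWHM(dI) - FWHM(dSR)`` in mm (positive = wider hemodynamic footprint).
    """
    di = np.asarray(i_profile, dtype=float)
    sr = np.asarray(sr_profile, dtype=float)
    if di.max() <= 0 or sr.max() <= 0:
        raise ValueError("profiles must have a positive peak")
    shift = int(np.argmax(di)) - int(np.argmax(sr))
    if shift >= 0:
        a, b = di[shift:], sr[: len(sr) - shift]
    else:
        a, b = di[: len(di) + shift], sr[-shift:]
    n = min(len(a), len(b))
    if n < 3:
        raise ValueError("profiles do not overlap after peak alignment")
    a, b = a[:n], b[:n]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r = 0.0
    else:
        r = float(stats.pearsonr(a, b).statistic)
    dfwhm = fwhm(di, pitch_mm, interpolate=interpolate_fwhm) - fwhm(
        sr, pitch_mm, interpolate=interpolate_fwhm
    )
    return r, float(dfwhm)


def group_compare(
    groups: dict[str, np.ndarray], test: str = "t"
) -> tuple[float, float]:
    """Compare metric values across regions.

    ``test="t"`` runs the two-sided independent-samples t-test (exactly two
    groups); ``test="kruskal"`` the Kruskal-Wallis test (two or more groups).
    P-values are reported uncorrected. Returns ``(statistic, p_value)``.
    """
    vals = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(vals) < 2 or any(len(v) < 2 for v in vals):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if test == "t":
        if len(vals) != 2:
            raise ValueError("t-test compares exactly 2 groups")
        res = stats.ttest_ind(vals[0], vals[1])
    elif test == "kruskal":
        try:
            res = stats.kruskal(*vals)
        except ValueError:  # all values identical across groups
            return 0.0, 1.0
    else:
        raise ValueError(f"unknown test {test!r}")
    stat, p = float(res.statistic), float(res.pvalue)
    if np.isnan(stat):  # identical groups: zero variance
        return 0.0, 1.0
    return stat, p


@dataclass
class SessionResult:
    """Per-session derived quantities produced by the full analysis chain."""

    region: str
    seed: int
    contrasts: np.ndarray
    max_di: np.ndarray  # per-contrast max dI (%) along the aligned trajectory
    max_dsr: np.ndarray  # per-contrast max dSR (%)
    slope: float
    intercept: float
    r2_amp: float
    tf_coeffs: np.ndarray
    ridge_lambda: float
    tf_time_to_peak_s: float
    tf_fwhm_s: float
    tf_r2: float
    gamma_shape: float
    gamma_scale_s: float
    gamma_delay_s: float
    gamma_rms: float
    spatial_r: float
    spatial_dfwhm_mm: float
    sigma_hat_mm: float
    basal_rate_hz_est: float
    tip_error_vox: float
    align_score: float
    included: bool
    exclusion_reason: str = ""
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "region": self.region,
            "seed": self.seed,
            "slope": self.slope,
            "intercept": self.intercept,
            "r2_amp": self.r2_amp,
            "ridge_lambda": self.ridge_lambda,
            "tf_time_to_peak_s": self.tf_time_to_peak_s,
            "tf_fwhm_s": self.tf_fwhm_s,
            "tf_r2": self.tf_r2,
            "gamma_shape": self.gamma_shape,
            "gamma_scale_s": self.gamma_scale_s,
            "gamma_delay_s": self.gamma_delay_s,
            "gamma_rms": self.gamma_rms,
            "spatial_r": self.spatial_r,
            "spatial_dfwhm_mm": self.spatial_dfwhm_mm,
            "sigma_hat_mm": self.sigma_hat_mm,
            "basal_rate_hz_est": self.basal_rate_hz_est,
            "tip_error_vox": self.tip_error_vox,
            "align_score": self.align_score,
            "included": self.included,
            "exclusion_reason": self.exclusion_reason,
        }
        for i, c in enumerate(self.contrasts):
            row[f"max_di_{c:g}"] = self.max_di[i]
            row[f"max_dsr_{c:g}"] = self.max_dsr[i]
        return row
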