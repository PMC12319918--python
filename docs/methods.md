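# Methods

`fusnpx` analyzes simultaneous functional-ultrasound (fUS) Power-Doppler
imaging and Neuropixels spiking from the same brain region, and quantifies
how the two signals are coupled in amplitude, time and space. Because the
full chain is exercised on synthetic sessions with known ground truth, this
note describes both the analysis model and the generator, and is explicit
about what the synthetic conditions do and do not establish about real data.

## Signal model

Both modalities are expressed as percent change relative to the pre-stimulus
baseline mean of each trial block:

    dI(t)  = 100 * (I(t)  - I_basal)  / I_basal
    dSR(t) = 100 * (SR(t) - SR_basal) / SR_basal

where the basal values are means over the frames from trial start to
stimulus onset. The coupling model is causal and linear, separable into a
spatial and a temporal kernel:

    dI(x, t) = dSR(x, t)  (*)_x  G(x; 0, sigma)  (*)_t  Gamma(t; theta)

* `G` — Gaussian spatial spread, standard deviation `sigma` in mm along the
  probe axis (default truth 0.15 mm; 0.1-mm depth bins).
* `Gamma(t) = a ((t-d)/tau)^(k-1) exp(-(t-d)/tau)` — gamma-shaped temporal
  kernel, zero before the onset delay `d`, peaking at `d + (k-1) tau`.

Region presets carry the coupling truths used throughout: calibration
slope (% dSR per % dI) 21.4 (SC), 7.7 (LGN), 10.5 (V1); basal rates 4.50,
10.36, 6.79 spikes/s; kernel peak 0.8 s for all regions with FWHM 1.5 s
(SC, V1) or 0.8 s (LGN). The kernel shape parameters were solved
numerically so the analytic peak and the continuous FWHM hit those values
exactly: short kernel k = 6.62156, tau = 0.142309 s; long kernel
k = 2.652156, tau = 0.484216 s; d = 0.

## Synthetic sessions

A session emulates the study design: a 143 x 128 voxel coronal Doppler
plane at 5 Hz, 34-s trials (10 s baseline, 4 s stimulus, 20 s post; 170
frames), six stimulus contrasts (0-100%), and spiking binned at 100 um /
200 ms along a linear probe (30 bins SC-like, 25 LGN/V1-like).

* **Spiking.** Poisson counts per bin-frame with rate
  `basal + r(c) * B(x) * e(t)`. The contrast response `r(c)` is
  Naka-Rushton (`r_max c^n / (c^n + c50^n)`, c50 = 20%, n = 2; `r_max`
  chosen per region so the peak evoked dI is ~10%, inside the linear range
  the calibration is valid for). The drive envelope `e(t)` is a sustained
  component plus an adapting onset transient
  (0.5 + 0.5 exp(-t/0.8 s)) — the canonical evoked shape, which also gives
  the deconvolution problem usable spectral content.
* **Spatial footprint.** `B(x)` is an anisotropic Gaussian (depth FWHM
  1.4 mm, lateral 0.6 mm) tilted 10 degrees from the probe axis,
  multiplied by a log-normal coupling-gain texture (sd 0.8, correlation
  length 0.2 mm). The texture represents responsivity heterogeneity at the
  100-300 um scale — in Power Doppler the evoked gain is dominated by
  discrete vessels, and spike counts per 100-um bin vary strongly with
  local cell content. It is not cosmetic: a perfectly smooth separable
  field would make lateral probe displacements mathematically invisible to
  any correlation-based alignment (a laterally shifted trajectory would see
  the same time course rescaled, and Pearson correlation is
  scale-invariant), so the texture is what makes the alignment problem
  well-posed at the voxel scale.
* **Doppler.** The noiseless dSR field is pushed through the forward model
  (2-D Gaussian blur, causal temporal convolution with the sampled kernel),
  scaled so that the peak of the noiseless region-averaged dSR trace over
  the peak of the matching dI trace equals the region's calibration slope
  (the slope is defined on the measured curves, so the generator calibrates
  the same functional the analysis estimates), and embedded as
  `I = I_basal (1 + dI/100)` with additive Gaussian voxel noise (default sd
  1.0% per frame against a ~10% evoked peak; single-trial voxel SNR of
  order ten, reduced a further sqrt(n_trials) by averaging).
* **Storage.** The additive-Gaussian noise model makes the per-contrast
  trial-mean movie exactly simulable (noise sd / sqrt(n)); sessions store
  those means plus full per-trial movies on a window around the region (for
  per-trial statistics), with whole-grid per-trial movies only on request.
  This is an exact shortcut, not an approximation.

What the generator does **not** emulate: probe drift and brain motion,
clutter-filter residues and non-Gaussian Doppler noise, correlated (shared
low-frequency / state-dependent) noise between the modalities, spike-sorting
errors, negative or saturating hemodynamic responses. Passing recovery
tests therefore shows the estimators are correct and well-calibrated under
the stated statistical model, not that they are robust to every artifact of
real recordings.

## Analysis chain

1. **Normalization.** dI per voxel from the trial-mean movie; per-bin dSR
   from trial-averaged rates (a per-trial per-bin basal divisor at a
   4.5 spikes/s basal rate has ~15% CV and would inject 1/x noise);
   per-trial region traces (confidence bands, inclusion test) use the
   region-mean rate whose basal is well estimated per trial.
2. **Probe alignment.** 10,000 Monte-Carlo candidates around the initial
   trajectory estimate — integer tip shifts in [-5, 5]^2, slope offset in
   [-0.2, 0.2], out-of-grid candidates resampled; the unperturbed initial
   is always candidate 0, so ties and failures fall back to it. Scoring
   modes: plain concatenated-trace Pearson correlation; per-bin time means;
   and the default "profile" mode used by the experiments — response-window
   depth profiles with the spike profile smoothed by the hemodynamic blur
   (compare like with like), scored as the profile correlation plus twice
   the correlation of high-pass residuals, which isolate the gain texture
   that carries the lateral information. The Doppler profile averages each
   voxel with its immediate lateral neighbours (the evoked field is smooth
   at the PSF scale; the noise is not).
3. **Region averaging.** fUS: voxels within a 3-voxel lateral band around
   the trajectory intersected with the region mask; spikes: trajectory bins
   inside the region. One trace per contrast per modality.
4. **Amplitude calibration.** Per-contrast maxima (post-onset window) of
   the region-restricted trajectory traces; ordinary least squares of max
   dSR on max dI with an intercept, the 0%-contrast point included.
5. **Transfer function.** Lag-stacked design: each row holds dSR over
   frames t-20..t (21 taps, 4-s window), stacked across all contrasts;
   dI(t) as target. The default estimator corrects the ridge fit for input
   noise: the trial-averaged dSR regressor has per-frame variance v(t)
   (estimated from trial-to-trial scatter), which attenuates high
   frequencies and systematically widens a plain ridge kernel (at the
   LGN-like spike statistics the plain estimate widens a 0.8-s kernel to
   ~1.2 s). The Gram matrix is debiased by D = diag(sum_t v(t-j)) and the
   penalty chosen by leave-one-contrast-out cross-validation on the
   correspondingly debiased held-out risk; penalties that leave the
   corrected system non-positive-definite are discarded. A pure ridge path
   (`fit_tf`, `fit_tf_cv`) is kept alongside.
6. **Shape metrics.** Time-to-peak: first post-onset local maximum whose
   amplitude reaches half the post-onset maximum (the floor keeps an early
   noise ripple from posing as the peak; a strict first-inflexion mode
   exists). FWHM: longest run of samples strictly above half the peak,
   times the step — no sub-sample interpolation by default (an interpolated
   variant is available); the mean + 2 sd outlier rule is applied to
   collections before aggregate statistics. A gamma parameterization is
   fitted to the estimated kernel by bounded least squares from multiple
   starts.
7. **Spatial comparison.** Per-bin maxima during the stimulus window at the
   highest contrast, peak-aligned by integer shift; Pearson correlation on
   the overlap and the FWHM difference (positive = wider hemodynamic
   footprint). The spatial kernel sigma is estimated separately from
   window-mean profiles pooled over the 30/50/100% contrasts: least squares
   of the dI profile on the Gaussian-convolved dSR profile with a per-pair
   affine and a shared sigma, with an errors-in-variables correction — the
   measured per-bin input variance (including the basal-divisor term, which
   dominates at high response ratios) is subtracted from both the scale
   normal equation and the objective, removing the ~+0.05 mm widening bias
   a naive fit shows at these spike statistics.
8. **Inclusion filter.** Keep a session iff the highest-contrast response
   is significant in both modalities (one-sided paired t-test across trials
   of stimulus-window vs baseline-window means of the region-mean trace,
   alpha 0.05) and at least one trajectory bin lies in the target region.

## Numerical choices and degenerate inputs

* Half-open 200-ms spike bins [t, t+0.2); edge events go to the later bin;
  a trailing partial 5-contact group is dropped with a warning.
* Zero-baseline traces: error for a single trace, NaN + warning voxelwise.
* Zero-variance voxels report r^2 = 0 in correlation maps; constant curves
  are excluded (with a warning) from the two-step curve-max normalization
  (per-curve z-score, then one pooled affine rescale to [0, 1]).
* Alignment ties break to the lowest candidate index (the initial).
* Quartiles use linear interpolation (`numpy.percentile` default).
* Confidence bands are Student-t; a single trial reports no band.

## Problem sizes

Recovery experiments use 20 sessions per configuration at 6 contrasts x 20
trials with 2,000 alignment candidates; the alignment-robustness experiment
uses 20 replicates at 50 trials of the highest contrast with 10,000
candidates and voxel noise at half the evoked peak; the baseline-rate check
uses 50 trials. These sizes give sub-percent Monte-Carlo error on the
slope, kernel and rate recoveries while keeping a full run in minutes on
one core.

## Known limitations

* **Lateral tip localization is information-limited.** Depth (row) and
  slope errors are sharply identified by the depth profile, but lateral
  (column) information must pass through the 0.15-mm hemodynamic blur:
  only the high-frequency gain texture distinguishes neighbouring columns,
  and ~25-30 bins provide few independent texture samples. Even on
  noise-free forward-model data the correlation maximizer misses the true
  column by 2 voxels in ~10-20% of texture realizations, and at voxel noise
  of half the evoked peak the tip lands within one voxel in roughly 70-85%
  of replicates rather than all of them. This is a property of the
  estimation problem, not of the optimizer: a materially higher success
  rate would require information the blurred field does not carry.
* The transfer-function correction assumes input noise that is white across
  frames and independent of the Doppler noise; both hold in the generator
  and approximately in trial-averaged recordings, but shared state
  fluctuations in real data would violate it.
* The gamma parameterization is weakly identified near k -> 1 and trades k
  against tau; the fitted kernel and its sampled shape metrics are the
  stable outputs, the individual gamma parameters less so.
* The spatial sigma fit assumes the 1-D profile along the probe of the 2-D
  blurred field behaves like a 1-D convolution of the sampled profile;
  exact for an untilted Gaussian footprint, and accurate to ~+0.005 mm at
  the default 10-degree tilt.
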