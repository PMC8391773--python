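# Methods

This note documents the models, the numerical choices, and what the
synthetic validation does and does not establish.

## Problem and model

The task is binary classification of 5-minute heart-rhythm segments:
*pre-AF* (a window ending at, or a stated offset before, an atrial
fibrillation onset) versus *control* (normal sinus rhythm).  The working
assumption is electrophysiological: premature atrial contractions (PACs)
become more frequent in the minutes before AF onset.  A PAC shortens one RR
interval and is typically followed by a compensatory pause, so the
tachogram acquires impulsive short–long couplets.  Every feature family is
chosen to be sensitive to this signature: dispersion statistics (RMSSD,
SD1), the unpredictable power left by an autoregressive fit, high-frequency
band energy, and the envelope/energy/entropy of sub-band decompositions
that isolate the 0.3–0.7 Hz range where couplet variability concentrates.

## Preprocessing

Units are fixed package-wide: RR intervals in milliseconds, times in
seconds.  Three views of each segment feed the features:

* **raw RR** — time-domain and nonlinear features; no correction, since
  ectopy is the signal.
* **corrected 4 Hz series** — frequency-domain features.  Ectopic intervals
  are flagged by the impulse-rejection statistic
  D(i) = |RRᵢ − median| / (1.483 · max(MAD, 1 ms)) with threshold τ = 4,
  then replaced by cubic-spline interpolation over the unflagged
  neighbours.  Spline replacements are clipped into the range of the
  unflagged intervals: when flagged beats cluster, an unconstrained cubic
  can overshoot to non-physiological (even negative) values, and clipping
  is the smallest intervention that preserves the interpolation elsewhere.
  A `delete` mode (drop flagged beats instead) is available.
  The filter is idempotent because the statistic is computed from the
  input series only.
* **uncorrected 4 Hz series** — VFCDM and TQWT features.

Resampling anchors each interval at its closing beat and evaluates the
cubic spline on a uniform 0.25 s grid spanning first to last beat time (the
sub-second stretch before the first interval anchor is extrapolated).  The
anchor convention shifts spectra by at most half a mean beat period and is
stated here because alternatives (opening beat, interval midpoint) are
equally defensible.  Detrending is a zero-phase 2nd-order Butterworth
high-pass at 0.01 Hz applied forward–backward, with the residual mean
subtracted so the output is exactly zero-mean; the cutoff is exposed as
`preproc.detrend_cutoff`.

R-peak detection uses a standard derivative/energy detector (5–25 Hz
band-pass, squared gradient, 150 ms integration, adaptive threshold,
200 ms refractory, refinement to the local band-passed maximum within
±50 ms).  Its contract — ≥ 99.5 % of beats within 20 ms with ≤ 1 false
positive on the synthetic ECG — is what the downstream features rely on;
any detector meeting it can be substituted.

## Feature conventions

* Sample (n−1) variance wherever a standard deviation is taken, so the
  Poincaré identity SD1² + SD2² = 2·Var(RR) holds exactly.
* Skewness/kurtosis are of the RR intervals (not of instantaneous rate; a
  config flag is not provided because the interval moments are the ones the
  rest of the pipeline uses), and kurtosis is the raw moment ratio (3 for a
  Gaussian), not excess.
* "RMSSD divided by mean heart rate" is implemented as RMSSD / mean(RR):
  dimensionless either way, and this reading directly normalises out the
  between-subject rate difference.
* Entropies use m = 2 and r = 0.2·SDNN of the segment with a 1 ms floor so
  constant series remain well defined (SampEn = ApEn = 0).  Undefined
  values (zero template counts, zero denominators) are NaN sentinels, never
  exceptions; selecting a subset through `assemble_features` turns
  sentinels into an explicit error naming the offending features.
* Multiscale entropy fixes the tolerance from the scale-1 series and is
  computed at scales 1–5; it is an extended feature only, not in the
  selected 14.
* The AR residual power fits order p = 12 by conditional least squares on
  the mean-removed intervals (Yule–Walker available via `method=`); the
  residual variance estimates the unpredictable, ectopy-driven power.
* Triangular index uses 1/128 s histogram bins, the classic convention
  matched to a 128 Hz acquisition clock.
* Band powers integrate the Welch density over half-open bands
  VLF [0, 0.04), LF [0.04, 0.15), HF [0.15, 0.40) Hz.  A configuration
  switch (`freq.lf_includes_vlf` / `BAND_EDGES_LF_INCLUDES_VLF`) instead
  starts LF at 0 Hz, making VLF a subset of LF, for compatibility with
  sources that tabulate the bands that way; the standard edges are the
  default because overlapping bands double-count power.  Denominators
  below 1e-12 ms² count as zero when forming LF/HF, LFn, HFn.

## VFCDM

The 4 Hz series is decomposed into K = 12 equal-bandwidth components by
complex demodulation: multiply by e^(−j2πfᵢt), low-pass, remodulate, with
fixed centers fᵢ = (2i−1)·F_w.  The half-bandwidth is F_w = fs/(2(2K+1)) =
0.08 Hz, the value that reproduces the center table 0.08 … 1.84 Hz exactly;
the twelve bands of width 2F_w then tile [0, 1.92] Hz, leaving one band
width below the 2 Hz Nyquist.  The low-pass filters are 129-tap Hamming
FIR, applied by symmetric convolution (zero phase); edge transients are
masked, not trimmed.

Stage 2 refines each component by re-demodulating **the stage-1 component
itself** around its own instantaneous frequency (gradient of unwrapped
phase, smoothed by a 51-sample moving median, clipped to the band) with a
narrower F_w/2 low-pass.  Refining each component against itself — rather
than re-demodulating the original signal — keeps the exact frequency
tiling of stage 1, so Σᵢ Vᵢ still reconstructs any band-limited input;
demodulating the original signal would double-count a tone on a band edge
when two adjacent bands' instantaneous frequencies converge on it.
`vfcdm.single_stage=True` disables the refinement for diagnostics.

Components 3 + 4 (0.40/0.56 Hz) are summed; the instantaneous amplitude of
the discrete analytic signal (FFT construction, outer 5 % masked) gives the
mean/variance/energy features.  The variance is taken of a(t), not of the
reconstructed signal, since the amplitude is what tracks couplet bursts.

## TQWT

The transform is an iterated two-channel frequency-domain filter bank with
low-pass scaling α = 1 − β/r and high-pass scaling β = 2/(Q+1); Q = 3,
r = 4, J = 17 gives α = 0.875, β = 0.5.  Channel lengths are rounded to
even sizes per stage; the transition between channels uses
θ(ω) = ½(1+cos ω)√(2−cos ω), which is power-complementary
(θ(ω)² + θ(π−ω)² = 1), so analysis/synthesis reconstruct to machine
precision and sub-band energies sum exactly to the input energy (a tight
frame — verified to 1e-12 in the tests).  Unitary DFTs are used at every
channel length.

Nominal centers follow f_c(j) = α^j (2−β)/(4α) · fs, which reproduces the
descending table 1.31, 1.15, 1.00, … 0.18 Hz (2 dp) for j = 2..17 at 4 Hz
and is cross-checked against impulse-response spectral peaks.  The formula
gives 1.5 Hz for j = 1 where the reference tabulation says 2 Hz; the first
band's response is one-sided against Nyquist so its "center" is
convention-dependent, and since band 1 feeds no selected feature the
discrepancy is recorded without resolution.

Band signals for the energy and entropy features are full-length
single-band reconstructions (all other bands zeroed before synthesis), so
every band shares the input's time base; `coeff_domain=True` switches to
the raw decimated coefficients.  The spectral-entropy feature ENT uses a
Hann spectrogram with 128-sample frames at 50 % overlap (unstated in the
source method; logged in metadata), per-frame normalisation to a
probability distribution, Shannon entropy in bits, and the L2 norm over
frames.

## Classification and evaluation

The selected 14 features are z-scored with training-set statistics stored
in the model bundle.  The RBF SVM tunes C ∈ {0.1, 1, 10, 100} ×
γ ∈ {0.01, 0.1, 1/14, 1} by inner 5-fold grid search (the reference method
tuned by cross-validation without printing values); the random forest uses
50 trees, unlimited depth, √14 candidate features per split, seeded.  kNN
(K = 5, Euclidean/Manhattan) and five discriminant-analysis variants
(linear, quadratic, diagonal-covariance versions of both, and
nearest-class-mean in pooled Mahalanobis distance) complete the classifier
menu.  Cross-validation is stratified with seeded shuffling, re-fits the
scaler inside each training fold, and pools fold predictions into one
confusion matrix before computing SEN/SPE/ACC/PPV/NPV (reported in percent
at 2 dp; zero denominators give NaN sentinels).  Pooled reporting is
chosen over averaging per-fold metrics because a single confusion matrix
is the natural summary of one pass over the data.

The backward protocol extracts, for offsets {0, 150, 300, 450, 600} s (5-min
windows at 50 % overlap back to 15 min), the window [onset − o − 300,
onset − o], featurises, predicts with the already-trained model, and
reports per-offset metrics; control records reuse one fixed reference point.
Records too short for an offset are excluded from that offset with a count.

## Synthetic data: what it emulates, what it does not

`generate_nsr_rr` builds interval k as mean + LF·sin + HF·sin + noise with
defaults 800 ms mean, 20 ms LF at 0.095 Hz, 10 ms HF at 0.25 Hz, 5 ms white
noise over 300 s — magnitudes typical of resting short-term HRV, with the
LF tone placed away from the 0.04/0.15 Hz edges so band integrals are
unambiguous.  PAC injection at rate λ/min picks non-adjacent sites
(optionally with density ramping linearly toward the record end, emulating
ectopy accelerating into an onset) and applies RRₖ → c·RRₖ,
RRₖ₊₁ → (2−c)·RRₖ + (RRₖ₊₁ − RRₖ) with c ~ U(0.55, 0.80): a premature beat
plus a full compensatory pause that preserves the couplet sum and hence the
mean rate, so features respond to variability rather than rate.  Cohorts
default to 0.5 PACs/min (controls; occasional benign ectopy) versus 10/min
(pre-AF), mirroring a 25 + 25 design.  The synthetic ECG places a
Gaussian-bump P-QRS-T template at each beat time (1 mV R, 80 ms QRS
footprint) plus 0.2 Hz/0.05 mV baseline wander and 0.02 mV noise.

Not emulated: respiratory sinus arrhythmia coupling, non-compensated or
interpolated PACs (a switch exists for the former), atrial runs/bigeminy,
waveform morphology changes before onset, noise/artifact bursts, or any
detailed AF-onset dynamics.  Passing tests therefore establish that the
pipeline recovers *injected couplet-type ectopy* and that the advertised
numerical identities hold — not that the classifier reaches any particular
accuracy on clinical recordings, where class overlap is far larger.

Validation problem sizes: monotonicity checks use medians over 20 seeds at
rates {0, 2, 6, 12}/min; the end-to-end benchmark is a 25 + 25 cohort with
5-fold cross-validation; the backward-horizon check uses 10 cohorts of
8 + 8 training and 6 + 6 evaluation records of ~20 minutes with ramped
ectopy (4/min overall, ramp factor 8) — sizes chosen to keep the full
validation suite fast while leaving the monotone effects far clearer than
seed noise.

## Known limitations

* WFDB support is single-segment, formats 212/16, one signal file per
  record; multi-segment layouts must be concatenated by the caller.
* The impulse-rejection statistic uses the global median/MAD of the 5-min
  segment; drifting baselines within a segment could mask ectopy (the
  0.01 Hz detrend mitigates this only for the resampled paths).
* VFCDM stage-2 refinement narrows each component around its instantaneous
  frequency; for broadband (noise-like) inputs some in-band energy is
  attenuated relative to stage 1.  Reconstruction error stays < 5 % RMS
  for multi-tone inputs in [0.02, 1.9] Hz, the regime tachograms occupy.
* The classifier menu is deliberately shallow (no probability calibration,
  no feature selection machinery); the 14-feature subset is fixed.
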