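# Methods

## Spectral estimation

The Blackman–Tukey estimator computes, per channel and 10-s segment, the
biased autocorrelation to a maximum lag of 1 s, tapers it with a Blackman
lag window (unit weight at zero lag), and Fourier-transforms the symmetric
sequence, zero-padded so the display grid spacing is at most 0.1 Hz. The
true spectral resolution is set by the lag window (≈ 1/max-lag ≈ 1 Hz main
lobe); the 0.1-Hz grid only samples the smoothed spectrum densely. Small
negative side-lobe values produced by the lag window are clipped to zero,
so the integrated spectrum equals the signal variance up to that clipping
(the white-noise tests bound the discrepancy at 10%). Both the maximum lag
and the grid spacing are configurable.

Aggregation order, which the per-recording summary leaves open, is: average
PSDs across segments, then across channels, then normalise the average once
on 1–70 Hz. This yields a single MF/IAF/SE per recording. The alternative —
normalise each channel to unit mass first, then average — is available as
`per_channel_normalize` and also produces a unit-mass distribution; the two
differ when channels carry very unequal total power.

Discrete-grid conventions: MF is the smallest grid frequency whose
cumulative mass reaches 0.5 (no interpolation; a linearly interpolated
variant sits behind `mf_interpolate`). IAF is the first in-band argmax
(ties break toward lower frequency); when the in-band maximum sits at a
band edge and the mass is monotone across the band there is no alpha peak,
and the edge value is returned with `iaf_peak_found=False` rather than a
sentinel, so downstream analyses decide explicitly whether to keep flagged
values. SE uses natural logarithms normalised by log of the in-band bin
count, hence 1 for a flat spectrum regardless of grid resolution. Band
powers follow the printed band edges (0–3, 4–7, 8–12, 13–25, 26–40,
41–80 Hz); grid bins strictly between printed edges belong to no band, so
band fractions can sum to slightly less than 1, and the delta and
high-gamma bands are truncated in practice at the 1- and 70-Hz PSDn
support. The 50-Hz band-stop is an IIR notch (quality factor f0/bandwidth,
default bandwidth 2 Hz) applied forward and backward for zero phase.

## Score model

Scores are assumed flat between the initial assessment and the first
treatment day, then linear across the treatment period; the estimated
score at the recording day follows from those two assumptions. Signs are
Last − Initial (outcome) and Last − Estimated (estimated change), so a
positive MMSE-like change and a negative ADAS-like change both mean
improvement. A recording day after the last assessment cannot occur under
the study design but can under a generator; it is capped at the last
assessment day with a warning. Calendar days are integer offsets from an
arbitrary epoch and all derived quantities are shift-invariant.

## Resampling inference

The bootstrap resamples participants with replacement, 20,000 times by
default, and reports the smaller of the two tail fractions around zero as
the p-value — deliberately *not* doubled, matching the convention the
analysis reproduces. This quantity is one-sided: under the null it is
approximately uniform on [0, 0.5], so thresholding it at 0.05 rejects at
roughly twice that rate even in large samples, and at n = 16 the
percentile pairs bootstrap of Pearson's r is further anticonservative
(measured ≈ 0.15 at the 0.05 threshold, ≈ 0.08 after doubling; the
calibration driver `analysis/05_bootstrap_calibration.py` and the
acceptance suite compute both). Users wanting conventionally calibrated
two-sided inference should pass `--two-sided` and still read small-n
p-values conservatively. Resampled statistics exactly at zero (or resamples
where a correlation is undefined because a resampled variable is constant)
fall in neither tail and are surfaced via `n_degenerate`.

BH-FDR is applied once across the whole pairwise family by default (a
per-instrument family partition is a configuration choice away). The scan
derives one seed per variable pair from the master seed and the pair
labels, so the association table is invariant to scan order; pairs with a
constant variable produce an `r = NaN` row excluded from the BH family
rather than an error.

## Synthetic data

The generator shapes one-sided Fourier amplitudes to the analytic target
spectrum `C·f^(−β)·boost(f) + alpha bump` and randomises phases only, so
the periodogram of each realisation equals the target exactly and the
estimators can be validated against closed forms. The 1/f curve is clamped
below 0.5 Hz to avoid the DC divergence; the alpha bump is Gaussian with
its bandwidth parameterised as full width at half maximum and its area set
to a requested fraction of the 1–70 Hz mass; the sub-8-Hz boost is the
"slowing" knob; an optional 50-Hz sinusoid emulates line noise. Channels
are independent realisations — sensor-level statistics here average across
channels, so cross-channel covariance would not change the test surface —
and signals are Gaussian-like but not physiological: no transients, no
artifacts, no nonstationarity. Passing tests therefore demonstrate correct
estimator behaviour on stationary spectra with known shape, not robustness
to real recording artifacts (recording-level exclusion flags stand in for
artifact rejection). Test-scale defaults are 200 Hz / 60 s / 8 channels;
the study-scale acquisition (2,000 Hz / 300 s / 160 channels) is available
behind `--full-scale`.

Cohorts: a latent slowing factor `z ~ N(0,1)` sets each participant's
low-band boost `exp(0.5·z)`; the analytic median frequency implied by that
boost is standardised and mixed into the score change as
`change = μ + σ·(ρ·u + sqrt(1−ρ²)·ε)`, so the correlation between the
(nearly deterministic) recording MF and the outcome approximates the
requested ρ. Initial scores, group-level change means and SDs, treatment
period lengths (126–245 days), session counts (14–29), recording delays
(0–76 days) and ages emulate the study cohort's reported ranges. Scores
are clipped to instrument ranges and clipping events counted: the
MMSE-like instrument's 30-point ceiling clips ~20% of participants at the
default settings and attenuates the realised correlation there, so
parameter-recovery checks use the lightly clipped ADAS-like instrument.
Alpha-peak centers get independent ±0.75 Hz jitter (kept clear of the band
edges) so IAF varies across a cohort; note that the *estimated* IAF still
acquires a weak coupling to slowing because the boosted 1/f background
leaks into the alpha band under the 1-Hz smoothing — a property of the
estimator, not of the generated peaks.

## Problem sizes

Routine tests and the acceptance script use the test-scale signal defaults,
20 seeds per spectral-oracle condition, 1,000 replicates × 2,000 resamples
for calibration, and n = 500 cohorts with 20,000 resamples for end-to-end
recovery; these sizes give Monte-Carlo error comfortably below the asserted
tolerances.

## Known limitations

- The smaller-tail p-value is not a calibrated two-sided test; see above.
- IAF is only meaningful when an alpha peak exists; use the
  `iaf_peak_found` flag.
- The piecewise-linear score model ignores practice effects and any change
  between assessment and treatment start by construction.
- EDF files are read (via mne) but not written; the text recording format
  is the interchange format.
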