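# Methods

This note records the models, conventions and numerical choices behind
`fiberphot`, and what the synthetic fixtures do and do not establish.

## Data model

A **Recording** is a time-indexed table: a strictly increasing time vector in
seconds, named numeric channels of equal length, and a nominal rate in Hz.
Missing samples are explicit NaN and are never silently dropped, so channels
stay row-aligned with time.  A **SpectralBlock** is a wavelength-bins ×
frames intensity matrix with a strictly increasing wavelength axis and a
frame clock (`t0 + k / frame_rate_hz`).  User-facing row/column/sheet indices
are 1-based (lab-spreadsheet convention); internal arrays are 0-based numpy.
Sessions serialize to a schema-versioned JSON archive; loading refuses
unknown versions and corrupt files rather than restoring partial state.
Spreadsheet output is limited by the xlsx format to 15 significant digits;
the CSV dialects round-trip at full float precision (readers use round-trip
float parsing).

## Spectral unmixing

Each frame *y* is fit by ordinary least squares against the matrix *X* of
normalized reference spectra, solved for all frames at once via
`numpy.linalg.lstsq`; `residual_rms` is the per-frame RMS misfit, which on
synthetic data calibrates to the injected noise SD.  Choices:

- **Unconstrained OLS by default.**  A non-negative variant (NNLS) is
  provided (`nonnegative=True`) since physical intensities cannot be
  negative, but the default matches plain linear regression coefficients.
- **Intercept off by default**: background is better modeled as an explicit
  reference spectrum column than as a wavelength-independent offset.
- References are linearly interpolated onto the block's bins; extrapolation
  outside the reference wavelength range is an error.
- Collinear references raise a rank error naming the most collinear pair
  (largest normalized inner product).

Band summaries take mean/median/trapezoidal AUC over bins whose centers lie
in `[lo, hi]` (inclusive); AUC integrates over the wavelength axis, so its
units are intensity·nm.  Band ratios map near-zero denominators
(|den| < 1e−12) to NaN; a ratio trace is normally detrended afterwards
(exponential by default, configurable), since bleaching rarely cancels
between bands.

## Signal conditioning

- **Nearest-neighbor alignment**: for each base timestamp the closest sample
  of the other stream is taken; exact midpoint ties take the earlier sample;
  queries outside the other stream's span clamp to its endpoints and are
  counted in a coverage report (plus a warning).  On identical time axes the
  operation is the identity.
- **Row-wise append**: the second recording's clock is shifted so sampling
  continues one period after the first recording's last sample (plus an
  optional gap).  Both recordings must share the channel set and the nominal
  rate — appending streams at different rates would silently corrupt the
  nominal-rate bookkeeping downstream.
- **Low-pass + downsample**: 4th-order Butterworth run forward-backward
  (zero phase, ≥24 dB/octave), then every *k*-th sample kept and the nominal
  rate divided by *k*.  The cutoff must lie below Nyquist.
- **Linear scaling** fits `target ≈ a·source + b` by simple regression and
  emits the scaled source with the fitted coefficients — the
  magnitude-matching step used before control-channel correction and in
  robust z-score pipelines.
- **Detrending** models photobleaching as `a + b·t` or `a·exp(−b·t) + c`
  (offset included: bleaching plateaus at the autofluorescence floor; decay
  rate constrained b ≥ 0).  Nonlinear fits use a deterministic start —
  `c₀ = last value`, `a₀ = first − last`, `b₀` from a log-linear fit of the
  positive part of `(y − c₀)` — then `scipy.optimize.curve_fit`; manual
  parameters bypass fitting.  Residual + prediction reconstructs the raw
  channel exactly at every sample (pure subtraction, no refitting).

## Periodicity diagnostics

Autocorrelation is mean-removed with **biased** normalization (divide by n),
so r[0] = 1 and the sequence is the standard correlogram; the unbiased
variant inflates high-lag noise and was not adopted.  The PSD is a Welch
averaged periodogram (Hann window, 8 s segments, 50% overlap by default);
`sum(power)·df` approximates the signal variance and the axis tops out at
the Nyquist frequency (12.5 Hz at 25 Hz sampling).  The spectrogram is the
short-time analogue with column timestamps at window centers.  Missing
samples are linearly interpolated before any spectral estimate (the FFT
needs a regular grid), with a warning carrying the count.

## Events

All event times are real seconds on the **half-open** convention
`[start, end)`: adjacent bins never double-count a shared boundary.

- **Binary**: one event per maximal run of 1s (rising edge through the next
  falling edge); inverted uses runs of 0s.  A run reaching the recording end
  closes at the last timestamp, so a run consisting solely of the final
  sample is degenerate and dropped; with that rule, the normal and inverted
  series exactly tile `[t₀, t_last)` with no gaps or overlaps.
- **Binned**: `[t0 + iL, t0 + (i+1)L)` kept while fully inside the span
  (tolerance 1e−9 s for float accumulation); trailing partial bins dropped.
- **Peaks**: sample *i* is flagged when `x_i > mean + k·sd` over the window
  of samples within L/2 seconds of *t_i* — centered, truncated at the edges,
  sample (n−1) SD; events are maximal flagged runs.  Windows must span at
  least 3 samples at the nominal rate.  Implemented with cumulative sums
  (O(n)); the test suite checks it against a direct per-sample enumeration.
- **Conditions** are a bounded expression grammar (comparisons between
  channel names, `time`, and numeric literals, combined with and/or/not and
  parentheses), compiled via a whitelisted AST walk; function calls and any
  other host-language construct are rejected.  Missing samples evaluate to
  false.  Mode `all` requires the condition at every in-event sample, `any`
  at one or more; events containing no samples are dropped.
- **Filter catalogue** (applied successively, order significant):
  first/last keep/drop; shift (both endpoints, preserving length);
  pad-to-minimum-length (extends the end only); truncate-to-maximum;
  drop-shorter/drop-longer with inclusive keep semantics (≥ / ≤);
  aggregate-within (merge when next start − previous end ≤ gap); coalesce
  (merge strictly overlapping; idempotent); minimum rate (count / recording
  span, all-or-nothing on the series); before/after a timestamp by event
  start, include or exclude; drop-successive-within (drop events starting
  within the gap of the previously *retained* event's end).  Each step logs
  before/after counts.
- **Intervals** are named windows anchored at event start, event end, or the
  event signal itself (offsets ignored); the non-overlap variant clips the
  window start to the maximum of the preceding event's end and its resolved
  interval ends.  Windows that collapse after clipping are dropped with a
  warning.  Shifted/padded events may extend past the recording span; they
  are not clamped.

## Normalization

Formulas as in the README.  Fixed choices: baseline SD uses the sample
(n−1) denominator; MAD carries no 1.4826 consistency constant; the robust
z-score applies no re-centering beyond its median subtraction; the baseline
interval is designated by name (default `"baseline"`).  Each event is
normalized strictly against its own baseline — events whose baseline window
resolves to fewer than 2 finite samples are dropped with a warning.  A
negative baseline mean flips ΔF/F signs and triggers a warning rather than
an error.

## Event-triggered analytics

Time zero anchors at the event-signal start; baselines occupy negative
times.  Each event is resampled onto the common grid by nearest sample
within half a grid step (no interpolation — interpolating would manufacture
data inside gaps), else missing.  Statistics run over the events available
per grid point: mean; sample SD (0 where a single event covers);
SE = SD/√n; the band half-width is a user multiplier times either.  Heatmap
sorts are descending for length and AUC (trapezoid over the requested
relative-time window, endpoints inclusive), with ties broken
chronologically.  Interval summaries emit one row per (event, interval,
statistic).

## Synthetic generator

`make_recording` produces `trend(t) + Σ transients + N(0, σ)` plus an exact
TTL channel; `make_behavior` a binary bout channel at an independent rate;
`make_spectral` frames mixed from Gaussian-peaked reference spectra (515/580
nm defaults, the classic green/red overlapping pair).  The default recording
is a 900 s session at 25 Hz with five 10 s tones at onsets 120–720 s,
transient amplitude 20 on a baseline of 100 (20% ΔF/F) and unit noise; the
transient kernel rises with τ ≈ 0.2 s, holds while the stimulus lasts, and
decays with τ ≈ 1.5 s — the response a slow indicator gives a sustained
stimulus; with zero duration it reduces to the standard
difference-of-exponentials impulse kernel.  Fixed seed ⇒ byte-identical
output.

What the generator does **not** emulate: motion artifacts and hemodynamic
contamination, isosbestic-channel crosstalk, sensor nonlinearity and
saturation, non-exponential (piecewise/biexponential) bleaching, non-Gaussian
noise, and timestamp jitter.  Passing tests therefore establish the
correctness of the pipeline's arithmetic and bookkeeping on well-posed
inputs, not robustness to those real-data pathologies.

## Problem sizes and tolerances

The test suite and the acceptance script run at desk scale: randomized
detector cross-checks use hundreds to a thousand recordings of ≤ 200
samples (the O(n²) peak oracle on a subset); end-to-end scenarios use one
900 s and two 300 s sessions.  Exact fixtures assert equality; OLS
agreement at 1e−10; noiseless recoveries at 1e−8…1e−6; stochastic
recoveries (SNR 20 detrending, ETA amplitude) at 5–10% with fixed seeds.

## Known limitations

Vendor binary acquisition formats are out of scope (export to tabular text
first); no pooled-baseline or isosbestic-regression ΔF/F variants beyond
linear scaling; no streaming/online detection; no inferential statistics
across groups.  The condition grammar is deliberately not a script hook — 
complex derived channels should be computed in Python and added as channels
before detection.
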