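# fiberphot

Scriptable analysis of fiber-photometry recordings: spectral unmixing of raw
spectrometer frames, signal conditioning (alignment, photobleaching
detrending, scaling, filtering), a general event
detection/filtering/interval system, per-event baseline normalizations, and
event-triggered analytics with tabular export.

Fiber photometry records bulk fluorescence from genetically encoded sensors
(calcium indicators, neurotransmitter sensors) through an implanted optical
fiber while an animal behaves.  The analysis problem is always the same
shape: turn raw streams (spectrometer frames, demodulated channels, video
behavior scores) into named time series, cut out *events* — stimulus
presentations marked by TTL pulses, or behavioral bouts such as wheel
running — normalize each event against its own baseline window, and
summarize across events.  `fiberphot` is a library for exactly that
pipeline, aimed at behavioral neuroscientists and analysts who want the
steps explicit and reproducible in Python rather than hidden in a GUI.

## Core methods

**Linear spectral unmixing.**  With overlapping emission spectra (e.g. a
green activity indicator and a red static control), each spectrometer frame
*y* (intensity over wavelength bins) is decomposed by ordinary least squares
against normalized reference spectra *X*: the per-frame coefficients
ĉ = argmin‖y − Xc‖ are the fluorophore intensity time courses.  A
wavelength-band alternative summarizes user-chosen ranges (mean, median,
trapezoidal AUC) per frame.

**Per-event normalization.**  Each event carries its own baseline interval
*r* (mean r̄, sample SD σ_r); baselines are never pooled across events:

- z-score: `z_i = (x_i − r̄) / σ_r`
- ΔF/F: `(x_i − r̄) / r̄` (also as %ΔF/F)
- robust z-score: `RZ_i = (%ΔF/F_i − median(%ΔF/F(r))) / MAD(%ΔF/F(r))`,
  with MAD the unscaled median absolute deviation — outlier-resistant at the
  cost of a median-centered reference.

**Events and intervals.**  Events are half-open periods `[start, end)`
detected from binary indicator edges, fixed time bins, moving-window peak
exceedance (`x > mean + k·SD` over a centered window), or manual timestamp
lists; gated by per-timestep condition expressions (`"time < 360 and
speed > 2"`); refined by an ordered catalogue of eleven filters (aggregate
within a gap, coalesce, pad/truncate, length and rate thresholds, shifts,
before/after selection, …); and given named interval windows anchored to
event start/end, including a non-overlapping baseline variant.

**Event-triggered analytics.**  Events are aligned at time zero and
resampled to a common grid: averaged traces with SD/SE bands, heatmaps
sortable by order, length, or AUC, and per-interval summary tables.

## Worked example

`examples/03_tone_events_eta.py` builds a synthetic 900 s session at 25 Hz
with five 10 s tones (transient amplitude 20 on a baseline of 100, i.e. a
20% ΔF/F response), detects the TTL events, normalizes each with a 3 s
pre-event baseline, and averages:

```
detected 5 tone events: [(120.0, 130.0), (270.0, 280.0), (420.0, 430.0), (570.0, 580.0), (720.0, 730.0)]
in-event ΔF/F mean 0.196 (injected amplitude/baseline = 0.200)
interval  stat
baseline  mean     -0.0000
          median   -0.0000
event     mean      0.1961
          median    0.1995
post      mean      0.0589
          median    0.0409
```

The detector recovers exactly the five scheduled tones; the event-triggered
average recovers the injected 20% response (0.196 measured, the small
deficit being the indicator's onset rise); baseline intervals center at zero
by construction, and the post window shows the decay after tone offset.  The
other examples cover spectral unmixing, detrending and conditioning, the
behavior-driven wheel-running workflow, and periodicity diagnostics — each
prints the numbers it computes and what they mean.

A thin CLI covers the shell-useful pieces: `fiberphot synth|unmix|band|detect`.

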