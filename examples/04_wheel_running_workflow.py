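"""Behavior-driven events without a TTL: wheel-running bouts.

Two 300 s photometry recordings (before/after a manipulation) are joined
row-wise; a binary running score sampled at a slower video rate is aligned
onto the photometry clock by nearest-neighbor sampling.  Bouts separated by
short pauses are aggregated, too-short bouts dropped, and the surviving
variable-length bouts are normalized (ΔF/F, 20 s non-overlapping baseline)
and laid out as a heatmap.
"""

import warnings

from fiberphot import (FilterStep, IntervalSpec, SynthSpec, Transient,
                       align_nearest, append_rows, apply_filters,
                       detect_binary, heatmap_matrix, make_behavior,
                       make_recording, normalize_events)

bouts_a = [(60.0, 68.0), (69.5, 90.0), (150.0, 153.0), (200.0, 240.0)]
bouts_b = [(30.0, 36.0), (100.0, 140.0), (141.0, 150.0), (250.0, 252.0)]
seg = dict(duration_s=300.0, rate_hz=20.0, baseline_mu=80.0, noise_sd=0.5,
           ttl_schedule=[])
rec_a, _ = make_recording(SynthSpec(
    **seg, seed=2, transients=[Transient(s, 6.0, 0.3, 2.0, e - s) for s, e in bouts_a]))
rec_b, _ = make_recording(SynthSpec(
    **seg, seed=3, transients=[Transient(s, 6.0, 0.3, 2.0, e - s) for s, e in bouts_b]))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # edge samples clamp to the behavior span
    rec_a, _ = align_nearest(rec_a, make_behavior(bouts_a, 300.0, rate_hz=10.0), ["running"])
    rec_b, _ = align_nearest(rec_b, make_behavior(bouts_b, 300.0, rate_hz=10.0), ["running"])
joined = append_rows(rec_a, rec_b)
print(f"joined recording: {joined.n_samples} samples over "
      f"{joined.span[1] - joined.span[0]:.0f} s")

bouts = detect_binary(joined, "running")
filtered = apply_filters(bouts, [
    FilterStep("aggregate_within", {"gap_s": 2.0}),   # merge pause-split bouts
    FilterStep("drop_shorter", {"min_s": 5.0}),       # discard spurious blips
], joined.span)
print(f"{len(bouts)} raw bouts -> {len(filtered)} after aggregation/length filtering")
print("bout lengths (s):", [round(e.length_s, 1) for e in filtered])

intervals = [IntervalSpec("baseline", "event_start_nonoverlap", -20.0, 0.0),
             IntervalSpec("event", "event_signal")]
normed = normalize_events(filtered, intervals, joined, "signal", method="dff")
hm = heatmap_matrix(normed, grid_step_s=0.05, sort="length")
print(f"heatmap: {hm.values.shape[0]} rows (one per bout) x "
      f"{hm.values.shape[1]} time bins, sorted by {hm.sort_key}")
# Ragged bouts share one time grid; rows end (become missing) where each
# bout does, so the heatmap shows every running event aligned at onset.
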