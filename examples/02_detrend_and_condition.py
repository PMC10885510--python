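"""Correct photobleaching and condition a recording.

Generates a 600 s recording whose fluorescence decays exponentially
(photobleaching) on top of transients, fits the decay by least squares,
subtracts it, then low-pass filters and downsamples the corrected trace.
"""

import numpy as np

from fiberphot import (SynthSpec, Transient, apply_detrend, fit_detrend,
                       lowpass_downsample, make_recording)

spec = SynthSpec(duration_s=600.0, rate_hz=25.0, baseline_mu=50.0, noise_sd=0.5,
                 bleach_amplitude=30.0, bleach_rate=1 / 200.0,
                 transients=[Transient(o, 5.0, 0.2, 1.5, 5.0) for o in (100, 300, 500)],
                 ttl_schedule=[], seed=4)
rec, truth = make_recording(spec)

model = fit_detrend(rec, "signal", kind="exponential")
p = model.params
print(f"fitted trend: {p['a']:.2f} * exp(-{p['b']:.5f} t) + {p['c']:.2f}")
print("generating trend: 30.00 * exp(-0.00500 t) + 50.00")
# The fitted amplitude/rate/offset recover the injected photobleaching model.

corrected = apply_detrend(rec, "signal", model, out="resid")
slope = np.polyfit(corrected.time, corrected.channels["resid"], 1)[0]
print(f"residual linear drift: {slope:.2e} per s (raw drift "
      f"{np.polyfit(rec.time, rec.channels['signal'], 1)[0]:.2e} per s)")
# Detrending removes the slow decay; the residual is flat around zero.

down = lowpass_downsample(corrected, "resid", cutoff_hz=2.0, factor=5)
print(f"downsampled {corrected.n_samples} -> {down.n_samples} samples at {down.rate_hz} Hz")
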