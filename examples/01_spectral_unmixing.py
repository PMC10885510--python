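"""Decompose spectrally resolved frames into per-fluorophore time courses.

Builds a synthetic wavelength x frame matrix mixed from two overlapping
Gaussian emission peaks (a 515 nm activity signal over a constant 580 nm
control), then separates them by per-frame least squares against the
normalized reference spectra, and by a wavelength-band summary.
"""

import numpy as np

from fiberphot import SpectralSynthSpec, band_ratio, make_spectral, summarize_band, unmix

block, refs, truth = make_spectral(SpectralSynthSpec(noise_sd=0.5, seed=1))
result = unmix(block, refs)

err = {name: float(np.max(np.abs(result.coefficients[name] - truth[name])))
       for name in refs.names}
print(f"frames: {block.n_frames}, wavelength bins: {block.wavelengths_nm.size}")
print(f"max |estimated - true| coefficient: green {err['green']:.3f}, red {err['red']:.3f}")
print(f"mean residual RMS {result.residual_rms.mean():.3f} (injected noise SD 0.5)")
# The unmixing error is at the noise scale and the residual RMS calibrates to
# the injected noise: the regression separates the overlapping fluorophores.

green = summarize_band(block, 500.0, 530.0, stat="auc")
red = summarize_band(block, 565.0, 595.0, stat="auc")
ratio = band_ratio(green, red)
r = np.corrcoef(ratio, truth["green"])[0, 1]
print(f"band-AUC green/red ratio vs true green course: correlation {r:.3f}")
# Without reference spectra, band summaries + a ratio recover the same
# activity modulation (the control channel is constant, so the ratio tracks it).
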