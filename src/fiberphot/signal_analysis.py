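"""Periodicity diagnostics: lag autocorrelation, power spectral density, spectrogram.

Photometry signals are slow (tens of Hz sampling), but oscillatory structure at
or below the Nyquist frequency — e.g. delta-band activity during slow-wave
sleep — is visible in the autocorrelation, the averaged-periodogram power
density spectrum, and a short-time spectrogram.  Missing samples are linearly
interpolated before any spectral estimate (the FFT requires a regular grid);
the number interpolated is reported through a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import Recording

__all__ = ["SpectrumResult", "autocorrelation", "power_spectrum", "spectrogram"]


@dataclass
class SpectrumResult:
    freqs_hz: np.ndarray
    power: np.ndarray  # vector (PSD) or matrix freq x time (spectrogram)
    times_s: np.ndarray | None = None


def _regular_channel(rec: Recording, channel: str) -> np.ndarray:
    x = rec.channel(channel)
    bad = ~np.isfinite(x)
    if bad.any():
        warnings.warn(
            f"channel {channel!r}: {int(bad.sum())} missing samples linearly "
            "interpolated before spectral analysis",
            stacklevel=3,
        )
        if bad.all():
            raise ValueError(f"channel {channel!r} is entirely missing")
        x = x.copy()
        x[bad] = np.interp(rec.time[bad], rec.time[~bad], x[~bad])
    return x


def autocorrelation(rec: Recording, channel: str, max_lag: int) -> np.ndarray:
    """Normalized sample autocorrelation at lags 0..max_lag.

    Mean-removed, biased normalization (divide by n), so r[0] == 1 and the
    sequence is the standard correlogram.  Lag k corresponds to a delay of
    k / rate_hz seconds.
    """
    x = _regular_channel(rec, channel)
    n = x.size
    if not 0 < max_lag < n:
        raise ValueError(f"max_lag must be in 1..{n - 1}, got {max_lag}")
    xc = x - x.mean()
    c0 = float(xc @ xc) / n
    if c0 == 0:
        raise ValueError(f"channel {channel!r} is constant; autocorrelation undefined")
    r = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        r[k] = (xc[: n - k] @ xc[k:]) / n / c0
    return r


def power_spectrum(
    rec: Recording,
    channel: str,
    segment_s: float = 8.0,
    overlap: float = 0.5,
) -> SpectrumResult:
    """Averaged-periodogram power spectral density (Hann window, 50% overlap default).

    The frequency axis runs from 0 to the Nyquist frequency rate_hz / 2; power
    is a one-sided density so that sum(power) * df approximates the signal
    variance.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be a fraction in [0, 1)")
    x = _regular_channel(rec, channel)
    nperseg = min(int(round(segment_s * rec.rate_hz)), x.size)
    if nperseg < 2:
        raise ValueError("segment too short for the sampling rate")
    freqs, power = sps.welch(
        x, fs=rec.rate_hz, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * overlap), detrend="constant",
    )
    return SpectrumResult(freqs, power)


def spectrogram(
    rec: Recording,
    channel: str,
    window_s: float = 8.0,
    step_s: float | None = None,
) -> SpectrumResult:
    """Short-time PSD matrix (frequency x time); column times at window centers."""
    x = _regular_channel(rec, channel)
    nperseg = int(round(window_s * rec.rate_hz))
    if nperseg < 2 or nperseg > x.size:
        raise ValueError(
            f"window of {window_s} s spans {nperseg} samples; recording has {x.size}"
        )
    step = step_s if step_s is not None else window_s / 2
    nstep = max(int(round(step * rec.rate_hz)), 1)
    freqs, times, power = sps.spectrogram(
        x, fs=rec.rate_hz, window="hann", nperseg=nperseg,
        noverlap=nperseg - nstep, detrend="constant", mode="psd",
    )
    return SpectrumResult(freqs, power, times + rec.time[0])
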