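"""Combining and conditioning recordings.

Covers the preprocessing a photometry session needs before events are cut out:
aligning an asynchronously sampled behavior stream onto the photometry clock,
appending back-to-back recordings, channel ratios, low-pass filtering with
downsampling, linear scaling of one channel's magnitude onto another's, and
photobleaching detrending with linear or exponential models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import curve_fit

from .io import Recording
from .spectral import band_ratio

__all__ = [
    "DetrendModel",
    "ScaleFit",
    "align_nearest",
    "append_rows",
    "ratio_channel",
    "lowpass_downsample",
    "linear_scale",
    "fit_detrend",
    "apply_detrend",
]


def _nearest_indices(base_t: np.ndarray, other_t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Index into other_t of the sample nearest each base_t; ties -> earlier sample.

    Returns (indices, clamped) where clamped marks base timestamps outside
    other's span (they take the nearest endpoint value).
    """
    pos = np.searchsorted(other_t, base_t)  # first index with other_t >= t
    pos = np.clip(pos, 0, other_t.size - 1)
    prev = np.clip(pos - 1, 0, other_t.size - 1)
    d_next = np.abs(other_t[pos] - base_t)
    d_prev = np.abs(base_t - other_t[prev])
    # strict '<' keeps the earlier sample on an exact midpoint tie
    idx = np.where(d_next < d_prev, pos, prev)
    clamped = (base_t < other_t[0]) | (base_t > other_t[-1])
    return idx, clamped


def align_nearest(
    base: Recording,
    other: Recording,
    channels: list[str] | None = None,
    rename: dict[str, str] | None = None,
) -> tuple[Recording, dict]:
    """Append channels of ``other`` onto ``base``'s time grid by nearest-neighbor sampling.

    For each base timestamp the appended value is the other recording's sample
    whose timestamp is closest (exact midpoints take the earlier sample).  Base
    samples outside the other recording's span take the nearest endpoint value;
    their count is returned in the coverage report.

    Returns (recording, coverage) where coverage holds per-channel counts of
    clamped (out-of-span) samples.
    """
    channels = list(channels) if channels is not None else list(other.channels)
    rename = dict(rename or {})
    out_names = {ch: rename.get(ch, ch) for ch in channels}
    collisions = [n for n in out_names.values() if n in base.channels]
    if collisions:
        raise ValueError(
            f"channel name collision with base recording: {sorted(collisions)}; "
            "pass rename={old: new} to resolve"
        )
    idx, clamped = _nearest_indices(base.time, other.time)
    n_clamped = int(clamped.sum())
    if n_clamped:
        warnings.warn(
            f"{n_clamped} of {base.n_samples} base samples fall outside "
            f"{other.name!r}'s span; nearest endpoint values used",
            stacklevel=2,
        )
    rec = base
    for ch in channels:
        rec = rec.with_channel(out_names[ch], other.channel(ch)[idx])
    coverage = {"clamped": {out_names[ch]: n_clamped for ch in channels},
                "n_base": base.n_samples}
    return rec, coverage


def append_rows(a: Recording, b: Recording, gap_s: float = 0.0) -> Recording:
    """Concatenate ``b`` after ``a`` row-wise, shifting b's clock to continue a's.

    b's first sample lands at ``a.end + gap_s + 1/rate`` (sampling continues one
    period after a's last sample).  Channel sets must match exactly; both
    recordings must share the nominal rate.
    """
    if gap_s < 0:
        raise ValueError("gap_s must be >= 0")
    if b.n_samples == 0:
        return Recording(a.name, a.time.copy(), {c: v.copy() for c, v in a.channels.items()},
                         a.rate_hz)
    if a.n_samples == 0:
        return Recording(a.name, b.time.copy(), {c: v.copy() for c, v in b.channels.items()},
                         b.rate_hz)
    if set(a.channels) != set(b.channels):
        diff = sorted(set(a.channels) ^ set(b.channels))
        raise ValueError(f"cannot append: channels differ by {diff}")
    if not np.isclose(a.rate_hz, b.rate_hz):
        raise ValueError(f"cannot append: rates differ ({a.rate_hz} vs {b.rate_hz} Hz)")
    offset = a.time[-1] + gap_s + 1.0 / a.rate_hz - b.time[0]
    time = np.concatenate([a.time, b.time + offset])
    channels = {c: np.concatenate([a.channels[c], b.channels[c]]) for c in a.channels}
    return Recording(f"{a.name}+{b.name}", time, channels, a.rate_hz)


def ratio_channel(rec: Recording, num: str, den: str, out: str) -> Recording:
    """Add the elementwise ratio num/den as a new channel (NaN where den ~ 0)."""
    return rec.with_channel(out, band_ratio(rec.channel(num), rec.channel(den)))


def _interp_nan(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Linear interpolation over missing samples (endpoints held)."""
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    if bad.all():
        raise ValueError("channel is entirely missing")
    out = x.copy()
    out[bad] = np.interp(t[bad], t[~bad], x[~bad])
    return out


def lowpass_downsample(
    rec: Recording, channel: str, cutoff_hz: float, factor: int = 1,
    channels: list[str] | None = None,
) -> Recording:
    """Zero-phase low-pass filter a channel, then keep every ``factor``-th sample.

    Uses a 4th-order Butterworth filter run forward and backward (no phase
    distortion).  The cutoff must be below the Nyquist frequency; the output
    recording's nominal rate is divided by ``factor``.  Channels not filtered
    are decimated as-is so the table stays rectangular.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    nyq = rec.rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff_hz must be in (0, {nyq}) for rate {rec.rate_hz} Hz")
    targets = [channel] if channels is None else list(dict.fromkeys([channel, *channels]))
    sos = sps.butter(4, cutoff_hz, btype="low", fs=rec.rate_hz, output="sos")
    new_channels = {}
    for ch, vec in rec.channels.items():
        if ch in targets:
            filled = _interp_nan(rec.time, vec)
            filt = sps.sosfiltfilt(sos, filled)
            new_channels[ch] = filt[::factor]
        else:
            new_channels[ch] = vec[::factor].copy()
    return Recording(rec.name, rec.time[::factor].copy(), new_channels, rec.rate_hz / factor)


@dataclass
class ScaleFit:
    """Least-squares fit of target on source: target ~ slope * source + intercept."""

    slope: float
    intercept: float


def linear_scale(rec: Recording, source: str, target: str, out: str) -> tuple[Recording, ScaleFit]:
    """Scale ``source`` to the magnitude of ``target`` via least squares.

    Writes ``out = slope * source + intercept`` where (slope, intercept) is the
    simple-regression fit of target on source over samples where both are
    finite.  This is the magnitude-matching step needed before, e.g., computing
    a control-corrected signal or the robust z-score pipeline.
    """
    x = rec.channel(source)
    y = rec.channel(target)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        raise ValueError("need at least two samples where both channels are finite")
    xv, yv = x[ok], y[ok]
    var = np.var(xv)
    if var == 0:
        raise ValueError(f"source channel {source!r} has zero variance; cannot scale")
    slope = float(np.cov(xv, yv, bias=True)[0, 1] / var)
    intercept = float(yv.mean() - slope * xv.mean())
    fitted = rec.with_channel(out, slope * x + intercept)
    return fitted, ScaleFit(slope, intercept)


@dataclass
class DetrendModel:
    """A fitted (or manually specified) photobleaching trend.

    ``linear``:       y(t) = a + b * t            params: a (intercept), b (slope)
    ``exponential``:  y(t) = a * exp(-b * t) + c  params: a (amplitude),
                      b (decay rate, 1/s, >= 0), c (offset / autofluorescence floor)
    """

    kind: str
    params: dict[str, float]
    fitted: bool = True
    fit_window: tuple[float, float] | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in {"linear", "exponential"}:
            raise ValueError(f"kind must be linear or exponential, got {self.kind!r}")
        needed = {"linear": {"a", "b"}, "exponential": {"a", "b", "c"}}[self.kind]
        if set(self.params) != needed:
            raise ValueError(f"{self.kind} model needs params {sorted(needed)}")
        if self.kind == "exponential" and self.params["b"] < 0:
            raise ValueError("exponential decay rate b must be >= 0 (a decreasing trend)")

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.kind == "linear":
            return p["a"] + p["b"] * t
        return p["a"] * np.exp(-p["b"] * t) + p["c"]


def _exp_initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # deterministic start: amplitude from endpoints, floor from the tail,
    # rate from a log-linear fit of (y - floor) where positive
    c0 = float(y[-1])
    a0 = float(y[0] - c0)
    if a0 == 0:
        a0 = max(float(np.ptp(y)), 1e-12)
    resid = (y - c0) / a0
    ok = resid > 1e-6
    if ok.sum() >= 2:
        slope = np.polyfit(t[ok], np.log(resid[ok]), 1)[0]
        b0 = max(-float(slope), 1e-9)
    else:
        b0 = 1.0 / max(t[-1] - t[0], 1e-9)
    return a0, b0, c0


def fit_detrend(
    rec: Recording,
    channel: str,
    kind: str = "exponential",
    params: dict[str, float] | None = None,
    fit_window: tuple[float, float] | None = None,
) -> DetrendModel:
    """Fit a decreasing trend model to a channel, or wrap manually supplied parameters.

    Photobleaching/photoswitching progressively lowers fluorescence intensity;
    the trend is modeled either as a line ``a + b*t`` or as an exponential
    decay toward an offset ``a*exp(-b*t) + c`` and fit by least squares.  When
    ``params`` is given no fitting happens and the model echoes them with
    ``fitted=False``.
    """
    if params is not None:
        return DetrendModel(kind, dict(params), fitted=False, fit_window=fit_window)
    t_all = rec.time
    y_all = rec.channel(channel)
    mask = np.isfinite(y_all)
    if fit_window is not None:
        lo, hi = fit_window
        mask &= (t_all >= lo) & (t_all <= hi)
    t, y = t_all[mask], y_all[mask]
    min_n = 3 if kind == "linear" else 4
    if t.size < min_n:
        raise ValueError(f"{kind} fit needs >= {min_n} finite samples, got {t.size}")

    if kind == "linear":
        b, a = np.polyfit(t, y, 1)
        return DetrendModel("linear", {"a": float(a), "b": float(b)},
                            fit_window=fit_window)
    if kind != "exponential":
        raise ValueError(f"kind must be linear or exponential, got {kind!r}")

    p0 = _exp_initial_guess(t, y)
    try:
        popt, _ = curve_fit(
            lambda tt, a, b, c: a * np.exp(-b * tt) + c,
            t, y, p0=p0, bounds=([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"exponential detrend fit did not converge on channel {channel!r} "
            f"(initial guess a={p0[0]:.4g}, b={p0[1]:.4g}, c={p0[2]:.4g}); "
            "consider kind='linear' or supplying manual params"
        ) from exc
    a, b, c = (float(v) for v in popt)
    resid = y - (a * np.exp(-b * t) + c)
    return DetrendModel(
        "exponential", {"a": a, "b": b, "c": c}, fit_window=fit_window,
        diagnostics={"rss": float(resid @ resid), "n": int(t.size)},
    )


def apply_detrend(
    rec: Recording,
    channel: str,
    model: DetrendModel,
    out: str | None = None,
    keep_prediction: bool = False,
) -> Recording:
    """Subtract the trend model's prediction from a channel.

    The residual (raw minus prediction) replaces or accompanies the raw
    channel; ``raw == residual + prediction`` holds exactly at every sample.
    With ``keep_prediction`` the prediction is emitted alongside as
    ``<out>_prediction``.
    """
    out = out or f"{channel}_detrended"
    pred = model.predict(rec.time)
    resid = rec.channel(channel) - pred
    rec2 = rec.with_channel(out, resid, replace=out in rec.channels)
    if keep_prediction:
        rec2 = rec2.with_channel(f"{out}_prediction", pred,
                                 replace=f"{out}_prediction" in rec2.channels)
    return rec2
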