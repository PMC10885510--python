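"""Per-event baseline normalization: z-score, ΔF/F (and %ΔF/F), robust z-score.

Each event carries its own baseline interval r (typically a window just before
the event); baselines are never pooled across events.  With r̄ the baseline
mean, σ_r its sample standard deviation:

    z_i(x)      = (x_i − r̄) / σ_r
    ΔF/F_i(x)   = (x_i − r̄) / r̄            (%ΔF/F = 100 × ΔF/F)
    RZ_i(x)     = (%ΔF/F_i(x) − median(%ΔF/F(r))) / MAD(%ΔF/F(r))

where MAD(v) = median(|v − median(v)|), unscaled (no consistency constant).
The z-score suits approximately normal baselines; ΔF/F is the conventional
fractional fluorescence change but is sensitive to baseline outliers; the
robust z-score trades interpretability (its reference is median-centered) for
bounded influence of outlying baseline samples.

Baseline σ uses the sample (n−1) denominator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .events import Event, IntervalSpec, resolve_intervals
from .io import Recording

logger = logging.getLogger(__name__)

__all__ = ["NormalizedEvent", "zscore", "dff", "robust_z", "normalize_events", "METHODS"]

METHODS = ("zscore", "dff", "pct_dff", "robust_z")


def _baseline(r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    r = r[np.isfinite(r)]
    if r.size < 2:
        raise ValueError(f"baseline needs at least 2 finite samples, got {r.size}")
    return r


def zscore(x, r) -> np.ndarray:
    """Z-score of x against baseline r: (x − mean(r)) / sd(r)."""
    x = np.asarray(x, dtype=float)
    r = _baseline(r)
    sd = r.std(ddof=1)
    if sd == 0:
        raise ValueError("baseline standard deviation is zero; z-score undefined")
    return (x - r.mean()) / sd


def dff(x, r, percent: bool = False) -> np.ndarray:
    """ΔF/F of x against baseline r: (x − mean(r)) / mean(r); ×100 when ``percent``."""
    x = np.asarray(x, dtype=float)
    r = _baseline(r)
    rbar = r.mean()
    if rbar == 0:
        raise ValueError("baseline mean is zero; ΔF/F undefined")
    if rbar < 0:
        warnings.warn(
            "baseline mean is negative; ΔF/F signs are flipped relative to the "
            "raw deflection direction",
            stacklevel=2,
        )
    out = (x - rbar) / rbar
    return 100.0 * out if percent else out


def mad(v) -> float:
    """Median absolute deviation, median(|v − median(v)|), unscaled."""
    v = np.asarray(v, dtype=float)
    return float(np.median(np.abs(v - np.median(v))))


def robust_z(x, r) -> np.ndarray:
    """Robust z-score: %ΔF/F re-centered by the baseline's median and scaled by its MAD."""
    x = np.asarray(x, dtype=float)
    rb = _baseline(r)
    pct_x = dff(x, rb, percent=True)
    pct_r = dff(rb, rb, percent=True)
    scale = mad(pct_r)
    if scale == 0:
        raise ValueError(
            "baseline %ΔF/F has zero median absolute deviation; robust z-score "
            "undefined — consider the plain z-score"
        )
    return (pct_x - np.median(pct_r)) / scale


_METHOD_FNS = {
    "zscore": lambda x, r: zscore(x, r),
    "dff": lambda x, r: dff(x, r),
    "pct_dff": lambda x, r: dff(x, r, percent=True),
    "robust_z": lambda x, r: robust_z(x, r),
}


@dataclass
class NormalizedEvent:
    """One event's interval traces, raw and normalized against its own baseline.

    ``intervals`` maps interval name to a dict with keys ``time`` (seconds
    relative to the event-signal start), ``raw`` and ``normalized`` —
    vectors aligned 1:1.
    """

    event: Event
    intervals: dict[str, dict] = field(default_factory=dict)
    baseline_name: str = "baseline"
    method: str = "dff"
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)


def _slice(rec: Recording, window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    lo = np.searchsorted(rec.time, window[0], side="left")
    hi = np.searchsorted(rec.time, window[1], side="left")
    return rec.time[lo:hi], slice(lo, hi)


def normalize_events(
    events: list[Event],
    interval_specs: list[IntervalSpec],
    rec: Recording,
    channel: str,
    method: str = "dff",
    baseline_name: str = "baseline",
) -> list[NormalizedEvent]:
    """Resolve intervals and normalize every interval against the event's baseline.

    For each event the named baseline interval supplies the reference vector r;
    every interval's samples (including the baseline's own) are then normalized
    with the chosen method.  Events whose baseline interval is missing or has
    fewer than 2 finite samples are dropped with a warning.  Times in the
    output are relative to the event-signal start.
    """
    if method not in _METHOD_FNS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    fn = _METHOD_FNS[method]
    x = rec.channel(channel)
    out: list[NormalizedEvent] = []
    prev_bound: float | None = None
    for ev in events:
        windows = resolve_intervals(ev, interval_specs, prev_event_end=prev_bound)
        bound = ev.end_s
        if windows:
            bound = max(bound, max(w[1] for w in windows.values()))
        prev_bound = bound if prev_bound is None else max(prev_bound, bound)
        if baseline_name not in windows:
            logger.warning(
                "event %d [%g, %g): baseline interval %r unresolved; event dropped",
                ev.index, ev.start_s, ev.end_s, baseline_name,
            )
            continue
        t_base, sl_base = _slice(rec, windows[baseline_name])
        r = x[sl_base]
        r = r[np.isfinite(r)]
        if r.size < 2:
            logger.warning(
                "event %d [%g, %g): baseline has %d finite samples (< 2); event dropped",
                ev.index, ev.start_s, ev.end_s, r.size,
            )
            continue
        intervals = {}
        for name, window in windows.items():
            t_w, sl_w = _slice(rec, window)
            raw = x[sl_w]
            intervals[name] = {
                "time": t_w - ev.start_s,
                "raw": raw.copy(),
                "normalized": fn(raw, r),
            }
        out.append(NormalizedEvent(ev, intervals, baseline_name, method, windows))
    return out
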