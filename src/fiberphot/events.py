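"""Event detection, conditioning, the filter catalogue, and interval windows.

An event is a continuous period ``[start_s, end_s)`` of interest — a TTL tone,
a behavioral bout, a fixed time bin, or a detected transient.  Event series
are built in four ways (binary indicator edges, fixed bins, moving-window peak
exceedance, manual timestamps), optionally gated by a per-timestep condition,
refined by an ordered list of filters, and finally given named interval
windows (e.g. a pre-event baseline and a post-event response) anchored to
event reference points.

All event times are real seconds on the half-open convention ``[start, end)``:
a sample at exactly ``end`` belongs to the next period, so adjacent bins never
double-count a shared boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._predicate import PredicateError, compile_predicate
from .io import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "Event",
    "PredicateError",
    "FilterStep",
    "IntervalSpec",
    "EventSeriesDef",
    "detect_binary",
    "detect_binned",
    "detect_peaks",
    "detect_timestamps",
    "apply_condition",
    "apply_filters",
    "resolve_intervals",
    "build_event_series",
    "events_to_table",
    "FILTER_KINDS",
]

_TOL = 1e-9


@dataclass
class Event:
    """A half-open period [start_s, end_s) with its ordinal in the series."""

    start_s: float
    end_s: float
    index: int = 0

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(f"event start {self.start_s} must precede end {self.end_s}")

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


def _reindex(events: list[Event]) -> list[Event]:
    return [replace(ev, index=i) for i, ev in enumerate(events)]


def _runs_to_events(active: np.ndarray, time: np.ndarray) -> list[Event]:
    """Maximal runs of True -> events.  A run opens at its first sample's
    timestamp and closes at the timestamp where the signal drops; a run still
    active at the recording end closes at the last timestamp (so a run that is
    only the final sample is degenerate and dropped)."""
    n = active.size
    padded = np.concatenate([[False], active, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])  # first index after the run
    events = []
    for i0, i1 in zip(starts, ends):
        t_start = time[i0]
        t_end = time[i1] if i1 < n else time[n - 1]
        if t_end > t_start:
            events.append(Event(float(t_start), float(t_end)))
    return _reindex(events)


def detect_binary(rec: Recording, channel: str, inverted: bool = False) -> list[Event]:
    """One event per maximal run of 1s (rising edge through the next falling edge).

    With ``inverted`` the logical complement is used (runs of 0s).  Values must
    be 0, 1 or missing; missing samples belong to neither state and break runs.
    """
    x = rec.channel(channel)
    finite = np.isfinite(x)
    offenders = np.setdiff1d(np.unique(x[finite]), [0.0, 1.0])
    if offenders.size:
        raise ValueError(
            f"channel {channel!r} is not binary; offending values: {offenders[:10].tolist()}"
        )
    target = 0.0 if inverted else 1.0
    active = finite & (x == target)
    return _runs_to_events(active, rec.time)


def detect_binned(rec: Recording, t0: float, L: float) -> list[Event]:
    """Fixed bins of length L starting at t0, kept while fully inside the span.

    Events are ``[t0 + iL, t0 + (i+1)L)``; a trailing partial bin is dropped.
    """
    if not L > 0:
        raise ValueError("bin length L must be positive")
    t_first, t_last = rec.span
    events = []
    i = 0
    while True:
        start = t0 + i * L
        end = t0 + (i + 1) * L
        if end > t_last + _TOL:
            break
        if start >= t_first - _TOL:
            events.append(Event(float(start), float(end)))
        i += 1
    return _reindex(events)


def detect_peaks(rec: Recording, channel: str, L: float, k: float) -> list[Event]:
    """Moving-window exceedance detection.

    Sample i is flagged when ``x_i > mean_w(i) + k * sd_w(i)`` with mean and
    sample standard deviation taken over the window of samples within L/2
    seconds of t_i (centered, truncated at the recording edges).  Events are
    maximal runs of flagged samples.  The window must span at least 3 samples
    at the nominal rate.
    """
    if L * rec.rate_hz < 3:
        raise ValueError(
            f"window of {L} s spans fewer than 3 samples at {rec.rate_hz} Hz"
        )
    x = rec.channel(channel)
    t = rec.time
    lo = np.searchsorted(t, t - L / 2, side="left")
    hi = np.searchsorted(t, t + L / 2, side="right")
    finite = np.isfinite(x)
    xf = np.where(finite, x, 0.0)
    cs = np.concatenate([[0.0], np.cumsum(xf)])
    cs2 = np.concatenate([[0.0], np.cumsum(xf * xf)])
    cn = np.concatenate([[0], np.cumsum(finite.astype(int))])
    m = cn[hi] - cn[lo]
    s1 = cs[hi] - cs[lo]
    s2 = cs2[hi] - cs2[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / m
        var = np.maximum(s2 - s1 * s1 / m, 0.0) / np.maximum(m - 1, 1)
        sd = np.sqrt(var)
        flagged = finite & (m >= 2) & (x > mean + k * sd)
    return _runs_to_events(flagged, t)


def detect_timestamps(pairs) -> list[Event]:
    """Validate and sort a manual list of (start_s, end_s) timestamps."""
    events = []
    for row, (start, end) in enumerate(pairs, start=1):
        if not start < end:
            raise ValueError(f"timestamp row {row}: start {start} must precede end {end}")
        events.append(Event(float(start), float(end)))
    events.sort(key=lambda ev: (ev.start_s, ev.end_s))
    return _reindex(events)


# ---------------------------------------------------------------------------
# conditions


def apply_condition(
    events: list[Event],
    rec: Recording,
    predicate: str,
    mode: str = "all",
) -> list[Event]:
    """Keep events whose condition holds over their samples.

    ``mode='all'`` requires the predicate to hold at every in-event sample;
    ``mode='any'`` at one or more.  Samples where a referenced channel is
    missing count as failing.  Events containing no samples are dropped.
    """
    if mode not in {"all", "any"}:
        raise ValueError(f"mode must be 'all' or 'any', got {mode!r}")
    fn, used = compile_predicate(predicate, rec.channels.keys())
    env = {name: rec.channels[name] for name in used if name != "time"}
    env["time"] = rec.time
    mask = np.asarray(fn(env))
    if mask.ndim == 0:  # constant predicate (e.g. a tautology)
        mask = np.broadcast_to(mask, rec.time.shape)
    kept = []
    for ev in events:
        lo = np.searchsorted(rec.time, ev.start_s, side="left")
        hi = np.searchsorted(rec.time, ev.end_s, side="left")
        if hi <= lo:
            logger.info("condition: event [%g, %g) contains no samples; dropped",
                        ev.start_s, ev.end_s)
            continue
        ok = mask[lo:hi]
        if (mode == "all" and ok.all()) or (mode == "any" and ok.any()):
            kept.append(ev)
    return _reindex(kept)


# ---------------------------------------------------------------------------
# filter catalogue


FILTER_KINDS = frozenset({
    "keep_first", "drop_first", "keep_last", "drop_last",
    "shift", "pad_min_length", "truncate_max",
    "drop_shorter", "drop_longer",
    "aggregate_within", "coalesce", "min_rate",
    "before", "after", "drop_successive_within",
})

_POSITIVE_PARAMS = {
    "pad_min_length": "min_s", "truncate_max": "max_s",
    "drop_shorter": "min_s", "drop_longer": "max_s",
    "aggregate_within": "gap_s", "min_rate": "rate_per_s",
    "drop_successive_within": "gap_s",
}


@dataclass
class FilterStep:
    """One step of the event filter catalogue; steps apply successively in order.

    Kinds and their parameters:

    - ``keep_first`` / ``drop_first`` / ``keep_last`` / ``drop_last`` (``n=1``)
    - ``shift`` (``dt_s``): move both endpoints by a constant, preserving length
    - ``pad_min_length`` (``min_s``): extend the *end* of shorter events
    - ``truncate_max`` (``max_s``): cut the end of longer events
    - ``drop_shorter`` (``min_s``) / ``drop_longer`` (``max_s``): inclusive
      keep semantics (length >= min_s kept / length <= max_s kept)
    - ``aggregate_within`` (``gap_s``): merge an event into its predecessor
      when the gap (next start minus previous end) is <= gap_s
    - ``coalesce``: merge strictly overlapping events (idempotent)
    - ``min_rate`` (``rate_per_s``): keep the whole series only when
      count / recording span >= rate, else drop every event
    - ``before`` / ``after`` (``t_s``, ``action='include'|'exclude'``): select
      events by start time (< t for before, >= t for after) and keep or drop
      the selection
    - ``drop_successive_within`` (``gap_s``): drop an event starting within
      gap_s of the previously retained event's end
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FILTER_KINDS:
            raise ValueError(f"unknown filter kind {self.kind!r}; known: {sorted(FILTER_KINDS)}")
        key = _POSITIVE_PARAMS.get(self.kind)
        if key is not None and not self.params.get(key, 0) > 0:
            raise ValueError(f"filter {self.kind!r} needs positive parameter {key!r}")


def _merge(events: list[Event], should_merge) -> list[Event]:
    out: list[Event] = []
    for ev in events:
        if out and should_merge(out[-1], ev):
            out[-1] = Event(out[-1].start_s, max(out[-1].end_s, ev.end_s))
        else:
            out.append(Event(ev.start_s, ev.end_s))
    return out


def _apply_one(events: list[Event], step: FilterStep, span: tuple[float, float]) -> list[Event]:
    kind, p = step.kind, step.params
    n = p.get("n", 1)
    if kind == "keep_first":
        return events[:n]
    if kind == "drop_first":
        return events[n:]
    if kind == "keep_last":
        return events[-n:] if n else []
    if kind == "drop_last":
        return events[:-n] if n else events
    if kind == "shift":
        dt = p["dt_s"]
        return [Event(ev.start_s + dt, ev.end_s + dt) for ev in events]
    if kind == "pad_min_length":
        m = p["min_s"]
        return [Event(ev.start_s, max(ev.end_s, ev.start_s + m)) for ev in events]
    if kind == "truncate_max":
        m = p["max_s"]
        return [Event(ev.start_s, min(ev.end_s, ev.start_s + m)) for ev in events]
    if kind == "drop_shorter":
        return [ev for ev in events if ev.length_s >= p["min_s"]]
    if kind == "drop_longer":
        return [ev for ev in events if ev.length_s <= p["max_s"]]
    if kind == "aggregate_within":
        gap = p["gap_s"]
        return _merge(events, lambda prev, ev: ev.start_s - prev.end_s <= gap)
    if kind == "coalesce":
        return _merge(events, lambda prev, ev: ev.start_s < prev.end_s)
    if kind == "min_rate":
        span_s = span[1] - span[0]
        if span_s <= 0:
            return []
        return events if len(events) / span_s >= p["rate_per_s"] else []
    if kind in {"before", "after"}:
        t = p["t_s"]
        action = p.get("action", "include")
        if action not in {"include", "exclude"}:
            raise ValueError("before/after action must be 'include' or 'exclude'")
        selected = [(ev.start_s < t) if kind == "before" else (ev.start_s >= t)
                    for ev in events]
        keep = selected if action == "include" else [not s for s in selected]
        return [ev for ev, k in zip(events, keep) if k]
    if kind == "drop_successive_within":
        gap = p["gap_s"]
        out: list[Event] = []
        for ev in events:
            if out and ev.start_s - out[-1].end_s <= gap:
                continue
            out.append(ev)
        return out
    raise AssertionError(f"unhandled filter kind {kind!r}")


def apply_filters(
    events: list[Event],
    steps: list[FilterStep],
    rec_span: tuple[float, float],
) -> list[Event]:
    """Apply filter steps in order; the empty step list is the identity.

    Each step's before/after event counts are logged.  Events are re-indexed
    chronologically at the end.
    """
    current = list(events)
    for step in steps:
        if not isinstance(step, FilterStep):
            step = FilterStep(step[0], dict(step[1]) if len(step) > 1 else {})
        before = len(current)
        current = _apply_one(current, step, rec_span)
        logger.info("filter %s%s: %d -> %d events", step.kind, step.params, before, len(current))
    return _reindex(current)


# ---------------------------------------------------------------------------
# intervals


@dataclass
class IntervalSpec:
    """A named window anchored to an event reference point with signed offsets.

    ``reference`` is one of ``event_start``, ``event_end``, ``event_signal``
    (the raw event span itself, offsets ignored) or ``event_start_nonoverlap``
    (like ``event_start`` but the window start is clipped so it cannot overlap
    the preceding event or its intervals).
    """

    name: str
    reference: str = "event_start"
    start_off_s: float = 0.0
    end_off_s: float = 0.0

    _REFERENCES = ("event_start", "event_end", "event_signal", "event_start_nonoverlap")

    def __post_init__(self) -> None:
        if self.reference not in self._REFERENCES:
            raise ValueError(
                f"unknown reference {self.reference!r}; choose from {self._REFERENCES}"
            )


def resolve_intervals(
    event: Event,
    specs: list[IntervalSpec],
    prev_event_end: float | None = None,
) -> dict[str, tuple[float, float]]:
    """Resolve each interval spec to a concrete (start_s, end_s) window.

    Windows that collapse (start >= end after nonoverlap clipping) are dropped
    with a warning.  Interval names must be unique within the spec list.
    """
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"interval names must be unique, got {names}")
    windows: dict[str, tuple[float, float]] = {}
    for spec in specs:
        if spec.reference == "event_signal":
            start, end = event.start_s, event.end_s
        else:
            anchor = event.end_s if spec.reference == "event_end" else event.start_s
            start = anchor + spec.start_off_s
            end = anchor + spec.end_off_s
            if spec.reference == "event_start_nonoverlap" and prev_event_end is not None:
                start = max(start, prev_event_end)
        if not start < end:
            logger.warning(
                "interval %r of event [%g, %g) collapsed to [%g, %g); dropped",
                spec.name, event.start_s, event.end_s, start, end,
            )
            continue
        windows[spec.name] = (float(start), float(end))
    return windows


# ---------------------------------------------------------------------------
# declarative series definition


@dataclass
class EventSeriesDef:
    """Declarative definition of one event series: source, condition, filters, intervals."""

    name: str
    source: dict
    condition: str | None = None
    condition_mode: str = "all"
    filters: list[FilterStep] = field(default_factory=list)
    intervals: list[IntervalSpec] = field(default_factory=list)


def build_event_series(rec: Recording, definition: EventSeriesDef) -> list[Event]:
    """Run detection, conditioning and filtering for one series definition."""
    src = dict(definition.source)
    kind = src.pop("kind")
    if kind == "binary":
        events = detect_binary(rec, src["channel"], src.get("inverted", False))
    elif kind == "binned":
        events = detect_binned(rec, src.get("t0", rec.span[0]), src["L"])
    elif kind == "peak":
        events = detect_peaks(rec, src["channel"], src["L"], src["k"])
    elif kind == "timestamps":
        events = detect_timestamps(src["pairs"])
    else:
        raise ValueError(f"unknown event source kind {kind!r}")
    if definition.condition:
        events = apply_condition(events, rec, definition.condition, definition.condition_mode)
    return apply_filters(events, definition.filters, rec.span)


def events_to_table(series: dict[str, list[Event]]) -> pd.DataFrame:
    """Flatten named event series into a (series, start_s, end_s) table."""
    rows = [
        {"series": name, "start_s": ev.start_s, "end_s": ev.end_s}
        for name, evs in series.items()
        for ev in evs
    ]
    return pd.DataFrame(rows, columns=["series", "start_s", "end_s"])
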