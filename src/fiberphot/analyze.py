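"""Event-triggered analytics: average traces, sortable heatmaps, interval summaries.

Events are aligned so that their event signals all start at time zero; baseline
intervals therefore occupy negative grid times.  Events of different lengths
(behavioral bouts) contribute to a grid point only where they have a sample
nearby, so summary statistics run over the available events per grid point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalize import NormalizedEvent

__all__ = [
    "EtaResult",
    "HeatmapMatrix",
    "event_triggered_average",
    "heatmap_matrix",
    "interval_summaries",
    "plot_eta",
    "plot_heatmap",
    "plot_interval_summaries",
]


@dataclass
class EtaResult:
    """Event-triggered average on a common grid relative to event-signal start."""

    time_grid: np.ndarray
    mean: np.ndarray
    dispersion: np.ndarray  # multiplier x (SD or SE), >= 0
    n_at_t: np.ndarray
    dispersion_kind: str = "sd"
    multiplier: float = 1.0

    @property
    def lower(self) -> np.ndarray:
        return self.mean - self.dispersion

    @property
    def upper(self) -> np.ndarray:
        return self.mean + self.dispersion

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time_grid, "mean": self.mean,
            "lower": self.lower, "upper": self.upper, "n": self.n_at_t,
        })


@dataclass
class HeatmapMatrix:
    """Per-event normalized responses on a shared grid, rows ordered by sort_key."""

    time_grid: np.ndarray
    values: np.ndarray  # (n_events, n_grid), NaN where an event has no sample
    event_indices: list[int]  # original chronological indices, in row order
    sort_key: str = "order"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.event_indices, name="event"),
            columns=pd.Index(np.round(self.time_grid, 9), name="time_s"),
        )


def _event_samples(ne: NormalizedEvent) -> tuple[np.ndarray, np.ndarray]:
    """All (relative time, normalized value) samples of one event, deduplicated."""
    ts, vs = [], []
    for data in ne.intervals.values():
        ts.append(data["time"])
        vs.append(data["normalized"])
    t = np.concatenate(ts)
    v = np.concatenate(vs)
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    keep = np.concatenate([[True], np.diff(t) > 0])  # overlapping intervals share samples
    return t[keep], v[keep]


def _resample_to_grid(t: np.ndarray, v: np.ndarray, grid: np.ndarray, step: float) -> np.ndarray:
    """Nearest sample within step/2 of each grid point, else NaN."""
    out = np.full(grid.size, np.nan)
    if t.size == 0:
        return out
    pos = np.clip(np.searchsorted(t, grid), 0, t.size - 1)
    prev = np.clip(pos - 1, 0, t.size - 1)
    idx = np.where(np.abs(t[pos] - grid) < np.abs(grid - t[prev]), pos, prev)
    dist = np.abs(t[idx] - grid)
    ok = dist <= step / 2 + 1e-12
    out[ok] = v[idx[ok]]
    return out


def _grid_matrix(normed: list[NormalizedEvent], step: float) -> tuple[np.ndarray, np.ndarray]:
    samples = [_event_samples(ne) for ne in normed]
    t_min = min(t[0] for t, _ in samples if t.size)
    t_max = max(t[-1] for t, _ in samples if t.size)
    n_pts = int(np.floor((t_max - t_min) / step + 1e-9)) + 1
    grid = t_min + step * np.arange(n_pts)
    mat = np.vstack([_resample_to_grid(t, v, grid, step) for t, v in samples])
    return grid, mat


def event_triggered_average(
    normed: list[NormalizedEvent],
    grid_step_s: float,
    dispersion: str = "sd",
    multiplier: float = 1.0,
) -> EtaResult:
    """Average the normalized event traces on a common grid.

    Each event is resampled onto the grid (nearest sample within half a step,
    else missing); mean and dispersion are computed per grid point over the
    events that cover it.  ``dispersion`` is ``sd`` (sample SD, 0 where a
    single event covers) or ``se`` (SD / sqrt(n)); the band half-width is
    ``multiplier`` times that.
    """
    if not normed:
        raise ValueError("need at least one normalized event")
    if dispersion not in {"sd", "se"}:
        raise ValueError(f"dispersion must be 'sd' or 'se', got {dispersion!r}")
    if not grid_step_s > 0:
        raise ValueError("grid_step_s must be positive")
    grid, mat = _grid_matrix(normed, grid_step_s)
    finite = np.isfinite(mat)
    n_at_t = finite.sum(axis=0)
    sums = np.where(finite, mat, 0.0).sum(axis=0)
    mean = np.where(n_at_t > 0, sums / np.maximum(n_at_t, 1), np.nan)
    sd = np.array([
        float(np.std(col[np.isfinite(col)], ddof=1)) if np.isfinite(col).sum() > 1 else 0.0
        for col in mat.T
    ])
    disp = sd if dispersion == "sd" else np.divide(
        sd, np.sqrt(np.maximum(n_at_t, 1)), out=np.zeros_like(sd), where=n_at_t > 0
    )
    return EtaResult(grid, mean, multiplier * disp, n_at_t, dispersion, multiplier)


def _event_auc(ne: NormalizedEvent, t1: float | None, t2: float | None) -> float:
    t, v = _event_samples(ne)
    lo = t1 if t1 is not None else 0.0
    hi = t2 if t2 is not None else ne.event.length_s
    mask = (t >= lo - 1e-12) & (t <= hi + 1e-12) & np.isfinite(v)
    if mask.sum() < 2:
        return np.nan
    return float(np.trapezoid(v[mask], x=t[mask]))


def heatmap_matrix(
    normed: list[NormalizedEvent],
    grid_step_s: float,
    sort: str = "order",
    auc_window: tuple[float | None, float | None] = (None, None),
) -> HeatmapMatrix:
    """Build the per-event response matrix, rows sorted by the requested key.

    ``sort='order'`` keeps chronological order; ``'length'`` sorts by total
    event length descending; ``'auc'`` sorts by the trapezoidal area of the
    normalized trace between ``auc_window`` (relative times; defaults to the
    full event span) descending.  Ties break chronologically.
    """
    if not normed:
        raise ValueError("need at least one normalized event")
    if sort not in {"order", "length", "auc"}:
        raise ValueError(f"sort must be order, length or auc, got {sort!r}")
    grid, mat = _grid_matrix(normed, grid_step_s)
    if sort == "order":
        order = np.arange(len(normed))
    elif sort == "length":
        key = np.array([ne.event.length_s for ne in normed])
        order = np.argsort(-key, kind="stable")  # stable: ties stay chronological
    else:
        key = np.array([_event_auc(ne, *auc_window) for ne in normed])
        key = np.where(np.isfinite(key), key, -np.inf)
        order = np.argsort(-key, kind="stable")
    return HeatmapMatrix(grid, mat[order], [normed[i].event.index for i in order], sort)


def interval_summaries(
    normed: list[NormalizedEvent],
    stats: list = ("mean", "median"),
    series: str = "events",
) -> pd.DataFrame:
    """Per-(event, interval, statistic) summary of the normalized samples.

    ``stats`` entries are ``"mean"``, ``"median"`` or ``("auc", t1, t2)``
    (trapezoidal area between two event-relative times, endpoints inclusive;
    pass None bounds for the interval's full extent).
    """
    rows = []
    for ne in normed:
        for name, data in ne.intervals.items():
            t, v = data["time"], data["normalized"]
            ok = np.isfinite(v)
            for stat in stats:
                if stat == "mean":
                    label, value = "mean", (float(np.mean(v[ok])) if ok.any() else np.nan)
                elif stat == "median":
                    label, value = "median", (float(np.median(v[ok])) if ok.any() else np.nan)
                elif isinstance(stat, (tuple, list)) and stat[0] == "auc":
                    t1 = stat[1] if stat[1] is not None else t[0] if t.size else 0.0
                    t2 = stat[2] if stat[2] is not None else t[-1] if t.size else 0.0
                    mask = ok & (t >= t1 - 1e-12) & (t <= t2 + 1e-12)
                    label = f"auc[{t1:g},{t2:g}]"
                    value = float(np.trapezoid(v[mask], x=t[mask])) if mask.sum() >= 2 else np.nan
                else:
                    raise ValueError(f"unknown statistic {stat!r}")
                rows.append({
                    "series": series, "event": ne.event.index, "interval": name,
                    "stat": label, "value": value,
                })
    return pd.DataFrame(rows, columns=["series", "event", "interval", "stat", "value"])


# ---------------------------------------------------------------------------
# plotting (optional outputs mirroring the trace / heatmap / boxplot views)


def plot_eta(eta: EtaResult, ax=None, label: str | None = None):
    """Averaged trace with a shaded mean ± dispersion band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(eta.time_grid, eta.mean, label=label)
    ax.fill_between(eta.time_grid, eta.lower, eta.upper, alpha=0.3)
    ax.axvline(0.0, color="k", lw=0.5, ls="--")
    ax.set_xlabel("time from event start (s)")
    ax.set_ylabel("normalized response")
    if label:
        ax.legend()
    return ax


def plot_heatmap(hm: HeatmapMatrix, ax=None):
    """Event x time heatmap, one row per event in sorted order."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = [hm.time_grid[0], hm.time_grid[-1], hm.values.shape[0], 0]
    im = ax.imshow(hm.values, aspect="auto", interpolation="nearest", extent=extent)
    ax.figure.colorbar(im, ax=ax, label="normalized response")
    ax.set_xlabel("time from event start (s)")
    ax.set_ylabel(f"event (sorted by {hm.sort_key})")
    return ax


def plot_interval_summaries(table: pd.DataFrame, stat: str = "mean", ax=None):
    """Box-and-whisker of one summary statistic per interval."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = table[table["stat"] == stat]
    groups = [g["value"].dropna().to_numpy() for _, g in sub.groupby("interval", sort=False)]
    labels = [name for name, _ in sub.groupby("interval", sort=False)]
    ax.boxplot(groups, tick_labels=labels)
    ax.set_ylabel(f"interval {stat}")
    return ax
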