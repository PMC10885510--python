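"""Export processed event data as spreadsheet workbooks or delimited tables.

Two layouts are provided.  The machine layout is a tidy long table per dataset
sheet — columns (series, event, interval, t_rel, value) plus optional raw
values and timestamp variants — chosen so downstream tools can consume it
without reshaping.  The human layout is wide, one labeled column group per
event, for side-by-side inspection in a spreadsheet.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .io import Session, save_session
from .normalize import NormalizedEvent

__all__ = ["export_events", "read_processed_table", "export_session"]


def _long_table(
    series_name: str,
    normed: list[NormalizedEvent],
    include_raw: bool,
    timestamps: tuple[str, ...],
) -> pd.DataFrame:
    rows = []
    for ne in normed:
        for interval, data in ne.intervals.items():
            t_rel = data["time"]
            for j in range(t_rel.size):
                row = {
                    "series": series_name,
                    "event": ne.event.index,
                    "interval": interval,
                    "t_rel": float(t_rel[j]),
                    "value": float(data["normalized"][j]),
                }
                if include_raw:
                    row["raw"] = float(data["raw"][j])
                if "raw" in timestamps:
                    row["t_raw"] = float(ne.event.start_s + t_rel[j])
                if "interval" in timestamps:
                    w = ne.windows.get(interval)
                    start_rel = (w[0] - ne.event.start_s) if w else t_rel[0]
                    row["t_interval"] = float(t_rel[j] - start_rel)
                rows.append(row)
    cols = ["series", "event", "interval", "t_rel", "value"]
    if include_raw:
        cols.append("raw")
    if "raw" in timestamps:
        cols.append("t_raw")
    if "interval" in timestamps:
        cols.append("t_interval")
    return pd.DataFrame(rows, columns=cols)


def _human_table(
    series_name: str,
    normed: list[NormalizedEvent],
    align: str,
) -> pd.DataFrame:
    """Wide layout: one column per event; rows on relative time, optionally
    partitioned into contiguous blocks per interval."""
    long = _long_table(series_name, normed, include_raw=False, timestamps=())
    long["t_rel"] = np.round(long["t_rel"], 9)
    if align == "interval":
        wide = long.pivot_table(
            index=["interval", "t_rel"], columns="event", values="value", aggfunc="first"
        ).sort_index()
    else:
        wide = long.pivot_table(
            index="t_rel", columns="event", values="value", aggfunc="first"
        ).sort_index()
    wide.columns = [f"{series_name} event {c}" for c in wide.columns]
    return wide.reset_index()


def export_events(
    processed: dict[str, dict[str, list[NormalizedEvent]]],
    path,
    layout: str = "machine",
    align: str = "time",
    include_raw: bool = False,
    timestamps: tuple[str, ...] = (),
) -> Path:
    """Write processed events to a workbook: one sheet per dataset.

    ``processed`` maps dataset name -> series name -> normalized events.
    ``layout='machine'`` writes the tidy long table (sorted by event then time
    when ``align='time'``, grouped by interval when ``align='interval'``);
    ``layout='human'`` writes wide per-event columns.  ``timestamps`` may
    include ``'raw'`` (dataset time) and ``'interval'`` (time within each
    interval); relative-to-event time is always present.  A ``.csv`` path
    writes one CSV per dataset sheet instead of a workbook.
    """
    if layout not in {"machine", "human"}:
        raise ValueError(f"layout must be 'machine' or 'human', got {layout!r}")
    if align not in {"time", "interval"}:
        raise ValueError(f"align must be 'time' or 'interval', got {align!r}")
    if not processed or not any(processed.values()):
        raise ValueError("nothing to export: no processed event series")
    path = Path(path)

    sheets: dict[str, pd.DataFrame] = {}
    for dataset, series_map in processed.items():
        frames = []
        for series_name, normed in series_map.items():
            if layout == "machine":
                df = _long_table(series_name, normed, include_raw, timestamps)
                sort_cols = (["event", "interval", "t_rel"] if align == "interval"
                             else ["event", "t_rel", "interval"])
                df = df.sort_values(sort_cols, kind="stable").reset_index(drop=True)
            else:
                df = _human_table(series_name, normed, align)
            frames.append(df)
        sheets[dataset] = pd.concat(frames, axis=0 if layout == "machine" else 1)

    if path.suffix.lower() == ".csv":
        for dataset, df in sheets.items():
            target = (path if len(sheets) == 1
                      else path.with_name(f"{path.stem}_{dataset}{path.suffix}"))
            df.to_csv(target, index=False)
        return path
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for dataset, df in sheets.items():
            df.to_excel(writer, sheet_name=str(dataset)[:31], index=False)
    return path


def read_processed_table(path, sheet: str | int = 0) -> pd.DataFrame:
    """Re-import a machine-layout export (workbook sheet or CSV)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return pd.read_csv(path, float_precision="round_trip")
    return pd.read_excel(path, sheet_name=sheet)


def export_session(session: Session, path, overwrite: bool = False) -> Path:
    """Save the active session as a portable archive (delegates to io.save_session)."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    return save_session(session, path)
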