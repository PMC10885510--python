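"""Reading and writing the tabular and spectral file dialects, plus session archives.

All recordings are time-indexed tables of named numeric channels.  Times are in
seconds throughout the package; row/column indices accepted from users (header
row, data row, sheet) are 1-based, matching how lab spreadsheets are described;
internal arrays are 0-based numpy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

SESSION_SCHEMA_VERSION = 1

__all__ = [
    "FormatError",
    "Recording",
    "SpectralBlock",
    "ReferenceSpectra",
    "Session",
    "read_tabular_recording",
    "read_spectral_block",
    "read_reference_spectra",
    "write_recording",
    "save_session",
    "load_session",
]


class FormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


def _as_float_vector(values, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise FormatError(f"{what} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class Recording:
    """A named, time-indexed table of numeric channels at a nominal rate.

    Parameters
    ----------
    name:
        Text label for the recording.
    time:
        Strictly increasing vector of timestamps in seconds.
    channels:
        Mapping of channel name to a numeric vector the same length as ``time``.
        Missing samples are NaN.
    rate_hz:
        Nominal sampling rate in samples per second.
    """

    name: str
    time: np.ndarray
    channels: dict[str, np.ndarray]
    rate_hz: float

    def __post_init__(self) -> None:
        self.time = _as_float_vector(self.time, "time")
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValueError(f"recording {self.name!r}: time must be strictly increasing")
        if not self.rate_hz > 0:
            raise ValueError(f"recording {self.name!r}: rate_hz must be positive")
        clean = {}
        for ch, vec in self.channels.items():
            v = _as_float_vector(vec, f"channel {ch!r}")
            if v.size != self.time.size:
                raise ValueError(
                    f"recording {self.name!r}: channel {ch!r} has {v.size} samples, "
                    f"time has {self.time.size}"
                )
            clean[ch] = v
        self.channels = clean

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def span(self) -> tuple[float, float]:
        """(first, last) timestamp in seconds."""
        if not self.time.size:
            raise ValueError("empty recording has no span")
        return float(self.time[0]), float(self.time[-1])

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"recording {self.name!r} has no channel {name!r}; "
                f"available: {sorted(self.channels)}"
            ) from None

    def with_channel(self, name: str, values, *, replace: bool = False) -> "Recording":
        """Return a copy with ``name`` added (or replaced when ``replace``)."""
        if name in self.channels and not replace:
            raise ValueError(f"channel {name!r} already exists in recording {self.name!r}")
        channels = dict(self.channels)
        channels[name] = _as_float_vector(values, f"channel {name!r}")
        return Recording(self.name, self.time.copy(), channels, self.rate_hz)

    def rename(self, *, name: str | None = None,
               channels: Mapping[str, str] | None = None) -> "Recording":
        """Rename the recording and/or its channels (trivial map-key edits)."""
        new = {}
        mapping = dict(channels or {})
        missing = set(mapping) - set(self.channels)
        if missing:
            raise KeyError(f"cannot rename unknown channels: {sorted(missing)}")
        for ch, vec in self.channels.items():
            new[mapping.get(ch, ch)] = vec.copy()
        if len(new) != len(self.channels):
            raise ValueError("channel rename would collapse two channels into one")
        return Recording(name or self.name, self.time.copy(), new, self.rate_hz)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time})
        for ch, vec in self.channels.items():
            df[ch] = vec
        return df

    def __eq__(self, other) -> bool:  # value equality, NaN-aware
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.name == other.name
            and self.rate_hz == other.rate_hz
            and np.array_equal(self.time, other.time)
            and set(self.channels) == set(other.channels)
            and all(
                np.array_equal(self.channels[c], other.channels[c], equal_nan=True)
                for c in self.channels
            )
        )


@dataclass
class SpectralBlock:
    """Raw spectrometer output: a wavelength-bins x frames intensity matrix."""

    wavelengths_nm: np.ndarray
    frames: np.ndarray
    frame_rate_hz: float
    t0: float = 0.0
    name: str = "spectral"

    def __post_init__(self) -> None:
        self.wavelengths_nm = _as_float_vector(self.wavelengths_nm, "wavelengths_nm")
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2:
            raise ValueError(f"frames must be 2-D, got shape {self.frames.shape}")
        if self.frames.shape[0] != self.wavelengths_nm.size:
            raise ValueError(
                f"frames has {self.frames.shape[0]} wavelength rows but "
                f"{self.wavelengths_nm.size} wavelength bins were given"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise FormatError("wavelength axis must be strictly increasing")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[1])

    @property
    def frame_times(self) -> np.ndarray:
        """Timestamp of each frame in seconds: t0 + k / frame_rate_hz."""
        return self.t0 + np.arange(self.n_frames) / self.frame_rate_hz

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpectralBlock):
            return NotImplemented
        return (
            self.name == other.name
            and self.frame_rate_hz == other.frame_rate_hz
            and self.t0 == other.t0
            and np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and np.array_equal(self.frames, other.frames, equal_nan=True)
        )


@dataclass
class ReferenceSpectra:
    """Normalized emission spectra, one per fluorophore, on a shared wavelength axis."""

    wavelengths_nm: np.ndarray
    signals: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.wavelengths_nm = _as_float_vector(self.wavelengths_nm, "wavelengths_nm")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise FormatError("reference wavelength axis must be strictly increasing")
        clean = {}
        for sig, vec in self.signals.items():
            v = _as_float_vector(vec, f"reference {sig!r}")
            if v.size != self.wavelengths_nm.size:
                raise ValueError(
                    f"reference {sig!r} has {v.size} bins, expected {self.wavelengths_nm.size}"
                )
            clean[sig] = v
        self.signals = clean

    @property
    def names(self) -> list[str]:
        return list(self.signals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReferenceSpectra):
            return NotImplemented
        return (
            np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and set(self.signals) == set(other.signals)
            and all(np.array_equal(self.signals[s], other.signals[s]) for s in self.signals)
        )


# ---------------------------------------------------------------------------
# tabular readers


_DELIMITERS = (",", "\t", ";")


def _sniff_delimiter(header_line: str) -> str:
    counts = {d: header_line.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else ","


def _read_table(path: Path, header_row: int, data_row: int, sheet: int) -> pd.DataFrame:
    """Read a delimited-text or spreadsheet table with 1-based header/data rows."""
    if header_row < 1 or data_row <= header_row:
        raise FormatError(
            f"need 1 <= header_row < data_row, got header_row={header_row}, data_row={data_row}"
        )
    skip = list(range(header_row - 1)) + list(range(header_row, data_row - 1))
    if path.suffix.lower() in {".xlsx", ".xlsm", ".ods"}:
        try:
            return pd.read_excel(path, sheet_name=sheet - 1, header=0, skiprows=skip)
        except IndexError:
            raise FormatError(f"{path.name}: header row {header_row} beyond end of sheet")
    with open(path) as fh:
        lines = fh.readlines()
    if header_row > len(lines):
        raise FormatError(f"{path.name}: header row {header_row} beyond end of file ({len(lines)} lines)")
    delim = _sniff_delimiter(lines[header_row - 1])
    return pd.read_csv(path, sep=delim, header=0, skiprows=skip,
                       skip_blank_lines=False, float_precision="round_trip")


def read_tabular_recording(
    path,
    header_row: int = 1,
    data_row: int = 2,
    rate_hz: float | None = None,
    time_column: str | None = None,
    sheet: int = 1,
    name: str | None = None,
) -> Recording:
    """Read a delimited-text or spreadsheet recording into a :class:`Recording`.

    When ``time_column`` is None, a time axis is synthesized as ``i / rate_hz``
    starting at zero.  All non-time columns become channels; non-numeric cells
    become NaN; blank rows are preserved so channels stay aligned with time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such recording file: {path}")
    df = _read_table(path, header_row, data_row, sheet)
    df = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    numeric_cols = [c for c in df.columns if df[c].notna().any()]
    if not numeric_cols:
        raise FormatError(f"{path.name}: no numeric columns found")

    if time_column is not None:
        if time_column not in df.columns:
            raise FormatError(f"{path.name}: no column named {time_column!r}")
        time = df[time_column].to_numpy(dtype=float)
        if np.any(~np.isfinite(time)):
            raise FormatError(f"{path.name}: time column {time_column!r} has non-numeric cells")
        if rate_hz is None:
            dt = np.median(np.diff(time)) if time.size > 1 else 1.0
            rate_hz = 1.0 / dt
        channel_cols = [c for c in df.columns if c != time_column]
    else:
        if rate_hz is None or not rate_hz > 0:
            raise ValueError("rate_hz must be a positive number when no time column is given")
        time = np.arange(len(df)) / rate_hz
        channel_cols = list(df.columns)

    if not channel_cols:
        raise FormatError(f"{path.name}: no channel columns besides time")
    channels = {str(c): df[c].to_numpy(dtype=float) for c in channel_cols}
    return Recording(name or path.stem, time, channels, float(rate_hz))


def read_spectral_block(
    path,
    wavelength_row: int = 1,
    data_row: int = 2,
    frame_rate_hz: float = 1.0,
    t0: float = 0.0,
    transpose: bool = False,
    name: str | None = None,
) -> SpectralBlock:
    """Read a raw spectrometer export: a wavelength header row, then one frame per row.

    With ``transpose=True`` the file instead holds one wavelength bin per row and
    one frame per column (the first column being the wavelength axis).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such spectral file: {path}")
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines()]
    if wavelength_row > len(lines):
        raise FormatError(f"{path.name}: wavelength row {wavelength_row} beyond end of file")
    delim = _sniff_delimiter(lines[wavelength_row - 1])

    def parse_row(line: str) -> np.ndarray:
        cells = line.split(delim)
        return pd.to_numeric(pd.Series(cells), errors="coerce").to_numpy(dtype=float)

    if transpose:
        rows = [parse_row(ln) for ln in lines[data_row - 1:] if ln.strip()]
        mat = np.vstack(rows)
        wavelengths, frames = mat[:, 0], mat[:, 1:]
    else:
        wavelengths = parse_row(lines[wavelength_row - 1])
        wavelengths = wavelengths[np.isfinite(wavelengths)]
        rows = [parse_row(ln) for ln in lines[data_row - 1:] if ln.strip()]
        if not rows:
            raise FormatError(f"{path.name}: no frame rows at or after data row {data_row}")
        frames = np.vstack(rows).T
    if wavelengths.size == 0 or np.any(~np.isfinite(wavelengths)):
        raise FormatError(f"{path.name}: wavelength row did not parse to numbers")
    if np.any(np.diff(wavelengths) <= 0):
        raise FormatError(f"{path.name}: wavelength axis is not strictly increasing")
    if frames.shape[0] != wavelengths.size:
        raise FormatError(
            f"{path.name}: frames have {frames.shape[0]} bins but wavelength row has {wavelengths.size}"
        )
    return SpectralBlock(wavelengths, frames, float(frame_rate_hz), float(t0), name or path.stem)


def read_reference_spectra(path) -> ReferenceSpectra:
    """Read a reference-spectra CSV: wavelength column, then one column per signal.

    Each signal is renormalized so its maximum equals 1 if it is not already.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such reference file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise FormatError(f"{path.name}: need a wavelength column plus at least one signal column")
    if len(df) < 2:
        raise FormatError(f"{path.name}: need at least two wavelength rows to define spectra")
    wavelengths = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(wavelengths)):
        raise FormatError(f"{path.name}: wavelength column has non-numeric cells")
    signals: dict[str, np.ndarray] = {}
    for col in df.columns[1:]:
        vec = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        if not np.any(np.isfinite(vec)):
            raise FormatError(f"{path.name}: signal column {col!r} is empty")
        peak = np.nanmax(np.abs(vec))
        if peak == 0:
            raise FormatError(f"{path.name}: signal column {col!r} is all zeros")
        signals[str(col)] = vec / peak
    return ReferenceSpectra(wavelengths, signals)


def write_recording(rec: Recording, path) -> Path:
    """Write a recording as CSV (time column first) at full float precision."""
    path = Path(path)
    rec.to_frame().to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# session archive


@dataclass
class Session:
    """A saved analysis session: every typed object the pipeline holds."""

    recordings: list[Recording] = field(default_factory=list)
    spectral_blocks: list[SpectralBlock] = field(default_factory=list)
    reference_spectra: dict[str, ReferenceSpectra] = field(default_factory=dict)
    event_series: dict[str, list] = field(default_factory=dict)  # name -> list[Event]


def _rec_to_dict(rec: Recording) -> dict:
    return {
        "name": rec.name,
        "rate_hz": rec.rate_hz,
        "time": rec.time.tolist(),
        "channels": {c: v.tolist() for c, v in rec.channels.items()},
    }


def _block_to_dict(b: SpectralBlock) -> dict:
    return {
        "name": b.name,
        "frame_rate_hz": b.frame_rate_hz,
        "t0": b.t0,
        "wavelengths_nm": b.wavelengths_nm.tolist(),
        "frames": b.frames.tolist(),
    }


def _refs_to_dict(r: ReferenceSpectra) -> dict:
    return {
        "wavelengths_nm": r.wavelengths_nm.tolist(),
        "signals": {s: v.tolist() for s, v in r.signals.items()},
    }


def save_session(session: Session, path) -> Path:
    """Serialize a session to a schema-versioned JSON archive (lossless round trip)."""
    payload = {
        "schema": "fiberphot-session",
        "version": SESSION_SCHEMA_VERSION,
        "recordings": [_rec_to_dict(r) for r in session.recordings],
        "spectral_blocks": [_block_to_dict(b) for b in session.spectral_blocks],
        "reference_spectra": {k: _refs_to_dict(v) for k, v in session.reference_spectra.items()},
        "event_series": {
            name: [[ev.start_s, ev.end_s] for ev in evs]
            for name, evs in session.event_series.items()
        },
    }
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def load_session(path) -> Session:
    """Restore a session archive; refuses unknown schema versions and corrupt files."""
    from .events import Event  # deferred: events depends on io

    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path.name}: not a valid session archive ({exc})") from exc
    if not isinstance(payload, dict) or payload.get("schema") != "fiberphot-session":
        raise FormatError(f"{path.name}: not a fiberphot session archive")
    if payload.get("version") != SESSION_SCHEMA_VERSION:
        raise FormatError(
            f"{path.name}: unsupported session schema version {payload.get('version')!r} "
            f"(this build reads version {SESSION_SCHEMA_VERSION})"
        )
    try:
        recordings = [
            Recording(d["name"], np.asarray(d["time"], dtype=float),
                      {c: np.asarray(v, dtype=float) for c, v in d["channels"].items()},
                      float(d["rate_hz"]))
            for d in payload["recordings"]
        ]
        blocks = [
            SpectralBlock(np.asarray(d["wavelengths_nm"], dtype=float),
                          np.asarray(d["frames"], dtype=float),
                          float(d["frame_rate_hz"]), float(d["t0"]), d["name"])
            for d in payload["spectral_blocks"]
        ]
        refs = {
            k: ReferenceSpectra(np.asarray(d["wavelengths_nm"], dtype=float),
                                {s: np.asarray(v, dtype=float) for s, v in d["signals"].items()})
            for k, d in payload["reference_spectra"].items()
        }
        series = {
            name: [Event(start_s=float(s), end_s=float(e), index=i)
                   for i, (s, e) in enumerate(evs)]
            for name, evs in payload["event_series"].items()
        }
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path.name}: truncated or malformed session archive") from exc
    return Session(recordings, blocks, refs, series)
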