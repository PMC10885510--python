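"""Synthetic photometry fixtures with ground truth.

Generates recordings, behavior streams and spectrally resolved blocks that
emulate the structures a fiber-photometry session produces: a fluorescence
channel with an exponential photobleaching trend, stimulus-locked transients,
Gaussian white noise and a TTL indicator; a binary behavior bout channel at an
independent (typically slower) video rate; and a wavelength x frame intensity
matrix mixed from Gaussian-peaked reference spectra.

Defaults mirror a standard tone-presentation session: a 900 s recording
sampled at 25 Hz with five 10 s tones, transient amplitude 20 on a baseline of
100 (a 20% ΔF/F response) and unit noise.  The transient kernel is a fast
exponential rise that is sustained while the stimulus is on and decays
exponentially after it ends — the shape a slow calcium indicator produces for
a sustained stimulus; with zero duration it reduces to the classic
difference-of-exponentials impulse response.  These are test assumptions, not
sensor calibration.

Fixed seed implies byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Recording, ReferenceSpectra, SpectralBlock

__all__ = [
    "SynthSpec",
    "SpectralSynthSpec",
    "Transient",
    "make_recording",
    "make_behavior",
    "make_spectral",
    "write_fixture_files",
]

_TONE_ONSETS = (120.0, 270.0, 420.0, 570.0, 720.0)
_TONE_LEN = 10.0


@dataclass
class Transient:
    """One stimulus-locked fluorescence transient.

    Rises as ``1 - exp(-(t-onset)/rise_tau)``, holds while the stimulus lasts
    (``duration_s``), then decays as ``exp(-dt/decay_tau)``; ``amplitude``
    scales the plateau.  ``duration_s=0`` gives the pure double-exponential
    impulse kernel normalized to peak at ``amplitude``.
    """

    onset_s: float
    amplitude: float = 20.0
    rise_tau_s: float = 0.2
    decay_tau_s: float = 1.5
    duration_s: float = 0.0

    def waveform(self, t: np.ndarray) -> np.ndarray:
        dt = t - self.onset_s
        out = np.zeros_like(t)
        on = dt >= 0
        if self.duration_s > 0:
            rising = on & (dt <= self.duration_s)
            out[rising] = 1.0 - np.exp(-dt[rising] / self.rise_tau_s)
            after = dt > self.duration_s
            level = 1.0 - np.exp(-self.duration_s / self.rise_tau_s)
            out[after] = level * np.exp(-(dt[after] - self.duration_s) / self.decay_tau_s)
            return self.amplitude * out
        kern = np.exp(-dt[on] / self.decay_tau_s) - np.exp(-dt[on] / self.rise_tau_s)
        peak = kern.max() if kern.size else 1.0
        out[on] = kern / peak if peak > 0 else kern
        return self.amplitude * out


@dataclass
class SynthSpec:
    """Parameters of one synthetic recording (defaults: the five-tone session)."""

    duration_s: float = 900.0
    rate_hz: float = 25.0
    baseline_mu: float = 100.0
    noise_sd: float = 1.0
    bleach_amplitude: float = 0.0   # added on top of baseline_mu ...
    bleach_rate: float = 0.0        # ... decaying at this rate (1/s)
    transients: list[Transient] = field(default_factory=lambda: [
        Transient(onset, amplitude=20.0, rise_tau_s=0.2, decay_tau_s=1.5,
                  duration_s=_TONE_LEN)
        for onset in _TONE_ONSETS
    ])
    ttl_schedule: list[tuple[float, float]] = field(default_factory=lambda: [
        (onset, onset + _TONE_LEN) for onset in _TONE_ONSETS
    ])
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if not (self.duration_s > 0 and self.rate_hz > 0):
            raise ValueError("duration_s and rate_hz must be positive")
        if self.noise_sd < 0 or self.bleach_rate < 0:
            raise ValueError("noise_sd and bleach_rate must be >= 0")


def _trend(spec: SynthSpec, t: np.ndarray) -> np.ndarray:
    return spec.bleach_amplitude * np.exp(-spec.bleach_rate * t) + spec.baseline_mu


def make_recording(spec: SynthSpec) -> tuple[Recording, dict]:
    """Generate a recording and its ground truth.

    The ``signal`` channel is ``trend(t) + sum of transients + N(0, noise_sd)``;
    the ``ttl`` channel is exactly 1 inside each scheduled period (half-open)
    and 0 elsewhere.  Ground truth holds the clean (noise-free) signal, the
    trend alone, the schedule, and each scheduled event's true mean ΔF/F
    (clean in-event transient mean over the local trend).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.rate_hz))
    t = np.arange(n) / spec.rate_hz
    trend = _trend(spec, t)
    transient_sum = np.zeros(n)
    for tr in spec.transients:
        transient_sum += tr.waveform(t)
    clean = trend + transient_sum
    signal = clean + rng.normal(0.0, spec.noise_sd, n)

    ttl = np.zeros(n)
    for start, end in spec.ttl_schedule:
        ttl[(t >= start) & (t < end)] = 1.0

    event_truth = []
    for start, end in spec.ttl_schedule:
        m = (t >= start) & (t < end)
        if m.any():
            event_truth.append({
                "start_s": start, "end_s": end,
                "mean_dff": float(np.mean(transient_sum[m] / trend[m])),
                "peak_amplitude": float(transient_sum[m].max()),
            })
    rec = Recording(spec.name, t, {"signal": signal, "ttl": ttl}, spec.rate_hz)
    truth = {
        "clean": clean, "trend": trend, "transient_sum": transient_sum,
        "events": event_truth, "schedule": list(spec.ttl_schedule),
    }
    return rec, truth


def make_behavior(
    bouts: list[tuple[float, float]],
    duration_s: float,
    rate_hz: float = 10.0,
    name: str = "behavior",
    t0: float = 0.0,
) -> Recording:
    """A binary behavior-score recording (e.g. wheel running) at its own rate.

    The channel is 1 at samples inside any bout (half-open) and 0 elsewhere,
    mimicking exported video-tracking scores at a rate independent of the
    photometry clock.
    """
    n = int(round(duration_s * rate_hz))
    t = t0 + np.arange(n) / rate_hz
    x = np.zeros(n)
    for start, end in bouts:
        x[(t >= start) & (t < end)] = 1.0
    return Recording(name, t, {"running": x}, rate_hz)


@dataclass
class SpectralSynthSpec:
    """Parameters of a synthetic spectrally resolved block.

    Reference spectra are Gaussian emission peaks (center, width in nm) — by
    default a 515 nm activity-dependent signal and a 580 nm static control,
    the classic green/red overlapping pair.  Coefficient time courses default
    to a slowly modulated activity signal over a constant control.
    """

    wavelengths_nm: np.ndarray = field(
        default_factory=lambda: np.arange(480.0, 641.0, 2.0))
    peaks: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "green": (515.0, 18.0), "red": (580.0, 22.0)})
    n_frames: int = 200
    frame_rate_hz: float = 10.0
    noise_sd: float = 0.0
    courses: dict[str, np.ndarray] | None = None
    seed: int = 0


def make_spectral(
    spec: SpectralSynthSpec,
) -> tuple[SpectralBlock, ReferenceSpectra, dict[str, np.ndarray]]:
    """Generate frames = refs x true coefficient courses (+ noise), with truth.

    Returns the block, the normalized reference spectra, and the true
    per-signal coefficient time courses.
    """
    w = np.asarray(spec.wavelengths_nm, dtype=float)
    refs = {}
    for name, (center, width) in spec.peaks.items():
        shape = np.exp(-0.5 * ((w - center) / width) ** 2)
        refs[name] = shape / shape.max()
    reference = ReferenceSpectra(w, refs)

    rng = np.random.default_rng(spec.seed)
    k = np.arange(spec.n_frames)
    if spec.courses is not None:
        courses = {n: np.asarray(c, dtype=float) for n, c in spec.courses.items()}
        if set(courses) != set(refs):
            raise ValueError("courses must name exactly the reference signals")
    else:
        names = list(refs)
        courses = {names[0]: 5.0 + 2.0 * np.sin(2 * np.pi * k / 50.0)}
        for extra in names[1:]:
            courses[extra] = np.full(spec.n_frames, 3.0)

    X = np.column_stack([refs[n] for n in refs])
    C = np.vstack([courses[n] for n in refs])
    frames = X @ C
    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, frames.shape)
    block = SpectralBlock(w, frames, spec.frame_rate_hz, name="synthetic_spectral")
    return block, reference, courses


def write_fixture_files(outdir, spec: SynthSpec | None = None,
                        spectral: SpectralSynthSpec | None = None) -> dict:
    """Write a full set of fixture files in the package's input dialects.

    Produces a tabular recording CSV, a spectrometer frame-matrix file
    (wavelength header row, one frame per row) and a reference-spectra CSV;
    returns the paths.
    """
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or SynthSpec()
    spectral = spectral or SpectralSynthSpec()

    rec, _ = make_recording(spec)
    rec_path = outdir / "recording.csv"
    rec.to_frame().to_csv(rec_path, index=False)

    block, refs, _ = make_spectral(spectral)
    spec_path = outdir / "spectral_frames.csv"
    header = ",".join(f"{v:g}" for v in block.wavelengths_nm)
    rows = [",".join(repr(float(v)) for v in block.frames[:, k])
            for k in range(block.n_frames)]
    spec_path.write_text(header + "\n" + "\n".join(rows) + "\n")

    refs_path = outdir / "reference_spectra.csv"
    df = pd.DataFrame({"wavelength_nm": refs.wavelengths_nm, **refs.signals})
    df.to_csv(refs_path, index=False)
    return {"recording": rec_path, "spectral": spec_path, "references": refs_path}
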