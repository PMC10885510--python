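"""Linear spectral unmixing and wavelength-band summaries.

Spectrally resolved photometry records a full emission spectrum per frame.  When
two fluorophores (say an activity-dependent calcium indicator and a static
control fluorophore) have overlapping emission, their contributions are
separated either by regressing each frame onto normalized reference spectra
(per-frame ordinary least squares), or by summarizing user-chosen wavelength
bands over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .io import Recording, ReferenceSpectra, SpectralBlock

__all__ = ["UnmixResult", "unmix", "summarize_band", "band_ratio"]

_EPS = 1e-12


@dataclass
class UnmixResult:
    """Per-frame regression coefficients, one time course per reference signal."""

    coefficients: dict[str, np.ndarray]  # signal -> vector over frames
    residual_rms: np.ndarray
    intercept: np.ndarray | None = None
    frame_times: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return int(self.residual_rms.size)

    def to_recording(self, frame_rate_hz: float, name: str = "unmixed") -> Recording:
        """Package the coefficient time courses as a Recording."""
        n = self.n_frames
        time = (self.frame_times if self.frame_times is not None
                else np.arange(n) / frame_rate_hz)
        channels = {sig: c.copy() for sig, c in self.coefficients.items()}
        channels["residual_rms"] = self.residual_rms.copy()
        return Recording(name, time, channels, frame_rate_hz)


def _interp_refs(block: SpectralBlock, refs: ReferenceSpectra) -> np.ndarray:
    """Reference responses on the block's wavelength bins (linear interpolation,
    extrapolation forbidden)."""
    w_block, w_ref = block.wavelengths_nm, refs.wavelengths_nm
    if np.array_equal(w_block, w_ref):
        return np.column_stack([refs.signals[s] for s in refs.names])
    if w_block[0] < w_ref[0] - _EPS or w_block[-1] > w_ref[-1] + _EPS:
        raise ValueError(
            f"reference spectra cover {w_ref[0]:g}-{w_ref[-1]:g} nm but the recording "
            f"spans {w_block[0]:g}-{w_block[-1]:g} nm; extrapolation is not supported"
        )
    return np.column_stack(
        [np.interp(w_block, w_ref, refs.signals[s]) for s in refs.names]
    )


def _check_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the most collinear pair for the error message
        norm = design / np.maximum(np.linalg.norm(design, axis=0), _EPS)
        gram = np.abs(norm.T @ norm)
        np.fill_diagonal(gram, 0.0)
        i, j = np.unravel_index(np.argmax(gram), gram.shape)
        labels = names + ["<intercept>"] * (design.shape[1] - len(names))
        raise np.linalg.LinAlgError(
            f"reference spectra are collinear (rank {rank} < {design.shape[1]}); "
            f"most collinear pair: {labels[i]!r} and {labels[j]!r}"
        )


def unmix(
    block: SpectralBlock,
    refs: ReferenceSpectra,
    include_intercept: bool = False,
    nonnegative: bool = False,
) -> UnmixResult:
    """Fit each spectral frame as a linear combination of the reference spectra.

    For every frame y (intensity over wavelength bins) the coefficients c solve
    ``min ||y - X c||`` with X holding one column per normalized reference
    spectrum (plus a constant column when ``include_intercept``).  The
    coefficient time courses measure each fluorophore's intensity over time.

    ``nonnegative=True`` constrains coefficients to c >= 0 (physical
    intensities cannot be negative); the default is unconstrained least
    squares.
    """
    names = refs.names
    X = _interp_refs(block, refs)
    if include_intercept:
        X = np.column_stack([X, np.ones(X.shape[0])])
    n_bins, n_cols = X.shape
    if n_bins < n_cols:
        raise ValueError(
            f"{n_bins} wavelength bins cannot determine {n_cols} coefficients"
        )
    _check_rank(X, names)

    Y = block.frames  # (n_bins, n_frames)
    if nonnegative:
        coef = np.empty((n_cols, block.n_frames))
        for k in range(block.n_frames):
            coef[:, k], _ = nnls(X, Y[:, k])
    else:
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    residual_rms = np.sqrt(np.mean(resid**2, axis=0))

    coefficients = {sig: coef[j] for j, sig in enumerate(names)}
    intercept = coef[-1] if include_intercept else None
    return UnmixResult(coefficients, residual_rms, intercept, block.frame_times)


def summarize_band(
    block: SpectralBlock, lo_nm: float, hi_nm: float, stat: str = "mean"
) -> np.ndarray:
    """Summarize intensities whose bin center lies in [lo_nm, hi_nm], per frame.

    ``stat`` is one of ``mean``, ``median`` or ``auc`` (trapezoidal integral
    over the wavelength axis, so its units are intensity x nm).
    """
    if not lo_nm < hi_nm:
        raise ValueError(f"need lo_nm < hi_nm, got [{lo_nm}, {hi_nm}]")
    if stat not in {"mean", "median", "auc"}:
        raise ValueError(f"stat must be mean, median or auc, got {stat!r}")
    w = block.wavelengths_nm
    mask = (w >= lo_nm) & (w <= hi_nm)
    n_in = int(mask.sum())
    if n_in == 0 or (stat == "auc" and n_in < 2):
        raise ValueError(
            f"band [{lo_nm}, {hi_nm}] nm selects {n_in} bins "
            f"(available range {w[0]:g}-{w[-1]:g} nm; auc needs at least 2)"
        )
    sub = block.frames[mask]
    if stat == "mean":
        return sub.mean(axis=0)
    if stat == "median":
        return np.median(sub, axis=0)
    return np.trapezoid(sub, x=w[mask], axis=0)


def band_ratio(numerator: np.ndarray, denominator: np.ndarray) -> np.ndarray:
    """Elementwise ratio of two band summaries; NaN where the denominator is ~0.

    Band-ratio traces are typically detrended afterwards (see
    :func:`fiberphot.transforms.fit_detrend`), which is the default pipeline
    step following this operation.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if num.shape != den.shape:
        raise ValueError(f"shape mismatch: {num.shape} vs {den.shape}")
    if np.all(np.abs(den) < _EPS):
        raise ValueError("denominator is zero everywhere; ratio undefined")
    out = np.full_like(num, np.nan)
    ok = np.abs(den) >= _EPS
    out[ok] = num[ok] / den[ok]
    return out
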