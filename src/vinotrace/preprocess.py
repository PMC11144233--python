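"""Spectral preprocessing: MSC, Savitzky-Golay smoothing, first derivative.

The chain applied to every scan, in order:

1. **MSC** (multiplicative scatter correction): each spectrum ``x`` is
   regressed on a reference spectrum by ordinary least squares,
   ``x ~ a*ref + b``, and replaced by ``(x - b)/a``.  This inverts the
   affine slope/offset distortion produced by particle scattering.  The
   reference is fitted once on training data (its mean spectrum) and
   reused for held-out data.
2. **S-G smoothing**: local polynomial least-squares filter
   (default window 11 grid points, order 2); edge points are handled by
   polynomial fits on the truncated window (``mode='interp'``).
3. **First derivative** with respect to wavelength, computed by the same
   Savitzky-Golay filter with ``deriv=1`` and scaled by the grid step,
   so units are absorbance per nm.  Removes residual additive baselines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .containers import SpectrumSet

__all__ = [
    "PreprocessConfig",
    "msc",
    "sg_smooth",
    "first_derivative",
    "preprocess_chain",
]


class DegenerateReferenceError(ValueError):
    """MSC reference has zero variance; the OLS slope is undefined."""


@dataclass
class PreprocessConfig:
    sg_window: int = 11
    sg_polyorder: int = 2

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must exceed sg_polyorder")


def _flat_view(spectra: SpectrumSet) -> np.ndarray:
    """All scans as rows, shape (n_samples*n_scans, n_wavelengths)."""
    return spectra.absorbance.reshape(-1, spectra.n_wavelengths)


def msc_vector(x: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """MSC-correct rows of ``x`` against ``reference`` (OLS slope/intercept)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    reference = np.asarray(reference, dtype=float)
    r_centered = reference - reference.mean()
    denom = np.dot(r_centered, r_centered)
    if denom == 0.0:
        raise DegenerateReferenceError(
            "MSC reference is constant (zero variance); slope undefined"
        )
    slope = (x - x.mean(axis=1, keepdims=True)) @ r_centered / denom
    intercept = x.mean(axis=1) - slope * reference.mean()
    return (x - intercept[:, None]) / slope[:, None]


def msc(spectra: SpectrumSet, reference: np.ndarray | None = None) -> SpectrumSet:
    """Multiplicative scatter correction of every scan.

    ``reference`` defaults to the mean spectrum over all scans in the set.
    Corrected spectra regress on the reference with slope 1, intercept 0.
    """
    flat = _flat_view(spectra)
    if reference is None:
        reference = flat.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (spectra.n_wavelengths,):
        raise ValueError("MSC reference must be on the same wavelength grid")
    corrected = msc_vector(flat, reference)
    return spectra.with_absorbance(
        corrected.reshape(spectra.absorbance.shape), note="msc"
    )


def sg_smooth(spectra: SpectrumSet, window: int = 11, polyorder: int = 2) -> SpectrumSet:
    """Savitzky-Golay smoothing of every scan along the wavelength axis."""
    _check_sg(spectra, window, polyorder)
    out = savgol_filter(spectra.absorbance, window, polyorder, axis=-1, mode="interp")
    return spectra.with_absorbance(out, note=f"sg_smooth(window={window}, order={polyorder})")


def first_derivative(spectra: SpectrumSet, window: int = 11, polyorder: int = 2) -> SpectrumSet:
    """Savitzky-Golay first derivative, in absorbance per nm (uniform grid only)."""
    _check_sg(spectra, window, polyorder)
    steps = np.diff(spectra.wavelengths)
    step = steps[0]
    if not np.allclose(steps, step, rtol=1e-6, atol=1e-9):
        raise ValueError(
            "first_derivative requires a uniform wavelength grid; resample first"
        )
    out = savgol_filter(spectra.absorbance, window, polyorder, deriv=1,
                        delta=step, axis=-1, mode="interp")
    return spectra.with_absorbance(out, note=f"first_derivative(step={step})")


def _check_sg(spectra: SpectrumSet, window: int, polyorder: int) -> None:
    if window % 2 == 0:
        raise ValueError("SG window must be odd")
    if window <= polyorder:
        raise ValueError("SG window must exceed the polynomial order")
    if window > spectra.n_wavelengths:
        raise ValueError(
            f"SG window {window} exceeds grid length {spectra.n_wavelengths}"
        )


def preprocess_chain(
    spectra: SpectrumSet,
    cfg: PreprocessConfig | None = None,
    fitted_reference: np.ndarray | None = None,
) -> tuple[SpectrumSet, np.ndarray]:
    """Apply MSC -> S-G smoothing -> first derivative.

    When ``fitted_reference`` is None the MSC reference is fitted as the
    mean spectrum of the input (a training fit) and returned so the same
    reference can be reused on held-out data.
    """
    cfg = cfg or PreprocessConfig()
    if fitted_reference is None:
        fitted_reference = _flat_view(spectra).mean(axis=0)
    out = msc(spectra, fitted_reference)
    out = sg_smooth(out, cfg.sg_window, cfg.sg_polyorder)
    out = first_derivative(out, cfg.sg_window, cfg.sg_polyorder)
    return out, fitted_reference
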