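"""Generalized two-dimensional correlation spectroscopy (2D-COS).

A sample measured repeatedly under a perturbation (here: scan index,
i.e. time) yields a dynamic spectrum ``y(v, t) = x(v, t) - xref(v)``.
Cross-correlating the dynamic spectra of two wavelengths over the
perturbation axis spreads the 1-D spectrum over a 2-D plane:

* synchronous spectrum ``Phi(v1, v2) = y(v1,:) . y(v2,:) / (m - 1)`` —
  in-phase co-variation; symmetric, positive semidefinite, diagonal
  auto-peaks are perturbation variances;
* asynchronous spectrum ``Psi(v1, v2) = y(v1,:) . (N y(v2,:)) / (m - 1)``
  with ``N`` the Hilbert-Noda matrix ``N_jk = 1/(pi (k - j))`` (zero
  diagonal) — out-of-phase, sequential variation; antisymmetric with no
  auto-peaks.

An equivalent Fourier-domain formulation (cross-spectrum over one-sided
frequencies; real part synchronous, imaginary part asynchronous) is
provided as an independent oracle: the Hilbert-Noda matrix is the
discrete quadrature operator, so both routes converge as the number of
perturbation points grows.

Note on the asynchronous formula: it is sometimes typeset as a product
of two *independent* full sums over the perturbation index, which would
make ``Psi`` rank-one and destroy its antisymmetry / zero diagonal.  The
implementation uses the standard single-sum Noda form above, which
satisfies those properties by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib import colormaps
from PIL import Image
from scipy.interpolate import RegularGridInterpolator

from .bands import BandWindow, cut_band
from .containers import SpectrumSet

__all__ = [
    "DynamicSpectrum",
    "CorrelationPair",
    "COSImage",
    "RenderConfig",
    "dynamic_spectrum",
    "hilbert_noda",
    "sync_spectrum",
    "async_spectrum",
    "fourier_oracle",
    "render_contour",
    "batch_cos",
]


@dataclass
class DynamicSpectrum:
    """Mean-referenced perturbation series of one sample in one band."""

    wavelengths: np.ndarray   # (n,)
    y: np.ndarray             # (n, m): wavelength x perturbation index
    reference: np.ndarray     # (n,)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("y must be (n_wavelengths, m)")
        if self.y.shape[1] < 2:
            raise ValueError("need m >= 2 perturbation points")
        if self.y.shape[0] != np.asarray(self.wavelengths).size:
            raise ValueError("y rows must match the wavelength grid")

    @property
    def m(self) -> int:
        return self.y.shape[1]


@dataclass
class CorrelationPair:
    wavelengths: np.ndarray
    sync: np.ndarray
    async_: np.ndarray


def dynamic_spectrum(
    scans: np.ndarray,
    wavelengths: np.ndarray | None = None,
    reference_mode: str = "perturbation_mean",
    reference: np.ndarray | None = None,
) -> DynamicSpectrum:
    """Build ``y(v, t) = x(v, t) - xref(v)`` from an (n, m) scan matrix.

    ``reference_mode``:

    * ``perturbation_mean`` — per-wavelength mean over the sample's own
      scans (the textbook choice; rows of ``y`` then sum to zero);
    * ``provided`` — an external reference vector, e.g. the grand mean
      spectrum of the whole sample set in the band, or zeros (in which
      case the dynamic spectrum is the raw intensity itself).
    """
    scans = np.asarray(scans, dtype=float)
    if scans.ndim != 2:
        raise ValueError("scans must be an (n_wavelengths, m) matrix")
    n, m = scans.shape
    if wavelengths is None:
        wavelengths = np.arange(n, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if reference_mode == "perturbation_mean":
        ref = scans.mean(axis=1)
    elif reference_mode == "provided":
        if reference is None:
            raise ValueError("reference_mode='provided' requires a reference vector")
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (n,):
            raise ValueError(
                f"reference grid mismatch: expected {(n,)}, got {ref.shape}"
            )
    else:
        raise ValueError(f"unknown reference_mode '{reference_mode}'")
    return DynamicSpectrum(wavelengths=wavelengths, y=scans - ref[:, None],
                           reference=ref)


def hilbert_noda(m: int) -> np.ndarray:
    """The m x m Hilbert-Noda matrix: 0 on the diagonal, 1/(pi(k-j)) off it."""
    if m < 1:
        raise ValueError("Hilbert-Noda matrix order must be >= 1")
    j = np.arange(m)
    diff = j[None, :] - j[:, None]       # k - j
    with np.errstate(divide="ignore"):
        out = np.where(diff == 0, 0.0, 1.0 / (np.pi * diff))
    return out


def sync_spectrum(d: DynamicSpectrum) -> np.ndarray:
    """Synchronous correlation spectrum ``Y Y^T / (m - 1)``."""
    return d.y @ d.y.T / (d.m - 1)


def async_spectrum(d: DynamicSpectrum) -> np.ndarray:
    """Asynchronous correlation spectrum ``Y N Y^T / (m - 1)`` (Hilbert-Noda)."""
    return d.y @ hilbert_noda(d.m) @ d.y.T / (d.m - 1)


def fourier_oracle(d: DynamicSpectrum, pad_factor: int = 8) -> CorrelationPair:
    """Cross-check route: correlation spectra via the Fourier transform.

    The defining cross-correlation integral treats the dynamic spectrum
    as zero outside the observation window, so the transform here is the
    zero-padded DFT (``pad_factor`` times the series length), which
    samples the continuous one-sided frequency axis.  The cross-spectrum
    ``sum_k w_k Y1(k) conj(Y2(k))`` then gives the synchronous spectrum
    as its real part (DC/Nyquist once, interior bins twice —
    Parseval-exact at any padding) and the asynchronous spectrum as its
    imaginary part (interior bins only).

    Used only to validate the Hilbert-Noda implementation.  The two
    asynchronous routes agree up to the truncated Hilbert kernel's gain
    rolloff, a relative error of about ``2 f / m`` for a component with
    ``f`` cycles over the ``m``-point window, vanishing as m grows.
    """
    m = d.m
    if m < 4:
        raise ValueError("fourier_oracle needs m >= 4")
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    M = pad_factor * m
    F = np.fft.rfft(d.y, n=M, axis=1)          # (n, M//2 + 1)
    n_bins = F.shape[1]
    w_sync = np.full(n_bins, 2.0)
    w_sync[0] = 1.0
    if M % 2 == 0:
        w_sync[-1] = 1.0
    w_async = np.full(n_bins, 2.0)
    w_async[0] = 0.0
    if M % 2 == 0:
        w_async[-1] = 0.0
    cross_sync = (F * w_sync) @ F.conj().T
    cross_async = (F * w_async) @ F.conj().T
    scale = 1.0 / (M * (m - 1))
    return CorrelationPair(
        wavelengths=d.wavelengths,
        sync=scale * cross_sync.real,
        async_=scale * cross_async.imag,
    )


# ---------------------------------------------------------------------------
# rendering

@dataclass
class RenderConfig:
    """Filled-contour raster settings: the correlation matrix is resampled
    to ``size x size``, quantized into ``levels`` bands on a diverging
    scale symmetric about zero (limits +/- max|matrix|, per image), and
    colorized through a fixed palette.  No axes, labels or margins, so the
    raster is a byte-deterministic function of (matrix, config)."""

    size: int = 128
    levels: int = 16
    cmap: str = "RdBu_r"

    def __post_init__(self) -> None:
        if self.size < 8:
            raise ValueError("render size must be >= 8")
        if self.levels < 2:
            raise ValueError("need at least 2 contour levels")


@dataclass
class COSImage:
    pixels: np.ndarray            # (H, W, 3) uint8
    meta: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Image.fromarray(self.pixels, mode="RGB").save(path)

    @classmethod
    def load(cls, path: str | Path) -> "COSImage":
        with Image.open(path) as im:
            pixels = np.asarray(im.convert("RGB"))
        return cls(pixels=pixels, meta={"path": str(path)})


def render_contour(matrix: np.ndarray, cfg: RenderConfig | None = None,
                   meta: dict | None = None) -> COSImage:
    """Render a square correlation matrix to a filled-contour RGB raster."""
    cfg = cfg or RenderConfig()
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("render_contour needs a square matrix")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("render_contour needs finite values")
    n = matrix.shape[0]
    if n >= 2 and cfg.size != n:
        src = np.arange(n, dtype=float)
        interp = RegularGridInterpolator((src, src), matrix, method="linear")
        tgt = np.linspace(0.0, n - 1.0, cfg.size)
        gx, gy = np.meshgrid(tgt, tgt, indexing="ij")
        field_ = interp(np.stack([gx, gy], axis=-1))
    else:
        field_ = np.broadcast_to(matrix, (cfg.size, cfg.size)) if n == 1 else matrix
    limit = np.abs(matrix).max()
    if limit == 0.0:
        idx = np.full((cfg.size, cfg.size), cfg.levels // 2, dtype=int)
    else:
        edges = np.linspace(-limit, limit, cfg.levels + 1)
        idx = np.clip(np.digitize(field_, edges) - 1, 0, cfg.levels - 1)
    lut = (colormaps[cfg.cmap].resampled(cfg.levels)(np.arange(cfg.levels))[:, :3]
           * 255.0 + 0.5).astype(np.uint8)
    # image convention: first wavelength axis runs bottom-to-top
    pixels = lut[idx[::-1, :]]
    return COSImage(pixels=pixels, meta=dict(meta or {}))


# ---------------------------------------------------------------------------
# batch generation

def correlation_pair(
    band_set: SpectrumSet, sample_index: int,
    reference_mode: str = "grand_mean",
) -> CorrelationPair:
    """Synchronous + asynchronous spectra of one sample within a band-cut set.

    ``reference_mode='grand_mean'`` references every sample against the
    mean spectrum of the whole set in the band (the study's convention:
    each sample's scan series is compared with the population average);
    ``'perturbation_mean'`` uses the sample's own scan mean.
    """
    scans = band_set.absorbance[sample_index].T       # (n_wl, m)
    if reference_mode == "grand_mean":
        ref = band_set.absorbance.mean(axis=(0, 1))
        d = dynamic_spectrum(scans, band_set.wavelengths,
                             reference_mode="provided", reference=ref)
    else:
        d = dynamic_spectrum(scans, band_set.wavelengths,
                             reference_mode=reference_mode)
    return CorrelationPair(wavelengths=band_set.wavelengths,
                           sync=sync_spectrum(d), async_=async_spectrum(d))


def batch_cos(
    spectra: SpectrumSet,
    windows: list[BandWindow],
    types: tuple[str, ...] = ("sync", "async"),
    render_cfg: RenderConfig | None = None,
    out_dir: str | Path | None = None,
    reference_mode: str = "grand_mean",
) -> tuple[list[COSImage], pd.DataFrame]:
    """One contour image per (sample, window, type), plus a manifest.

    The manifest records sample id, class, window, type and (when
    ``out_dir`` is given) the PNG path of every image; the image count is
    ``n_samples * len(windows) * len(types)``.
    """
    if not windows:
        raise ValueError("batch_cos needs at least one band window")
    bad = [t for t in types if t not in ("sync", "async")]
    if bad:
        raise ValueError(f"unknown image type(s) {bad}; use 'sync'/'async'")
    render_cfg = render_cfg or RenderConfig()
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

    images: list[COSImage] = []
    rows = []
    for window in windows:
        band_set = cut_band(spectra, window)
        for i, sid in enumerate(band_set.sample_ids):
            try:
                pair = correlation_pair(band_set, i, reference_mode=reference_mode)
            except Exception as exc:
                raise RuntimeError(f"2D-COS failed for sample '{sid}' in "
                                   f"{window.label}: {exc}") from exc
            for kind in types:
                matrix = pair.sync if kind == "sync" else pair.async_
                meta = {"sample_id": sid, "class": band_set.labels[sid],
                        "window": window.label, "type": kind}
                img = render_contour(matrix, render_cfg, meta=meta)
                path = ""
                if out is not None:
                    path = str(out / f"{sid}__{window.label}__{kind}.png")
                    img.save(path)
                    img.meta["path"] = path
                images.append(img)
                rows.append({"sample_id": sid, "class": band_set.labels[sid],
                             "window": window.label, "type": kind, "path": path})
    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return images, manifest
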