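"""Synthetic NIR spectra and metabolite peak-area tables.

Emulates a wine origin-traceability study: six production regions, 30
bottles per region, each measured by repeated NIR scans on a 900-2500 nm
grid at 3.2 nm resolution.  Every statistical feature the downstream
analysis relies on is generated explicitly and controllably:

* class-dependent absorbance peaks (the chemical signature of origin),
* per-sample multiplicative scatter (slope/offset, so that MSC is the
  correct corrector by construction),
* per-scan gain drift of the absorption peaks (the perturbation that
  generalized 2D correlation analysis cross-correlates),
* additive white noise.

A matched metabolite table emulates UPLC-Q-TOF-MS peak areas with a
configurable set of truly differential compounds, so the screening stage
has a known ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ConfigurationError, MetaboliteTable, SpectrumSet

__all__ = [
    "SimConfig",
    "simulate_spectra",
    "simulate_metabolites",
    "write_fixture",
    "read_fixture",
    "DEFAULT_COMPOUNDS",
    "DEFAULT_DIFFERENTIAL",
    "EXTENDED_COMPOUNDS",
]

#: Default compound panel: the three region-differential marker
#: compounds the screening stage is meant to recover.
DEFAULT_COMPOUNDS = ("Indole", "Sulfacetamide", "Caffeine")
DEFAULT_DIFFERENTIAL = ("Indole", "Sulfacetamide", "Caffeine")

#: Richer panel adding matrix compounds common to all regions, for
#: fixtures that should exercise the screen's specificity.
EXTENDED_COMPOUNDS = DEFAULT_COMPOUNDS + ("Tartaric acid", "Glycerol", "Resveratrol")

_BASE_AREAS = {
    "Indole": 84.0,
    "Sulfacetamide": 79.0,
    "Caffeine": 93.0,
    "Tartaric acid": 60.0,
    "Glycerol": 110.0,
    "Resveratrol": 45.0,
}


@dataclass
class SimConfig:
    """Generator settings; defaults reproduce the study design shape.

    Absorbance peaks sit at the five wavelengths where real wine spectra
    differ between regions; each class shifts the peak amplitudes by
    ``class_effect_size`` times a fixed unit pattern (see
    :meth:`class_pattern`), so classes are separable by construction and
    the shifted peaks fall inside the 1000-1400 / 1500-1800 nm
    characteristic windows.
    """

    n_classes: int = 6
    samples_per_class: int = 30
    scans_per_sample: int = 10
    wavelength_start: float = 900.0
    wavelength_stop: float = 2500.0
    wavelength_step: float = 3.2
    peak_centers: tuple[float, ...] = (1123.0, 1281.0, 1592.0, 1650.0, 1805.0)
    peak_amplitudes: tuple[float, ...] = (0.30, 0.25, 0.35, 0.30, 0.28)
    peak_fwhm_nm: float = 30.0
    class_effect_size: float = 0.06     # absorbance shift at peak apex
    scatter_slope_sd: float = 0.05      # lognormal sigma of slope a
    scatter_offset_sd: float = 0.02     # normal sd of offset b
    noise_sd: float = 0.002             # absorbance units per grid point
    drift_per_scan: float = 0.003       # peak-apex absorbance units per scan index
    metabolite_sd: float = 4.0          # peak-area noise sd
    metabolite_effect: float = 10.0     # area shift of a differential compound
    seed: int = 0

    def __post_init__(self) -> None:
        self.peak_centers = tuple(float(c) for c in self.peak_centers)
        self.peak_amplitudes = tuple(float(a) for a in self.peak_amplitudes)
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        if self.samples_per_class < 1:
            raise ConfigurationError("samples_per_class must be >= 1")
        if self.scans_per_sample < 2:
            raise ConfigurationError(
                "scans_per_sample must be >= 2 (the asynchronous spectrum "
                "needs at least two perturbation points)"
            )
        if self.wavelength_step <= 0:
            raise ConfigurationError("wavelength_step must be > 0")
        if self.wavelength_stop <= self.wavelength_start:
            raise ConfigurationError("wavelength_stop must exceed wavelength_start")
        if len(self.peak_amplitudes) != len(self.peak_centers):
            raise ConfigurationError(
                "peak_amplitudes must match peak_centers in length"
            )
        if self.peak_fwhm_nm <= 0:
            raise ConfigurationError("peak_fwhm_nm must be > 0")
        for name in ("scatter_slope_sd", "scatter_offset_sd", "noise_sd",
                     "metabolite_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(np.floor((self.wavelength_stop - self.wavelength_start)
                         / self.wavelength_step + 1e-9)) + 1
        return self.wavelength_start + self.wavelength_step * np.arange(n)

    @property
    def class_names(self) -> list[str]:
        return [f"region{c + 1:02d}" for c in range(self.n_classes)]

    def class_pattern(self, c: int) -> np.ndarray:
        """Unit amplitude-shift pattern of class ``c`` across the peaks.

        Consecutive peak pairs carry ``(cos, sin)`` of the class angle
        ``pi*c/n_classes`` (with a fixed per-pair phase offset), so
        within any wavelength window holding at least two peaks every
        class shifts the local peak amplitudes in a *distinct direction*
        — classes stay separable inside each characteristic band even
        under per-sample scaling.  Angles span a half-turn only, so no
        two classes are antipodal: sign-blind statistics (such as the
        synchronous correlation spectrum's outer-product structure)
        still distinguish every pair.
        """
        theta = np.pi * c / self.n_classes
        w = np.empty(len(self.peak_centers))
        for p in range(len(self.peak_centers)):
            pair, part = divmod(p, 2)
            phase = theta + pair * np.pi / 4.0
            w[p] = np.cos(phase) if part == 0 else np.sin(phase)
        return w

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["peak_centers"] = list(self.peak_centers)
        d["peak_amplitudes"] = list(self.peak_amplitudes)
        return d


def _peak_profiles(cfg: SimConfig) -> np.ndarray:
    """Unit-apex Gaussian per peak, shape (n_peaks, n_wavelengths)."""
    v = cfg.wavelengths
    sigma = cfg.peak_fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    centers = np.asarray(cfg.peak_centers)[:, None]
    return np.exp(-0.5 * ((v[None, :] - centers) / sigma) ** 2)


def mean_class_spectrum(cfg: SimConfig, c: int) -> np.ndarray:
    """Noise-free spectrum of class ``c``: baseline + class-shifted peak sum.

    This closed form is what a scatter-, drift- and noise-free simulation
    must reproduce exactly.
    """
    v = cfg.wavelengths
    v_norm = (v - cfg.wavelength_start) / (cfg.wavelength_stop - cfg.wavelength_start)
    baseline = 0.5 + 0.2 * v_norm
    amps = np.asarray(cfg.peak_amplitudes) + cfg.class_effect_size * cfg.class_pattern(c)
    return baseline + amps @ _peak_profiles(cfg)


def simulate_spectra(cfg: SimConfig) -> SpectrumSet:
    """Generate the full (sample, scan, wavelength) absorbance cube.

    Each scan is ``a_s * clean_class_spectrum + b_s + j * drift * S(v) +
    noise`` where ``(a_s, b_s)`` are the per-sample scatter slope/offset,
    ``j`` is the scan index and ``S(v)`` the unit-apex peak-shape sum
    (peaks grow linearly over the scan series, emulating temperature /
    evaporation drift during measurement).
    """
    rng = np.random.default_rng([cfg.seed, 0])
    v = cfg.wavelengths
    n_wl = v.size
    n_samples = cfg.n_classes * cfg.samples_per_class
    m = cfg.scans_per_sample

    drift_shape = _peak_profiles(cfg).sum(axis=0)
    apex = drift_shape.max()
    if apex > 0:
        drift_shape = drift_shape / apex

    absorbance = np.empty((n_samples, m, n_wl))
    sample_ids: list[str] = []
    labels: dict[str, str] = {}

    i = 0
    for c, cls in enumerate(cfg.class_names):
        clean = mean_class_spectrum(cfg, c)
        for s in range(cfg.samples_per_class):
            sid = f"{cls}_s{s:02d}"
            sample_ids.append(sid)
            labels[sid] = cls
            a = np.exp(rng.normal(0.0, cfg.scatter_slope_sd)) if cfg.scatter_slope_sd else 1.0
            b = rng.normal(0.0, cfg.scatter_offset_sd) if cfg.scatter_offset_sd else 0.0
            scans = a * clean[None, :] + b
            scans = scans + cfg.drift_per_scan * np.arange(m)[:, None] * drift_shape[None, :]
            if cfg.noise_sd:
                scans = scans + rng.normal(0.0, cfg.noise_sd, size=(m, n_wl))
            absorbance[i] = scans
            i += 1

    prov = (f"simulate_spectra(seed={cfg.seed}, classes={cfg.n_classes}, "
            f"per_class={cfg.samples_per_class}, scans={m})")
    return SpectrumSet(wavelengths=v, absorbance=absorbance,
                       sample_ids=sample_ids, labels=labels, provenance=prov)


def simulate_metabolites(
    cfg: SimConfig,
    differential: tuple[str, ...] | list[str] = DEFAULT_DIFFERENTIAL,
    compounds: tuple[str, ...] | list[str] = DEFAULT_COMPOUNDS,
) -> MetaboliteTable:
    """Peak-area table with class-dependent means for ``differential`` compounds.

    The i-th differential compound is elevated by ``cfg.metabolite_effect``
    in class ``i mod n_classes``; all other compound/class means are flat,
    so under ``differential=[]`` the table is an exact null.
    """
    unknown = [d for d in differential if d not in compounds]
    if unknown:
        raise ValueError(
            f"unknown differential compound(s) {unknown}; valid names: {list(compounds)}"
        )
    rng = np.random.default_rng([cfg.seed, 1])
    n_samples = cfg.n_classes * cfg.samples_per_class
    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    class_idx = np.empty(n_samples, dtype=int)
    i = 0
    for c, cls in enumerate(cfg.class_names):
        for s in range(cfg.samples_per_class):
            sid = f"{cls}_s{s:02d}"
            sample_ids.append(sid)
            labels[sid] = cls
            class_idx[i] = c
            i += 1

    areas = np.empty((len(compounds), n_samples))
    for k, comp in enumerate(compounds):
        base = _BASE_AREAS.get(comp, 75.0)
        mean = np.full(n_samples, base)
        if comp in differential:
            target = list(differential).index(comp) % cfg.n_classes
            mean = mean + np.where(class_idx == target, cfg.metabolite_effect, 0.0)
        areas[k] = mean + rng.normal(0.0, cfg.metabolite_sd, size=n_samples)
    areas = np.clip(areas, 0.0, None)

    return MetaboliteTable(
        compounds=list(compounds), areas=areas, sample_ids=sample_ids,
        labels=labels,
        provenance=f"simulate_metabolites(seed={cfg.seed}, differential={list(differential)})",
        differential_truth=list(differential),
    )


def write_fixture(spectra: SpectrumSet, table: MetaboliteTable, out_dir: str | Path,
                  cfg: SimConfig | None = None) -> dict:
    """Write spectra/labels/metabolite CSVs plus a JSON manifest; return the manifest."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        spectra.to_frame().to_csv(out / "spectra.csv", index=False)
        pd.DataFrame({
            "sample_id": spectra.sample_ids,
            "class": [spectra.labels[s] for s in spectra.sample_ids],
        }).to_csv(out / "labels.csv", index=False)
        table.to_frame().to_csv(out / "metabolites.csv", index=False)
        manifest = {
            "config": cfg.to_dict() if cfg is not None else None,
            "seed": cfg.seed if cfg is not None else None,
            "n_samples": spectra.n_samples,
            "n_scans": spectra.n_scans,
            "n_wavelengths": spectra.n_wavelengths,
            "files": ["spectra.csv", "labels.csv", "metabolites.csv"],
            "provenance": {"spectra": spectra.provenance,
                           "metabolites": table.provenance},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except OSError as exc:
        raise OSError(f"failed writing fixture under {out}: {exc}") from exc
    return manifest


def read_fixture(in_dir: str | Path) -> tuple[SpectrumSet, MetaboliteTable, dict]:
    """Read back what :func:`write_fixture` wrote (numeric round-trip exact)."""
    src = Path(in_dir)
    try:
        spectra_df = pd.read_csv(src / "spectra.csv")
        labels_df = pd.read_csv(src / "labels.csv")
        metab_df = pd.read_csv(src / "metabolites.csv")
        manifest = json.loads((src / "manifest.json").read_text())
    except OSError as exc:
        raise OSError(f"failed reading fixture under {src}: {exc}") from exc

    labels = dict(zip(labels_df["sample_id"], labels_df["class"]))
    wavelengths = spectra_df["wavelength_nm"].to_numpy()
    sample_ids = list(labels_df["sample_id"])
    scan_cols: dict[str, list[str]] = {}
    for col in spectra_df.columns:
        if col == "wavelength_nm":
            continue
        sid, _, _ = col.rpartition("__scan")
        scan_cols.setdefault(sid, []).append(col)
    n_scans = len(next(iter(scan_cols.values())))
    cube = np.empty((len(sample_ids), n_scans, wavelengths.size))
    for i, sid in enumerate(sample_ids):
        cols = sorted(scan_cols[sid], key=lambda c: int(c.rpartition("__scan")[2]))
        cube[i] = spectra_df[cols].to_numpy().T
    spectra = SpectrumSet(wavelengths=wavelengths, absorbance=cube,
                          sample_ids=sample_ids, labels=labels,
                          provenance=f"read_fixture({src})")

    compounds = list(metab_df["compound"])
    areas = metab_df[sample_ids].to_numpy()
    table = MetaboliteTable(compounds=compounds, areas=areas,
                            sample_ids=sample_ids, labels=labels,
                            provenance=f"read_fixture({src})")
    return spectra, table, manifest
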