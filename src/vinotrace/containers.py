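"""Core in-memory containers shared across the pipeline.

The pipeline's currency is the :class:`SpectrumSet`: a shared wavelength
grid, an absorbance cube indexed ``(sample, scan, wavelength)``, and a
class label per sample.  Repeated scans of the same sample form the
perturbation series that generalized 2D correlation analysis needs;
"time" (the scan index) is the perturbation variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SpectrumSet", "MetaboliteTable"]


class ConfigurationError(ValueError):
    """An invalid configuration field, named in the message."""


@dataclass
class SpectrumSet:
    """Absorbance spectra over (sample, scan) on one wavelength grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid, in nm, shape ``(n_wavelengths,)``.
    absorbance
        Cube of shape ``(n_samples, n_scans, n_wavelengths)``.
    sample_ids
        One id per sample, in cube order.
    labels
        Mapping ``sample_id -> class name``; must cover every sample.
    provenance
        Free-text generation/processing record, appended to by each stage.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: list[str]
    labels: dict[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be a 1-D grid")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.absorbance.ndim != 3:
            raise ValueError(
                "absorbance must have shape (n_samples, n_scans, n_wavelengths)"
            )
        n_samples, _, n_wl = self.absorbance.shape
        if n_wl != self.wavelengths.size:
            raise ValueError("absorbance last axis must match the wavelength grid")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids must match absorbance first axis")
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise ValueError(f"labels missing for samples: {missing[:5]}")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_scans(self) -> int:
        return self.absorbance.shape[1]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[2]

    @property
    def classes(self) -> list[str]:
        """Distinct class names in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.labels[s], None)
        return list(seen)

    def label_array(self) -> np.ndarray:
        """Class label per sample, aligned with the cube's first axis."""
        return np.array([self.labels[s] for s in self.sample_ids])

    def scan_mean(self) -> np.ndarray:
        """Per-sample mean over scans, shape ``(n_samples, n_wavelengths)``."""
        return self.absorbance.mean(axis=1)

    def with_absorbance(self, absorbance: np.ndarray, note: str = "") -> "SpectrumSet":
        """Copy with a new cube (same samples/labels), appending ``note``."""
        prov = self.provenance + ("\n" + note if note else "")
        return replace(self, absorbance=np.asarray(absorbance, dtype=float),
                       provenance=prov)

    def with_grid(self, wavelengths: np.ndarray, absorbance: np.ndarray,
                  note: str = "") -> "SpectrumSet":
        prov = self.provenance + ("\n" + note if note else "")
        return replace(self, wavelengths=np.asarray(wavelengths, dtype=float),
                       absorbance=np.asarray(absorbance, dtype=float),
                       provenance=prov)

    def to_frame(self) -> pd.DataFrame:
        """Wide table: `wavelength_nm` column then one `<sample>__scan<k>` per scan."""
        data = {"wavelength_nm": self.wavelengths}
        for i, sid in enumerate(self.sample_ids):
            for k in range(self.n_scans):
                data[f"{sid}__scan{k}"] = self.absorbance[i, k]
        return pd.DataFrame(data)


@dataclass
class MetaboliteTable:
    """Compound x sample peak areas with class labels (UPLC-Q-TOF-MS shape)."""

    compounds: list[str]
    areas: np.ndarray  # (n_compounds, n_samples), peak-area units, >= 0
    sample_ids: list[str]
    labels: dict[str, str]
    provenance: str = ""
    differential_truth: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (len(self.compounds), len(self.sample_ids)):
            raise ValueError("areas must be (n_compounds, n_samples)")
        if np.any(self.areas < 0):
            raise ValueError("peak areas must be non-negative")
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise ValueError(f"labels missing for samples: {missing[:5]}")

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.labels[s], None)
        return list(seen)

    def label_array(self) -> np.ndarray:
        return np.array([self.labels[s] for s in self.sample_ids])

    def to_frame(self) -> pd.DataFrame:
        """`compound` column then one column per sample id."""
        df = pd.DataFrame(self.areas, columns=self.sample_ids)
        df.insert(0, "compound", self.compounds)
        return df
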