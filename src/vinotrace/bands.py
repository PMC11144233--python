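"""Metabolomics-guided selection of NIR characteristic bands.

Differential compounds are screened from a peak-area table by Welch
t-tests, then mapped to near-infrared wavelength windows through a
compound -> window lookup that encodes which spectral region the
compound's functional groups absorb in (overtone/combination bands).
The shipped default lookup assigns indole and sulfacetamide to
1000-1400 nm and caffeine to 1500-1800 nm.

Screening design
----------------
The table has one group per production region, but a t-test is a
two-group statistic.  Each compound is therefore tested one-vs-rest:
every region against the pooled remaining regions (Welch, two-sided),
and the most extreme contrast (largest |t|) is reported.  Because the
reported contrast is selected from ``n_classes`` candidates, the raw
p-value of the winner is Sidak-adjusted, ``p = 1 - (1 - p_min)^K``,
which keeps the per-compound false-flag rate at the nominal alpha under
a null table.  With exactly two classes both contrasts coincide, so no
adjustment is applied and the result is the plain Welch test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MetaboliteTable, SpectrumSet

__all__ = [
    "TTestResult",
    "BandWindow",
    "CompoundWindowLookup",
    "DEFAULT_LOOKUP",
    "screen_metabolites",
    "map_to_windows",
    "cut_band",
]


@dataclass
class TTestResult:
    compound: str
    statistic: float
    p_value: float          # selection-adjusted; the value compared to alpha
    raw_p_value: float      # unadjusted Welch p of the selected contrast
    group_design: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class BandWindow:
    start_nm: float
    end_nm: float
    source_compounds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.start_nm < self.end_nm:
            raise ValueError("BandWindow requires start_nm < end_nm")

    @property
    def label(self) -> str:
        return f"{self.start_nm:g}-{self.end_nm:g}nm"


@dataclass
class CompoundWindowLookup:
    """Compound name -> (start_nm, end_nm) characteristic window."""

    mapping: dict[str, tuple[float, float]] = field(default_factory=dict)

    def window_for(self, compound: str) -> tuple[float, float] | None:
        return self.mapping.get(compound)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CompoundWindowLookup":
        df = pd.read_csv(path)
        required = {"compound", "start_nm", "end_nm"}
        if not required.issubset(df.columns):
            raise ValueError(f"lookup CSV needs columns {sorted(required)}")
        return cls({row.compound: (float(row.start_nm), float(row.end_nm))
                    for row in df.itertuples()})

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(c, s, e) for c, (s, e) in self.mapping.items()],
            columns=["compound", "start_nm", "end_nm"],
        ).to_csv(path, index=False)


#: Literature-derived functional-group window assignments for the default
#: compound panel (aromatic/amide C-H and N-H overtones vs. the
#: methylxanthine combination region).
DEFAULT_LOOKUP = CompoundWindowLookup({
    "Indole": (1000.0, 1400.0),
    "Sulfacetamide": (1000.0, 1400.0),
    "Caffeine": (1500.0, 1800.0),
})


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t; degenerate identical-value groups give t=0, p=1."""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        return np.inf * np.sign(a[0] - b[0]), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def screen_metabolites(table: MetaboliteTable, alpha: float = 0.05) -> list[TTestResult]:
    """Welch one-vs-rest screen of every compound; sorted by p-value.

    Compounds with adjusted ``p_value <= alpha`` are the differential
    set.  Raises if any class has fewer than two samples.
    """
    labels = table.label_array()
    classes = table.classes
    for cls in classes:
        if int((labels == cls).sum()) < 2:
            raise ValueError(f"class '{cls}' has fewer than 2 samples")
    n_contrasts = len(classes) if len(classes) > 2 else 1

    results: list[TTestResult] = []
    for k, comp in enumerate(table.compounds):
        areas = table.areas[k]
        best: tuple[float, float, str] | None = None
        for cls in classes:
            mask = labels == cls
            t, p = _welch(areas[mask], areas[~mask])
            if best is None or abs(t) > abs(best[0]):
                best = (t, p, cls)
        t, raw_p, cls = best
        adj_p = float(-np.expm1(n_contrasts * np.log1p(-min(raw_p, 1.0)))) \
            if raw_p < 1.0 else 1.0
        adj_p = min(max(adj_p, 0.0), 1.0)
        design = (f"Welch two-sided, {cls} vs rest (most extreme of "
                  f"{len(classes)} one-vs-rest contrasts, Sidak x{n_contrasts})")
        results.append(TTestResult(compound=comp, statistic=t, p_value=adj_p,
                                   raw_p_value=raw_p, group_design=design))
    results.sort(key=lambda r: (r.p_value, r.compound))
    return results


class WindowSelection(list):
    """List of :class:`BandWindow` plus the compounds no window was known for."""

    def __init__(self, windows: list[BandWindow], unmapped: list[str]):
        super().__init__(windows)
        self.unmapped = list(unmapped)


def map_to_windows(
    results: list[TTestResult],
    lookup: CompoundWindowLookup = DEFAULT_LOOKUP,
    alpha: float = 0.05,
) -> WindowSelection:
    """Windows of all differential compounds, merged and sorted by start.

    Identical windows are merged (their source compounds pooled);
    flagged compounds absent from the lookup are warned about and listed
    in ``.unmapped`` rather than silently dropped.
    """
    flagged = [r.compound for r in results if r.p_value <= alpha]
    grouped: dict[tuple[float, float], list[str]] = {}
    unmapped: list[str] = []
    for comp in flagged:
        win = lookup.window_for(comp)
        if win is None:
            unmapped.append(comp)
            continue
        grouped.setdefault(win, [])
        if comp not in grouped[win]:
            grouped[win].append(comp)
    if unmapped:
        warnings.warn(
            f"no characteristic window known for flagged compound(s): {unmapped}",
            stacklevel=2,
        )
    windows = [
        BandWindow(start_nm=s, end_nm=e, source_compounds=tuple(sorted(comps)))
        for (s, e), comps in grouped.items()
    ]
    windows.sort(key=lambda w: (w.start_nm, w.end_nm))
    return WindowSelection(windows, unmapped)


def cut_band(spectra: SpectrumSet, window: BandWindow) -> SpectrumSet:
    """Restrict the grid to ``start_nm <= v <= end_nm`` (closed interval)."""
    mask = (spectra.wavelengths >= window.start_nm) & (spectra.wavelengths <= window.end_nm)
    if not mask.any():
        raise ValueError(
            f"window {window.label} does not intersect the grid "
            f"[{spectra.wavelengths[0]:g}, {spectra.wavelengths[-1]:g}] nm"
        )
    return spectra.with_grid(
        spectra.wavelengths[mask], spectra.absorbance[:, :, mask],
        note=f"cut_band({window.label})",
    )
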