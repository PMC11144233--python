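"""One-command orchestration: simulate -> preprocess -> bands -> 2D-COS -> classify.

A run is a pure function of (config, seed): every stage reads only the
previous stages' artifacts inside one run directory, all randomness is
seeded from the config, and re-running with the same config reproduces
every numeric output.  The resolved config, a manifest and a log are
written alongside the artifacts for inspectability.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bands import (CompoundWindowLookup, DEFAULT_LOOKUP, cut_band,
                    map_to_windows, screen_metabolites)
from .classify import (SplitPlan, band_feature_matrix, evaluate,
                       load_images_from_manifest)
from .cnn import CNNConfig
from .containers import SpectrumSet
from .preprocess import PreprocessConfig, preprocess_chain
from .synthetic import SimConfig, read_fixture, simulate_metabolites, \
    simulate_spectra, write_fixture
from .twodcos import RenderConfig, batch_cos

__all__ = ["RunConfig", "validate_config", "run_all"]

log = logging.getLogger("vinotrace")


@dataclass
class RunConfig:
    """Nested configuration for a full pipeline run."""

    out_root: str = "runs/run"
    seed: int = 0
    alpha: float = 0.05
    lookup_csv: str | None = None          # None -> shipped default lookup
    steps: dict = field(default_factory=lambda: {
        "simulate": True, "preprocess": True, "bands": True,
        "cos": True, "classify": True,
    })
    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    split: SplitPlan = field(default_factory=SplitPlan)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    image_types: tuple[str, ...] = ("sync", "async")
    reference_mode: str = "grand_mean"

    def __post_init__(self) -> None:
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        steps = {"simulate": True, "preprocess": True, "bands": True,
                 "cos": True, "classify": True}
        steps.update(self.steps)
        self.steps = steps

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (("sim", SimConfig), ("preprocess", PreprocessConfig),
                         ("render", RenderConfig), ("split", SplitPlan),
                         ("cnn", CNNConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        if "image_types" in kwargs:
            kwargs["image_types"] = tuple(kwargs["image_types"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["image_types"] = list(self.image_types)
        return d


def validate_config(cfg: RunConfig) -> list[dict]:
    """Schema and cross-field checks; returns machine-readable findings."""
    findings: list[dict] = []

    def finding(fld: str, rule: str, message: str) -> None:
        findings.append({"field": fld, "rule": rule, "message": message})

    if cfg.sim.n_classes < 2:
        finding("sim.n_classes", "min", "need at least 2 classes")
    if cfg.sim.scans_per_sample < 2:
        finding("sim.scans_per_sample", "min", "need at least 2 scans per sample")
    if cfg.preprocess.sg_window % 2 == 0:
        finding("preprocess.sg_window", "odd", "S-G window must be odd")
    if cfg.preprocess.sg_window <= cfg.preprocess.sg_polyorder:
        finding("preprocess.sg_window", "gt_polyorder",
                "S-G window must exceed the polynomial order")
    grid = cfg.sim.wavelengths
    if cfg.preprocess.sg_window > grid.size:
        finding("preprocess.sg_window", "le_grid",
                "S-G window exceeds the wavelength grid length")
    if not 0 < cfg.alpha < 1:
        finding("alpha", "range", "alpha must lie in (0, 1)")
    lookup = _load_lookup(cfg)
    for comp, (start, end) in lookup.mapping.items():
        if start >= end:
            finding(f"lookup[{comp}]", "order", "window start must precede end")
        if end < grid[0] or start > grid[-1]:
            finding(f"lookup[{comp}]", "within_grid",
                    f"window {start:g}-{end:g} nm lies outside the grid "
                    f"{grid[0]:g}-{grid[-1]:g} nm")
    if cfg.split.train_fraction <= 0 or cfg.split.train_fraction >= 1:
        finding("split.train_fraction", "range", "must lie in (0, 1)")
    min_class = cfg.sim.samples_per_class
    if cfg.steps.get("classify") and min_class < 3:
        finding("sim.samples_per_class", "min_split",
                "classification needs >= 3 samples per class to split")
    bad_types = [t for t in cfg.image_types if t not in ("sync", "async")]
    if bad_types:
        finding("image_types", "enum", f"unknown image types {bad_types}")
    return findings


def _load_lookup(cfg: RunConfig) -> CompoundWindowLookup:
    if cfg.lookup_csv:
        return CompoundWindowLookup.from_csv(cfg.lookup_csv)
    return DEFAULT_LOOKUP


def _setup_logging(run_dir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(run_dir / "run.log")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def run_all(cfg: RunConfig) -> Path:
    """Execute the enabled stages in order; return the run directory."""
    findings = validate_config(cfg)
    if findings:
        raise ValueError(f"invalid config: {findings}")
    run_dir = Path(cfg.out_root)
    run_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(run_dir)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))

    spectra = table = None
    stage_t0 = time.time()

    def _fail(stage: str, exc: Exception) -> None:
        raise RuntimeError(
            f"pipeline stage '{stage}' failed (artifacts under {run_dir}): {exc}"
        ) from exc

    if cfg.steps.get("simulate", True):
        log.info("stage simulate: %d classes x %d samples x %d scans",
                 cfg.sim.n_classes, cfg.sim.samples_per_class,
                 cfg.sim.scans_per_sample)
        try:
            spectra = simulate_spectra(cfg.sim)
            table = simulate_metabolites(cfg.sim)
            write_fixture(spectra, table, run_dir / "fixture", cfg.sim)
        except Exception as exc:
            _fail("simulate", exc)

    preprocessed = None
    if cfg.steps.get("preprocess", True):
        if spectra is None:
            spectra, table, _ = read_fixture(run_dir / "fixture")
        log.info("stage preprocess: MSC + S-G(%d,%d) + FD",
                 cfg.preprocess.sg_window, cfg.preprocess.sg_polyorder)
        try:
            preprocessed, reference = preprocess_chain(spectra, cfg.preprocess)
            pdir = run_dir / "preprocess"
            pdir.mkdir(exist_ok=True)
            preprocessed.to_frame().to_csv(pdir / "spectra.csv", index=False)
            np.savetxt(pdir / "msc_reference.csv", reference, delimiter=",")
        except Exception as exc:
            _fail("preprocess", exc)

    windows = None
    if cfg.steps.get("bands", True):
        if table is None:
            _, table, _ = read_fixture(run_dir / "fixture")
        log.info("stage bands: Welch screen at alpha=%g", cfg.alpha)
        try:
            results = screen_metabolites(table, alpha=cfg.alpha)
            windows = map_to_windows(results, _load_lookup(cfg), alpha=cfg.alpha)
            bdir = run_dir / "bands"
            bdir.mkdir(exist_ok=True)
            pd.DataFrame([{
                "compound": r.compound, "statistic": r.statistic,
                "p_value": r.p_value, "raw_p_value": r.raw_p_value,
                "group_design": r.group_design,
                "flagged": r.p_value <= cfg.alpha,
            } for r in results]).to_csv(bdir / "screen.csv", index=False)
            pd.DataFrame([{
                "start_nm": w.start_nm, "end_nm": w.end_nm,
                "source_compounds": ";".join(w.source_compounds),
            } for w in windows]).to_csv(bdir / "windows.csv", index=False)
            if windows.unmapped:
                log.warning("unmapped flagged compounds: %s", windows.unmapped)
        except Exception as exc:
            _fail("bands", exc)

    manifest = None
    if cfg.steps.get("cos", True):
        if preprocessed is None or windows is None:
            raise RuntimeError("cos stage needs the preprocess and bands stages")
        log.info("stage cos: %d samples x %d windows x %s",
                 preprocessed.n_samples, len(windows), list(cfg.image_types))
        try:
            _, manifest = batch_cos(preprocessed, list(windows),
                                    types=cfg.image_types,
                                    render_cfg=cfg.render,
                                    out_dir=run_dir / "cos",
                                    reference_mode=cfg.reference_mode)
            log.info("wrote %d images", len(manifest))
        except Exception as exc:
            _fail("cos", exc)

    if cfg.steps.get("classify", True):
        if preprocessed is None or windows is None or manifest is None:
            raise RuntimeError("classify stage needs preprocess, bands and cos")
        log.info("stage classify: %d repeats", cfg.split.n_repeats)
        try:
            band_features = {
                w.label: band_feature_matrix(preprocessed, w) for w in windows
            }
            image_cells = load_images_from_manifest(manifest)
            report = evaluate(preprocessed.labels, cfg.split,
                              band_features=band_features,
                              image_cells=image_cells, cnn_cfg=cfg.cnn)
            rdir = run_dir / "report"
            rdir.mkdir(exist_ok=True)
            report.to_frame().to_csv(rdir / "report.csv", index=False)
            report.per_repeat_frame().to_csv(rdir / "per_repeat.csv", index=False)
            (rdir / "report.json").write_text(json.dumps({
                f"{m}|{b}|{p}": float(a.mean())
                for (m, b, p), a in sorted(report.per_repeat.items())
            }, indent=2))
            log.info("report:\n%s", report.table().to_string())
        except Exception as exc:
            _fail("classify", exc)

    log.info("run complete in %.1f s: %s", time.time() - stage_t0, run_dir)
    return run_dir
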