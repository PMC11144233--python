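"""Origin classification: CNN on 2D-COS images, LDA/SVM on 1-D band spectra.

The evaluation protocol mirrors a repeated random-split design: samples
are stratified-split 2/3 train / 1/3 test many times (default 50), each
model is refit per split, and the grid of mean train/test accuracies
over ``model x band x partition`` is reported, with the per-repeat
accuracies retained.

Splitting is done at the *sample* level: all images derived from one
sample (synchronous/asynchronous, any band) land on the same side of
every split, so no sample leaks between train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC

from .bands import BandWindow, cut_band
from .cnn import CNNClassifier, CNNConfig
from .containers import SpectrumSet
from .twodcos import COSImage

__all__ = [
    "SplitPlan",
    "RunReport",
    "make_splits",
    "train_baseline",
    "train_cnn",
    "band_feature_matrix",
    "images_by_cell",
    "load_images_from_manifest",
    "evaluate",
]

BASELINE_MODELS = ("LDA", "SVM")
CNN_MODELS = ("sync+CNN", "async+CNN")


@dataclass
class SplitPlan:
    n_repeats: int = 50
    train_fraction: float = 2.0 / 3.0
    stratified: bool = True
    seeds: list[int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.seeds is None:
            self.seeds = list(range(self.n_repeats))
        if len(self.seeds) != self.n_repeats:
            raise ValueError("need exactly one seed per repeat")


def make_splits(
    sample_ids: list[str], labels: dict[str, str], plan: SplitPlan
) -> list[tuple[list[str], list[str]]]:
    """Seeded stratified sample-level splits; train/test disjoint, exhaustive."""
    by_class: dict[str, list[str]] = {}
    for sid in sample_ids:
        by_class.setdefault(labels[sid], []).append(sid)
    for cls, members in by_class.items():
        if len(members) < 3:
            raise ValueError(f"class '{cls}' has fewer than 3 samples; "
                             "cannot stratify a 2/3-1/3 split")
    splits = []
    for seed in plan.seeds:
        rng = np.random.default_rng(seed)
        train: list[str] = []
        test: list[str] = []
        if plan.stratified:
            for cls in sorted(by_class):
                members = list(by_class[cls])
                order = rng.permutation(len(members))
                n_train = int(round(plan.train_fraction * len(members)))
                n_train = min(max(n_train, 1), len(members) - 1)
                train.extend(members[i] for i in order[:n_train])
                test.extend(members[i] for i in order[n_train:])
        else:
            order = rng.permutation(len(sample_ids))
            n_train = int(round(plan.train_fraction * len(sample_ids)))
            n_train = min(max(n_train, 1), len(sample_ids) - 1)
            train = [sample_ids[i] for i in order[:n_train]]
            test = [sample_ids[i] for i in order[n_train:]]
        splits.append((sorted(train), sorted(test)))
    return splits


def train_baseline(X: np.ndarray, y: np.ndarray, model: str):
    """Fit an LDA (shrinkage fallback when scatter is singular) or RBF SVM."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("baseline needs a (n_samples, n_features>=1) matrix")
    if model == "LDA":
        if X.shape[1] >= X.shape[0]:
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        else:
            clf = LinearDiscriminantAnalysis(solver="svd")
        try:
            return clf.fit(X, y)
        except np.linalg.LinAlgError:
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto").fit(X, y)
    if model == "SVM":
        return SVC(kernel="rbf", C=1.0, gamma="scale").fit(X, y)
    raise ValueError(f"unknown baseline model '{model}' (use 'LDA' or 'SVM')")


def train_cnn(X: np.ndarray, y: np.ndarray, cfg: CNNConfig) -> CNNClassifier:
    """Fit the numpy CNN on images ``X`` (N, H, W[, C])."""
    return CNNClassifier(cfg).fit(X, y)


def band_feature_matrix(preprocessed: SpectrumSet, window: BandWindow
                        ) -> tuple[list[str], np.ndarray]:
    """1-D baseline features: band-cut, per-sample scan-mean spectra."""
    band = cut_band(preprocessed, window)
    return list(band.sample_ids), band.scan_mean()


def images_by_cell(images: list[COSImage]) -> dict[tuple[str, str], tuple[list[str], np.ndarray]]:
    """Group in-memory contour images into (window, type) cells.

    Returns ``{(window_label, kind): (sample_ids, X)}`` with ``X`` scaled
    to float32 in [0, 1], shape (n, H, W, 3).
    """
    cells: dict[tuple[str, str], tuple[list[str], list[np.ndarray]]] = {}
    for img in images:
        key = (img.meta["window"], img.meta["type"])
        ids, stack = cells.setdefault(key, ([], []))
        ids.append(img.meta["sample_id"])
        stack.append(img.pixels)
    return {key: (ids, np.asarray(stack, dtype=np.float32) / 255.0)
            for key, (ids, stack) in cells.items()}


def load_images_from_manifest(manifest: pd.DataFrame
                              ) -> dict[tuple[str, str], tuple[list[str], np.ndarray]]:
    """Load the PNGs a batch-generation manifest points to, grouped by cell."""
    images = []
    for row in manifest.itertuples():
        img = COSImage.load(row.path)
        img.meta.update({"sample_id": row.sample_id, "window": row.window,
                         "type": row.type})
        images.append(img)
    return images_by_cell(images)


@dataclass
class RunReport:
    """Mean-accuracy grid over repeats, with per-repeat values retained."""

    per_repeat: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)
    n_repeats: int = 0

    def add(self, model: str, band: str, partition: str, accs: np.ndarray) -> None:
        accs = np.asarray(accs, dtype=float)
        if np.any((accs < 0) | (accs > 1)):
            raise ValueError("accuracies must lie in [0, 1]")
        self.per_repeat[(model, band, partition)] = accs

    def mean(self, model: str, band: str, partition: str) -> float:
        return float(self.per_repeat[(model, band, partition)].mean())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"model": m, "band": b, "partition": p,
             "mean_accuracy": float(a.mean()), "n_repeats": a.size}
            for (m, b, p), a in sorted(self.per_repeat.items())
        ]
        return pd.DataFrame(rows)

    def table(self) -> pd.DataFrame:
        """Accuracy grid shaped like the study's summary table:
        rows (partition, band), one column per model."""
        df = self.to_frame()
        return df.pivot_table(index=["partition", "band"], columns="model",
                              values="mean_accuracy")

    def per_repeat_frame(self) -> pd.DataFrame:
        rows = []
        for (m, b, p), accs in sorted(self.per_repeat.items()):
            for i, a in enumerate(accs):
                rows.append({"model": m, "band": b, "partition": p,
                             "repeat": i, "accuracy": float(a)})
        return pd.DataFrame(rows)


def evaluate(
    labels: dict[str, str],
    plan: SplitPlan,
    band_features: dict[str, tuple[list[str], np.ndarray]] | None = None,
    image_cells: dict[tuple[str, str], tuple[list[str], np.ndarray]] | None = None,
    cnn_cfg: CNNConfig | None = None,
    baseline_models: tuple[str, ...] = BASELINE_MODELS,
) -> RunReport:
    """Repeated-split evaluation of every model x band cell.

    ``band_features`` feeds the LDA/SVM baselines (one entry per band);
    ``image_cells`` feeds the CNNs (one entry per (band, sync/async)
    cell).  All cells share the same sample-level splits per repeat.
    """
    band_features = band_features or {}
    image_cells = image_cells or {}
    if not band_features and not image_cells:
        raise ValueError("evaluate needs band_features and/or image_cells")
    cnn_cfg = cnn_cfg or CNNConfig()

    sample_ids = None
    for ids, _ in list(band_features.values()) + list(image_cells.values()):
        if sample_ids is None:
            sample_ids = list(ids)
        elif set(ids) != set(sample_ids):
            raise ValueError("inconsistent sample ids across cells")
    missing = [s for s in sample_ids if s not in labels]
    if missing:
        raise ValueError(f"labels missing for samples: {missing[:5]}")

    splits = make_splits(sample_ids, labels, plan)
    y_of = {sid: labels[sid] for sid in sample_ids}

    def rows_for(ids_in_cell: list[str], wanted: list[str]) -> np.ndarray:
        index = {sid: i for i, sid in enumerate(ids_in_cell)}
        return np.array([index[s] for s in wanted])

    report = RunReport(n_repeats=plan.n_repeats)
    acc: dict[tuple[str, str, str], list[float]] = {}

    for rep, (train_ids, test_ids) in enumerate(splits):
        y_train = np.array([y_of[s] for s in train_ids])
        y_test = np.array([y_of[s] for s in test_ids])
        for band, (ids, X) in band_features.items():
            tr, te = rows_for(ids, train_ids), rows_for(ids, test_ids)
            for model in baseline_models:
                clf = train_baseline(X[tr], y_train, model)
                acc.setdefault((model, band, "train"), []).append(
                    float(np.mean(clf.predict(X[tr]) == y_train)))
                acc.setdefault((model, band, "test"), []).append(
                    float(np.mean(clf.predict(X[te]) == y_test)))
        for (band, kind), (ids, X) in image_cells.items():
            tr, te = rows_for(ids, train_ids), rows_for(ids, test_ids)
            model = f"{kind}+CNN"
            cfg = CNNConfig(**{**cnn_cfg.__dict__,
                               "seed": (cnn_cfg.seed * 100003 + plan.seeds[rep])
                                       % 2**31})
            clf = train_cnn(X[tr], y_train, cfg)
            acc.setdefault((model, band, "train"), []).append(clf.score(X[tr], y_train))
            acc.setdefault((model, band, "test"), []).append(clf.score(X[te], y_test))

    for key, values in acc.items():
        report.add(*key, np.array(values))
    return report
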