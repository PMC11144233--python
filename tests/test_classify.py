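"""Split protocol, baselines, and the repeated-split evaluation grid."""

import numpy as np
import pytest

from vinotrace import (CNNConfig, RunReport, SimConfig, SplitPlan,
                       band_feature_matrix, evaluate, make_splits,
                       preprocess_chain, simulate_spectra, train_baseline)
from vinotrace.bands import BandWindow


@pytest.fixture(scope="module")
def small_study():
    cfg = SimConfig(n_classes=3, samples_per_class=6, scans_per_sample=6,
                    wavelength_step=12.8, seed=11)
    spectra = simulate_spectra(cfg)
    pre, _ = preprocess_chain(spectra)
    return cfg, spectra, pre


class TestMakeSplits:
    def test_study_split_sizes(self, study_spectra):
        """180 samples split 2/3-1/3: 120 train / 60 test samples, hence
        480 train / 240 test images when each sample has 4 images."""
        plan = SplitPlan(n_repeats=3)
        splits = make_splits(study_spectra.sample_ids, study_spectra.labels,
                             plan)
        images_per_sample = 4  # 2 windows x {sync, async}
        for train, test in splits:
            assert (len(train), len(test)) == (120, 60)
            assert (len(train) * images_per_sample,
                    len(test) * images_per_sample) == (480, 240)

    def test_stratified_exactly_per_class(self, study_spectra):
        plan = SplitPlan(n_repeats=1)
        [(train, test)] = make_splits(study_spectra.sample_ids,
                                      study_spectra.labels, plan)
        for cls in set(study_spectra.labels.values()):
            n_train = sum(study_spectra.labels[s] == cls for s in train)
            n_test = sum(study_spectra.labels[s] == cls for s in test)
            assert (n_train, n_test) == (20, 10)

    def test_disjoint_and_exhaustive(self, study_spectra):
        plan = SplitPlan(n_repeats=2)
        for train, test in make_splits(study_spectra.sample_ids,
                                       study_spectra.labels, plan):
            assert not set(train) & set(test)
            assert set(train) | set(test) == set(study_spectra.sample_ids)

    def test_same_seed_same_split(self, study_spectra):
        plan = SplitPlan(n_repeats=1, seeds=[42])
        a = make_splits(study_spectra.sample_ids, study_spectra.labels, plan)
        b = make_splits(study_spectra.sample_ids, study_spectra.labels, plan)
        assert a == b

    def test_small_class_rejected(self):
        labels = {"a": "x", "b": "x", "c": "x", "d": "y", "e": "y"}
        with pytest.raises(ValueError, match="y"):
            make_splits(list(labels), labels, SplitPlan(n_repeats=1))


class TestBaselines:
    def test_lda_separates_linear_toy(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(20, 3)),
                       rng.normal(3, 0.1, size=(20, 3))])
        y = np.array(["a"] * 20 + ["b"] * 20)
        clf = train_baseline(X, y, "LDA")
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_lda_deterministic(self, rng):
        X = rng.normal(size=(30, 5))
        y = np.array(["a", "b", "c"] * 10)
        p1 = train_baseline(X, y, "LDA").predict(X)
        p2 = train_baseline(X, y, "LDA").predict(X)
        assert np.array_equal(p1, p2)

    def test_shrinkage_path_when_features_exceed_samples(self, rng):
        X = rng.normal(size=(10, 40))
        y = np.array(["a", "b"] * 5)
        clf = train_baseline(X, y, "LDA")
        assert clf.predict(X).shape == (10,)

    def test_permuted_labels_give_chance_accuracy(self, small_study):
        """Under label permutation the baselines must fall to ~1/n_classes."""
        cfg, spectra, pre = small_study
        ids, X = band_feature_matrix(pre, BandWindow(1000.0, 1400.0))
        rng = np.random.default_rng(0)
        perm_labels = dict(zip(ids, rng.permutation(
            [spectra.labels[s] for s in ids])))
        plan = SplitPlan(n_repeats=10)
        report = evaluate(perm_labels, plan,
                          band_features={"band": (ids, X)})
        chance = 1.0 / cfg.n_classes
        n_test = 10 * (cfg.samples_per_class // 3) * cfg.n_classes
        sd = np.sqrt(chance * (1 - chance) / n_test)
        for model in ("LDA", "SVM"):
            assert abs(report.mean(model, "band", "test") - chance) < 4 * sd

    def test_zero_class_effect_gives_chance_accuracy(self):
        """With class_effect_size = 0 the labels carry no information and
        the baselines must hover near 1/n_classes."""
        cfg = SimConfig(n_classes=3, samples_per_class=8, scans_per_sample=5,
                        wavelength_step=12.8, class_effect_size=0.0, seed=21)
        spectra = simulate_spectra(cfg)
        pre, _ = preprocess_chain(spectra)
        ids, X = band_feature_matrix(pre, BandWindow(1000.0, 1400.0))
        report = evaluate(spectra.labels, SplitPlan(n_repeats=10),
                          band_features={"band": (ids, X)})
        chance = 1.0 / 3.0
        n_test = 10 * 2 * 3   # repeats x test-per-class x classes
        sd = np.sqrt(chance * (1 - chance) / n_test)
        for model in ("LDA", "SVM"):
            assert abs(report.mean(model, "band", "test") - chance) < 4 * sd

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="feature"):
            train_baseline(np.zeros((4, 0)), np.array(list("abab")), "LDA")
        with pytest.raises(ValueError, match="unknown"):
            train_baseline(rng.normal(size=(4, 2)), np.array(list("abab")),
                           "forest")


class TestEvaluate:
    def test_full_grid_shape_and_mean_consistency(self, small_study):
        from vinotrace import batch_cos, images_by_cell, map_to_windows, \
            screen_metabolites, simulate_metabolites
        from vinotrace.twodcos import RenderConfig
        cfg, spectra, pre = small_study
        windows = [BandWindow(1000.0, 1400.0), BandWindow(1500.0, 1800.0)]
        images, _ = batch_cos(pre, windows, render_cfg=RenderConfig(size=32))
        cells = images_by_cell(images)
        band_features = {w.label: band_feature_matrix(pre, w) for w in windows}
        plan = SplitPlan(n_repeats=2)
        cnn_cfg = CNNConfig(conv_channels=(4, 8), dense_widths=(16,),
                            n_classes=cfg.n_classes, epochs=2, seed=0)
        report = evaluate(spectra.labels, plan, band_features=band_features,
                          image_cells=cells, cnn_cfg=cnn_cfg)
        frame = report.to_frame()
        assert set(frame["model"]) == {"LDA", "SVM", "sync+CNN", "async+CNN"}
        assert set(frame["band"]) == {"1000-1400nm", "1500-1800nm"}
        assert set(frame["partition"]) == {"train", "test"}
        assert len(frame) == 4 * 2 * 2
        assert frame["mean_accuracy"].between(0, 1).all()
        # mean column equals the mean of the retained per-repeat values
        for (m, b, p), accs in report.per_repeat.items():
            assert report.mean(m, b, p) == pytest.approx(accs.mean(), abs=1e-12)
        table = report.table()
        assert table.shape == (4, 4)

    def test_inconsistent_sample_ids_rejected(self, rng):
        feats_a = (["s1", "s2"], rng.normal(size=(2, 3)))
        feats_b = (["s1", "s3"], rng.normal(size=(2, 3)))
        with pytest.raises(ValueError, match="inconsistent"):
            evaluate({"s1": "a", "s2": "b", "s3": "b"}, SplitPlan(n_repeats=1),
                     band_features={"x": feats_a, "y": feats_b})

    def test_no_inputs_rejected(self):
        with pytest.raises(ValueError, match="needs"):
            evaluate({}, SplitPlan(n_repeats=1))


class TestRepeatStability:
    def test_cell_means_agree_across_repeat_counts(self, small_study):
        """Fewer repeats only widen the uncertainty: cell means at 20 and 5
        repeats agree within their combined confidence intervals."""
        cfg, spectra, pre = small_study
        ids, X = band_feature_matrix(pre, BandWindow(1000.0, 1400.0))
        feats = {"band": (ids, X)}
        wide = evaluate(spectra.labels, SplitPlan(n_repeats=20),
                        band_features=feats)
        narrow = evaluate(spectra.labels, SplitPlan(n_repeats=5),
                          band_features=feats)
        for model in ("LDA", "SVM"):
            a = wide.per_repeat[(model, "band", "test")]
            b = narrow.per_repeat[(model, "band", "test")]
            margin = 2 * np.sqrt(a.var(ddof=1) / a.size +
                                 b.var(ddof=1) / b.size) + 1e-9
            assert abs(a.mean() - b.mean()) <= margin


class TestRunReport:
    def test_accuracy_bounds_enforced(self):
        report = RunReport()
        with pytest.raises(ValueError):
            report.add("LDA", "b", "test", np.array([0.5, 1.2]))
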