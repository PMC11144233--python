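import numpy as np
import pytest

from vinotrace import (SimConfig, SplitPlan, batch_cos, images_by_cell,
                       map_to_windows, preprocess_chain, screen_metabolites,
                       simulate_metabolites, simulate_spectra)


@pytest.fixture
def tiny_cfg():
    """Small, fast study: 3 classes x 4 samples x 6 scans on a coarse grid."""
    return SimConfig(n_classes=3, samples_per_class=4, scans_per_sample=6,
                     wavelength_step=12.8, seed=7)


@pytest.fixture(scope="session")
def study_cfg():
    """The full default study design: 6 classes x 30 samples x 10 scans."""
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def study_spectra(study_cfg):
    return simulate_spectra(study_cfg)


@pytest.fixture(scope="session")
def study_preprocessed(study_spectra):
    out, _ = preprocess_chain(study_spectra)
    return out


@pytest.fixture(scope="session")
def study_windows(study_cfg):
    table = simulate_metabolites(study_cfg)
    return map_to_windows(screen_metabolites(table))


@pytest.fixture(scope="session")
def study_images(study_preprocessed, study_windows):
    """All 2D-COS contour images of the default study plus their manifest."""
    images, manifest = batch_cos(study_preprocessed, list(study_windows))
    return images, manifest


@pytest.fixture(scope="session")
def study_cells(study_images):
    return images_by_cell(study_images[0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
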