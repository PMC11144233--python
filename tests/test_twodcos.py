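"""2D-COS mathematics: Noda matrix, sync/async spectra, Fourier oracle, rendering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vinotrace import (BandWindow, RenderConfig, SimConfig, async_spectrum,
                       batch_cos, dynamic_spectrum, fourier_oracle,
                       hilbert_noda, preprocess_chain, render_contour,
                       simulate_spectra, sync_spectrum)
from vinotrace.twodcos import DynamicSpectrum


def _dyn(y):
    y = np.asarray(y, dtype=float)
    return DynamicSpectrum(wavelengths=np.arange(y.shape[0], dtype=float),
                           y=y, reference=np.zeros(y.shape[0]))


def _naive_pair(y):
    """Brute-force double/triple loop evaluation of the defining sums."""
    n, m = y.shape
    M = hilbert_noda(m)
    sync = np.zeros((n, n))
    asyn = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            sync[a, b] = sum(y[a, j] * y[b, j] for j in range(m)) / (m - 1)
            asyn[a, b] = sum(
                y[a, j] * sum(M[j, k] * y[b, k] for k in range(m))
                for j in range(m)) / (m - 1)
    return sync, asyn


class TestHilbertNoda:
    def test_elementwise_construction(self):
        M = hilbert_noda(4)
        assert np.all(np.diag(M) == 0.0)
        assert M[0, 1] == pytest.approx(1 / np.pi)
        assert M[0, 1] == pytest.approx(0.318310, abs=1e-6)
        assert M[1, 0] == pytest.approx(-1 / np.pi)
        assert M[0, 3] == pytest.approx(1 / (3 * np.pi))

    def test_exactly_antisymmetric(self):
        M = hilbert_noda(9)
        assert np.all(M + M.T == 0.0)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            hilbert_noda(0)


class TestSyncSpectrum:
    def test_hand_example_two_points(self):
        d = _dyn([[1.0, -1.0], [1.0, -1.0]])
        phi = sync_spectrum(d)
        assert phi[0, 1] == pytest.approx(2.0)
        assert phi[0, 0] == pytest.approx(2.0)

    @pytest.mark.parametrize("n,m,seed", [(4, 5, 0), (8, 10, 1), (3, 7, 2),
                                          (6, 4, 3)])
    def test_matches_naive_double_sum(self, n, m, seed):
        y = np.random.default_rng(seed).normal(size=(n, m))
        d = _dyn(y)
        sync_naive, async_naive = _naive_pair(y)
        assert np.abs(sync_spectrum(d) - sync_naive).max() < 1e-10
        assert np.abs(async_spectrum(d) - async_naive).max() < 1e-10

    def test_symmetric_and_psd(self, rng):
        y = rng.normal(size=(6, 9))
        phi = sync_spectrum(_dyn(y))
        assert np.abs(phi - phi.T).max() < 1e-12
        assert np.linalg.eigvalsh(phi).min() > -1e-10

    def test_diagonal_is_perturbation_variance(self, rng):
        y = rng.normal(size=(5, 8))
        phi = sync_spectrum(_dyn(y))
        expected = (y**2).sum(axis=1) / 7
        assert np.abs(np.diag(phi) - expected).max() < 1e-12
        assert np.diag(phi).min() >= 0.0


class TestAsyncSpectrum:
    def test_antisymmetric_with_zero_diagonal(self, rng):
        y = rng.normal(size=(7, 11))
        psi = async_spectrum(_dyn(y))
        assert np.abs(psi + psi.T).max() < 1e-12
        assert np.abs(np.diag(psi)).max() < 1e-12

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(c=st.floats(-5.0, 5.0), seed=st.integers(0, 100))
    def test_scaling_scans_scales_quadratically(self, c, seed):
        y = np.random.default_rng(seed).normal(size=(4, 6))
        base_phi = sync_spectrum(_dyn(y))
        base_psi = async_spectrum(_dyn(y))
        assert np.abs(sync_spectrum(_dyn(c * y)) - c**2 * base_phi).max() < 1e-8
        assert np.abs(async_spectrum(_dyn(c * y)) - c**2 * base_psi).max() < 1e-8

    def test_in_phase_signals_give_no_cross_peak(self):
        t = np.arange(200)
        wave = np.cos(2 * np.pi * t / 200)
        y = np.vstack([wave, 3.0 * wave])
        psi = async_spectrum(_dyn(y))
        phi = sync_spectrum(_dyn(y))
        assert abs(psi[0, 1]) < 0.02 * abs(phi[0, 1])

    def test_quadrature_lag_sign_rule_and_fourier_match(self):
        """v1 leading v2 by pi/2 gives sign(Phi*Psi) > 0 at the cross peak,
        and the Hilbert-Noda route matches the Fourier route within 2%."""
        m = 200
        t = np.arange(m)
        lead = np.cos(2 * np.pi * t / m)
        lag = np.cos(2 * np.pi * t / m - np.pi / 2)
        d = _dyn(np.vstack([lead, lag]))
        phi, psi = sync_spectrum(d), async_spectrum(d)
        oracle = fourier_oracle(d)
        assert np.sign(phi[0, 1] * psi[0, 1]) > 0
        rel = abs(psi[0, 1] - oracle.async_[0, 1]) / abs(oracle.async_[0, 1])
        assert rel < 0.02

    def test_converges_to_fourier_oracle_at_m64(self):
        m = 64
        t = np.arange(m)
        rng = np.random.default_rng(5)
        rows = [np.cos(2 * np.pi * t / m + rng.uniform(0, 2 * np.pi))
                for _ in range(5)]
        d = _dyn(np.vstack(rows))
        psi = async_spectrum(d)
        oracle = fourier_oracle(d).async_
        rel = np.linalg.norm(psi - oracle) / np.linalg.norm(oracle)
        assert rel < 0.05


class TestFourierOracle:
    def test_sync_part_is_parseval_exact(self, rng):
        y = rng.normal(size=(6, 64))
        d = _dyn(y)
        phi = sync_spectrum(d)
        rel = np.abs(fourier_oracle(d).sync - phi).max() / np.abs(phi).max()
        assert rel < 1e-6

    def test_async_part_antisymmetric(self, rng):
        psi = fourier_oracle(_dyn(rng.normal(size=(4, 32)))).async_
        assert np.abs(psi + psi.T).max() < 1e-10

    def test_zero_input_gives_zero_output(self):
        pair = fourier_oracle(_dyn(np.zeros((3, 16))))
        assert np.all(pair.sync == 0.0)
        assert np.all(pair.async_ == 0.0)


class TestDynamicSpectrum:
    def test_identical_scans_give_zero_dynamics(self):
        scans = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 5))
        d = dynamic_spectrum(scans, reference_mode="perturbation_mean")
        assert np.all(d.y == 0.0)

    def test_perturbation_mean_rows_sum_to_zero(self, rng):
        d = dynamic_spectrum(rng.normal(size=(6, 9)),
                             reference_mode="perturbation_mean")
        assert np.abs(d.y.sum(axis=1)).max() < 1e-10

    def test_zero_reference_returns_raw_intensities(self, rng):
        scans = rng.normal(size=(4, 5))
        d = dynamic_spectrum(scans, reference_mode="provided",
                             reference=np.zeros(4))
        assert np.array_equal(d.y, scans)

    def test_reference_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            dynamic_spectrum(rng.normal(size=(4, 5)),
                             reference_mode="provided",
                             reference=np.zeros(3))

    def test_single_scan_rejected(self):
        with pytest.raises(ValueError, match="m >= 2|2 perturbation"):
            dynamic_spectrum(np.ones((4, 1)))


class TestRender:
    def test_byte_deterministic(self, rng):
        matrix = rng.normal(size=(20, 20))
        a = render_contour(matrix)
        b = render_contour(matrix)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.pixels.dtype == np.uint8

    def test_output_shape_from_config(self, rng):
        img = render_contour(rng.normal(size=(15, 15)),
                             RenderConfig(size=64, levels=8))
        assert img.pixels.shape == (64, 64, 3)

    def test_negation_inverts_palette(self, rng):
        cfg = RenderConfig(size=32, levels=16)
        matrix = rng.normal(size=(32, 32))  # no resampling: exact level flip
        pos = render_contour(matrix, cfg)
        neg = render_contour(-matrix, cfg)
        lut = np.unique(pos.pixels.reshape(-1, 3), axis=0)
        # negated matrix must use the mirrored level for every pixel
        levels = np.linspace(-np.abs(matrix).max(), np.abs(matrix).max(), 17)
        idx = np.clip(np.digitize(matrix, levels) - 1, 0, 15)[::-1, :]
        from matplotlib import colormaps
        full_lut = (colormaps["RdBu_r"].resampled(16)(np.arange(16))[:, :3]
                    * 255 + 0.5).astype(np.uint8)
        assert np.array_equal(pos.pixels, full_lut[idx])
        assert np.array_equal(neg.pixels, full_lut[15 - idx])

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="square"):
            render_contour(rng.normal(size=(3, 4)))
        bad = np.full((4, 4), np.nan)
        with pytest.raises(ValueError, match="finite"):
            render_contour(bad)


class TestBatchCos:
    def test_single_sample_single_window_sync_only(self):
        cfg = SimConfig(n_classes=2, samples_per_class=1, scans_per_sample=4,
                        wavelength_step=12.8, seed=1)
        spectra = simulate_spectra(cfg)
        images, manifest = batch_cos(spectra, [BandWindow(1000.0, 1400.0)],
                                     types=("sync",),
                                     render_cfg=RenderConfig(size=32))
        assert len(images) == 2  # 2 samples x 1 window x 1 type
        assert set(manifest["type"]) == {"sync"}

    def test_count_formula_and_manifest_cells(self, tiny_cfg):
        spectra = simulate_spectra(tiny_cfg)
        pre, _ = preprocess_chain(spectra)
        windows = [BandWindow(1000.0, 1400.0), BandWindow(1500.0, 1800.0)]
        images, manifest = batch_cos(pre, windows,
                                     render_cfg=RenderConfig(size=32))
        n = spectra.n_samples
        assert len(images) == n * 2 * 2
        cell_sizes = manifest.groupby(["window", "type"]).size()
        assert set(cell_sizes) == {n}
        assert len(cell_sizes) == 4

    def test_empty_window_list_rejected(self, tiny_cfg):
        spectra = simulate_spectra(tiny_cfg)
        with pytest.raises(ValueError, match="window"):
            batch_cos(spectra, [])
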