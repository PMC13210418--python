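"""Detector model: DRF structure, sharing kernel, forward counts, noise, rebin."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import pcdspect as p
from pcdspect.detector import (DETECTED_GRID_KEV, INCIDENT_GRID_KEV,
                               BinnedCountImage, charge_sharing_fraction)
from pcdspect.phantom import ThicknessMaps


class TestDRF:
    def test_photopeak_at_incident_energy(self, drf):
        i60 = int(np.where(INCIDENT_GRID_KEV == 60.0)[0][0])
        assert drf.detected_energies[np.argmax(drf.R[i60])] == 60.0

    def test_row_sum_equals_interaction_probability(self, drf, mu_cdte,
                                                    det_config):
        i60 = int(np.where(INCIDENT_GRID_KEV == 60.0)[0][0])
        eff = 1.0 - np.exp(-mu_cdte(60.0) * det_config.cdte_thickness)
        assert drf.R[i60].sum() == pytest.approx(eff, rel=1e-6)

    def test_rows_nonnegative_bounded(self, drf):
        assert np.all(drf.R >= 0)
        sums = drf.R.sum(axis=1)
        assert np.all(sums > 0) and np.all(sums <= 2.0)

    def test_peak_never_above_incident_energy(self, drf):
        for i in range(0, len(INCIDENT_GRID_KEV), 20):
            e_det = drf.detected_energies[np.argmax(drf.R[i])]
            assert e_det <= INCIDENT_GRID_KEV[i] + 1e-9

    def test_degenerate_limit_is_diagonal(self, mu_cdte):
        cfg = p.DetectorConfig(charge_cloud_sigma=1e-6,
                               electronic_noise_sigma=1e-3,
                               escape_model_on=False)
        drf = p.build_drf(cfg, mu_cdte)
        i80 = int(np.where(INCIDENT_GRID_KEV == 80.0)[0][0])
        row = drf.R[i80]
        eff = 1.0 - np.exp(-mu_cdte(80.0) * cfg.cdte_thickness)
        assert row[int(80) - 1] == pytest.approx(eff, rel=1e-3)
        off = row.sum() - row[int(80) - 1]
        assert off < 1e-3 * eff

    def test_escape_lines_present_when_enabled(self, det_config, mu_cdte):
        on = p.build_drf(det_config, mu_cdte)
        off = p.build_drf(
            p.DetectorConfig(escape_model_on=False), mu_cdte)
        i100 = int(np.where(INCIDENT_GRID_KEV == 100.0)[0][0])
        # escape moves photopeak mass down by the fluorescence energies
        j_esc = int(round(100 - 23.17)) - 1
        assert on.R[i100, j_esc] > off.R[i100, j_esc]

    def test_csv_export(self, drf, tmp_path):
        path = tmp_path / "drf.csv"
        drf.to_csv(str(path))
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        assert data.shape == (len(INCIDENT_GRID_KEV),
                              len(DETECTED_GRID_KEV) + 1)


class TestSharingKernel:
    def test_unit_sum_and_symmetry(self, det_config):
        k = p.fit_sharing_kernel(det_config).weights
        assert k.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(k, np.rot90(k))
        assert np.allclose(k, k.T)

    def test_sigma_to_zero_gives_identity(self):
        k = p.fit_sharing_kernel(
            p.DetectorConfig(charge_cloud_sigma=1e-9)).weights
        assert k[1, 1] == pytest.approx(1.0, abs=1e-9)

    def test_center_weight_matches_quadrature_oracle(self, det_config):
        # independent oracle: integrate the collected-in-pixel fraction of a
        # Gaussian cloud over a uniform center position with scipy.quad
        sigma, pitch = det_config.charge_cloud_sigma, det_config.pixel_pitch

        def collected(c):
            return norm.cdf((pitch - c) / sigma) - norm.cdf(-c / sigma)

        w1, _ = quad(collected, 0, pitch)
        w1 /= pitch
        k = p.fit_sharing_kernel(det_config).weights
        # kernel is renormalized over 3x3; compare unnormalized center mass
        assert k[1, 1] * _kernel_mass(det_config) == pytest.approx(
            w1 ** 2, abs=1e-6)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            p.DetectorConfig(charge_cloud_sigma=-0.1)

    def test_sharing_fraction_complements_center_weight(self, det_config):
        s = charge_sharing_fraction(det_config)
        assert 0 < s < 1


def _kernel_mass(cfg):
    from pcdspect.detector import _collection_profile

    w1 = _collection_profile(cfg.charge_cloud_sigma, cfg.pixel_pitch)
    return np.outer(w1, w1).sum()


def _uniform_maps(n, al, pmma, pitch=0.1):
    return ThicknessMaps(np.full((n, n), float(al)),
                         np.full((n, n), float(pmma)), pitch)


class TestExpectedCounts:
    def test_open_beam_uniform(self, spectrum, drf, thresholds_m4):
        maps = _uniform_maps(20, 0.0, 0.0)
        img = p.expected_bin_counts(maps, spectrum, drf, thresholds_m4, 7.5)
        for k in range(img.n_bins):
            assert np.ptp(img.counts[k]) == 0
            assert img.counts[k, 0, 0] == pytest.approx(img.open_beam[k])

    def test_bins_partition_counts_above_first_threshold(self, spectrum, drf,
                                                         thresholds_m4):
        maps = _uniform_maps(4, 4.1, 83.0)
        img = p.expected_bin_counts(maps, spectrum, drf, thresholds_m4, 7.5)
        m2 = p.ThresholdConfig((20.0, 174.0))
        img2 = p.expected_bin_counts(maps, spectrum, drf, m2, 7.5)
        total_above_20 = img2.counts[:, 0, 0].sum()
        assert img.counts[:, 0, 0].sum() == pytest.approx(total_above_20,
                                                          rel=1e-12)

    def test_thicker_pmma_reduces_every_bin(self, spectrum, drf,
                                            thresholds_m4):
        a = p.expected_bin_counts(_uniform_maps(2, 4.1, 60.0), spectrum, drf,
                                  thresholds_m4, 7.5)
        b = p.expected_bin_counts(_uniform_maps(2, 4.1, 80.0), spectrum, drf,
                                  thresholds_m4, 7.5)
        assert np.all(b.counts < a.counts)

    def test_exposure_scaling_linear(self, spectrum, drf, thresholds_m4):
        maps = _uniform_maps(2, 4.1, 83.0)
        lo = p.expected_bin_counts(maps, spectrum, drf, thresholds_m4, 0.075)
        hi = p.expected_bin_counts(maps, spectrum, drf, thresholds_m4, 7.5)
        assert np.allclose(hi.counts, lo.counts * 100.0, rtol=1e-12)


class TestSharingConvolution:
    def test_uniform_image_unchanged(self, det_config, thresholds_m4):
        kernel = p.fit_sharing_kernel(det_config)
        img = BinnedCountImage(np.full((1, 30, 30), 5.0), 0.1, 7.5,
                               thresholds_m4, False, np.array([5.0]))
        out = p.apply_sharing(img, kernel)
        assert np.allclose(out.counts, 5.0, rtol=1e-12)

    def test_impulse_reproduces_kernel(self, det_config, thresholds_m4):
        kernel = p.fit_sharing_kernel(det_config)
        arr = np.zeros((1, 11, 11))
        arr[0, 5, 5] = 1.0
        img = BinnedCountImage(arr, 0.1, 7.5, thresholds_m4, False,
                               np.array([1.0]))
        out = p.apply_sharing(img, kernel)
        assert np.allclose(out.counts[0, 4:7, 4:7], kernel.weights, atol=1e-15)

    def test_interior_counts_conserved(self, det_config, thresholds_m4, rng):
        kernel = p.fit_sharing_kernel(det_config)
        arr = rng.uniform(10, 100, size=(2, 40, 40))
        arr[:, :5, :] = arr[:, -5:, :] = arr[:, :, :5] = arr[:, :, -5:] = 50.0
        img = BinnedCountImage(arr, 0.1, 7.5, thresholds_m4, False,
                               np.full(2, 50.0))
        out = p.apply_sharing(img, kernel)
        assert out.counts.sum() == pytest.approx(arr.sum(), rel=1e-9)

    def test_rejects_noisy_input(self, det_config, thresholds_m4):
        kernel = p.fit_sharing_kernel(det_config)
        img = BinnedCountImage(np.ones((1, 5, 5), dtype=np.int64), 0.1, 7.5,
                               thresholds_m4, True, np.array([1.0]))
        with pytest.raises(ValueError):
            p.apply_sharing(img, kernel)


class TestPoisson:
    def test_zero_mean_zero_counts(self, thresholds_m4):
        img = BinnedCountImage(np.zeros((1, 10, 10)), 0.1, 7.5, thresholds_m4,
                               False, np.array([1.0]))
        out = p.sample_poisson(img, seed=3)
        assert np.all(out.counts == 0)

    def test_sample_mean_within_sem(self, thresholds_m4):
        img = BinnedCountImage(np.full((1, 320, 320), 100.0), 0.1, 7.5,
                               thresholds_m4, False, np.array([100.0]))
        out = p.sample_poisson(img, seed=7)
        assert abs(out.counts.mean() - 100.0) < 0.5

    def test_same_seed_identical(self, thresholds_m4):
        img = BinnedCountImage(np.full((2, 20, 20), 30.0), 0.1, 7.5,
                               thresholds_m4, False, np.full(2, 30.0))
        a = p.sample_poisson(img, seed=11)
        b = p.sample_poisson(img, seed=11)
        assert np.array_equal(a.counts, b.counts)
        c = p.sample_poisson(img, seed=12)
        assert not np.array_equal(a.counts, c.counts)

    def test_variance_matches_mean(self, thresholds_m4):
        # Poisson character survives sharing-on-means + rebin: across seeds
        # the per-pixel variance of rebinned counts tracks the mean
        mean = np.full((1, 200, 200), 40.0)
        img = BinnedCountImage(mean, 0.1, 7.5, thresholds_m4, False,
                               np.array([40.0]))
        stacks = [p.rebin(p.sample_poisson(img, seed=s)).counts
                  for s in range(5)]
        arr = np.stack(stacks)          # (5, 1, 20, 20), mean 4000 per pixel
        pooled_var = arr.var(axis=0, ddof=1).mean()
        assert pooled_var == pytest.approx(4000.0, rel=0.10)


class TestRebin:
    def test_block_of_ones(self, thresholds_m4):
        img = BinnedCountImage(np.ones((1, 20, 20)), 0.1, 7.5, thresholds_m4,
                               False, np.array([1.0]))
        out = p.rebin(img, 10)
        assert out.counts.shape == (1, 2, 2)
        assert np.all(out.counts == 100.0)
        assert out.pitch == pytest.approx(1.0)
        assert out.open_beam[0] == pytest.approx(100.0)

    def test_total_conserved_exactly(self, thresholds_m4, rng):
        arr = rng.integers(0, 50, size=(3, 40, 40)).astype(np.int64)
        img = BinnedCountImage(arr, 0.1, 7.5, thresholds_m4, True,
                               np.full(3, 10.0), seed=0)
        out = p.rebin(img, 10)
        assert out.counts.sum() == arr.sum()
        assert out.counts.dtype == arr.dtype

    def test_non_divisible_rejected(self, thresholds_m4):
        img = BinnedCountImage(np.ones((1, 15, 15)), 0.1, 7.5, thresholds_m4,
                               False, np.array([1.0]))
        with pytest.raises(ValueError):
            p.rebin(img, 10)


class TestThresholdConfig:
    def test_equally_spaced_examples(self):
        assert p.ThresholdConfig.equally_spaced(2).thresholds == (20.0, 60.0)
        assert p.ThresholdConfig.equally_spaced(4).thresholds == \
            (20.0, 40.0, 60.0, 80.0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            p.ThresholdConfig((60.0, 20.0))
        with pytest.raises(ValueError):
            p.ThresholdConfig((20.0,))

    def test_hdf5_roundtrip(self, thresholds_m4, tmp_path):
        img = BinnedCountImage(np.arange(32.0).reshape(2, 4, 4), 1.0, 1.7,
                               p.ThresholdConfig((20.0, 60.0)), False,
                               np.array([5.0, 6.0]))
        path = str(tmp_path / "stack.h5")
        img.save(path)
        import h5py

        with h5py.File(path) as fh:
            assert fh.attrs["exposure_mAs"] == 1.7
            assert list(fh.attrs["thresholds_keV"]) == [20.0, 60.0]
            assert np.array_equal(fh["bin_1"][()], img.counts[1])
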