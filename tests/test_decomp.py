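"""Features, calibration grids, and the three decomposition regressors."""

import numpy as np
import pytest

import pcdspect as p
from pcdspect._mlp import parameter_count, train_mlp
from pcdspect.decomp import (DEFAULT_AL_RANGE, DEFAULT_PMMA_RANGE, MLPHyper,
                             CalibrationGrid, features_for_thicknesses,
                             fit_mlp, load_model, save_model)
from pcdspect.detector import BinnedCountImage


def _image(counts, open_beam, thresholds, noisy=True):
    arr = np.asarray(counts)
    if noisy:
        arr = arr.astype(np.int64)
    return BinnedCountImage(arr, 1.0, 7.5, thresholds, noisy,
                            np.asarray(open_beam, dtype=float))


class TestFeatures:
    def test_equal_counts_give_zero(self, thresholds_m4):
        img = _image(np.full((4, 3, 3), 1000), np.full(4, 1000.0),
                     thresholds_m4)
        f = p.to_features(img, img)
        assert np.all(f.features == 0.0)

    def test_log_ratio(self, thresholds_m4):
        n0 = 1000.0
        img = _image(np.full((4, 2, 2), int(round(n0 * np.exp(-2)))),
                     np.full(4, n0), thresholds_m4)
        f = p.to_features(img, img)
        assert np.allclose(f.features, -np.log(135 / 1000), rtol=1e-12)

    def test_zero_count_clamp(self, thresholds_m4):
        img = _image(np.zeros((4, 1, 1)), np.full(4, 1000.0), thresholds_m4)
        f = p.to_features(img, img)
        assert np.allclose(f.features, -np.log(0.5 / 1000), rtol=1e-12)
        assert f.features[0, 0, 0] == pytest.approx(7.601, abs=1e-3)

    def test_open_beam_must_be_positive(self, thresholds_m4):
        img = _image(np.ones((4, 1, 1)), np.array([0.0, 1, 1, 1]),
                     thresholds_m4)
        with pytest.raises(ValueError):
            p.to_features(img, np.array([0.0, 1, 1, 1]))


class TestCalibrationGrid:
    def test_uniform_lattice_with_endpoints(self, spectrum, drf,
                                            thresholds_m4):
        g = p.make_calibration_grid(3, spectrum, drf, thresholds_m4)
        assert sorted(set(g.thicknesses[:, 0])) == [0.0, 5.0, 10.0]
        assert sorted(set(g.thicknesses[:, 1])) == [0.0, 60.0, 120.0]
        assert g.features.shape == (9, 4)

    def test_origin_has_zero_features(self, grid8_m4):
        i0 = np.where((grid8_m4.thicknesses == 0).all(axis=1))[0][0]
        assert np.allclose(grid8_m4.features[i0], 0.0, atol=1e-12)

    def test_features_increase_with_thickness(self, grid8_m4):
        t = grid8_m4.thicknesses
        f = grid8_m4.features
        # fix PMMA = 0 row, increasing Al
        sel = t[:, 1] == 0
        order = np.argsort(t[sel, 0])
        assert np.all(np.diff(f[sel][order], axis=0) > 0)
        sel = t[:, 0] == 0
        order = np.argsort(t[sel, 1])
        assert np.all(np.diff(f[sel][order], axis=0) > 0)

    def test_invalid_grid(self, spectrum, drf, thresholds_m4):
        with pytest.raises(ValueError):
            p.make_calibration_grid(1, spectrum, drf, thresholds_m4)
        with pytest.raises(ValueError):
            p.make_calibration_grid(3, spectrum, drf, thresholds_m4,
                                    al_range=(5.0, 5.0))

    def test_csv_export(self, grid8_m4, tmp_path):
        import pandas as pd

        grid8_m4.to_csv(str(tmp_path / "grid.csv"))
        df = pd.read_csv(tmp_path / "grid.csv")
        assert list(df.columns) == ["x_al", "x_pmma", "f_1", "f_2", "f_3",
                                    "f_4"]
        assert len(df) == 64


class TestPoly:
    def test_exact_degree2_map_is_interpolated(self, rng):
        f = rng.uniform(0, 3, size=(60, 4))
        coef = rng.normal(size=(15, 2))
        from sklearn.preprocessing import PolynomialFeatures

        y = PolynomialFeatures(2).fit_transform(f) @ coef
        grid = CalibrationGrid(thicknesses=y, features=f, g=0,
                               al_range=(0, 1), pmma_range=(0, 1))
        model = p.fit_poly2(grid)
        pred = model.predict(f)
        assert np.allclose(pred, y, atol=1e-8)

    def test_matches_pseudoinverse_oracle(self, grid8_m4):
        from sklearn.preprocessing import PolynomialFeatures

        model = p.fit_poly2(grid8_m4, rcond=1e-6)
        d = PolynomialFeatures(2).fit_transform(grid8_m4.features)
        # independent oracle: explicit truncated pseudo-inverse
        coef = np.linalg.pinv(d, rcond=1e-6) @ grid8_m4.thicknesses
        assert np.allclose(model.predict(grid8_m4.features), d @ coef,
                           atol=1e-6)

    def test_underdetermined_raises(self, spectrum, drf):
        thr6 = p.ThresholdConfig.equally_spaced(6)
        grid = p.make_calibration_grid(3, spectrum, drf, thr6)  # 9 samples
        with pytest.raises(ValueError, match="28 terms"):
            p.fit_poly2(grid)  # 28 terms > 9 samples

    def test_degree3_behind_flag(self, grid8_m4):
        m3 = p.fit_poly2(grid8_m4, degree=3)
        assert m3.kind == "poly3"
        m2 = p.fit_poly2(grid8_m4)
        assert m2.kind == "poly2"


class TestMLP:
    def test_parameter_counts_closed_form(self):
        assert parameter_count(4, (128, 128), 2) == 17410
        assert parameter_count(4, (256, 256), 2) == 67586

    def test_deterministic_given_seed(self, grid8_m4):
        h = MLPHyper(hidden=(16, 16), epochs=300, seed=5)
        a = fit_mlp(grid8_m4, h)
        b = fit_mlp(grid8_m4, h)
        x = grid8_m4.features[:10]
        assert np.array_equal(a.predict(x), b.predict(x))

    def test_capacity_on_linear_map(self, rng):
        # ample training on an exact linear map: RMSE < 1% of target range
        x = rng.uniform(-1, 1, size=(512, 3))
        w = np.array([[1.0, -2.0], [0.5, 1.5], [-1.0, 0.3]])
        y = x @ w
        net = train_mlp(x, y, hidden=(32, 32), epochs=3000, lr=3e-3,
                        dropout=0.0, weight_decay=0.0, seed=1)
        xv = rng.uniform(-1, 1, size=(200, 3))
        rmse = np.sqrt(((net.predict(xv) - xv @ w) ** 2).mean())
        assert rmse < 0.01 * (y.max() - y.min())

    def test_nonfinite_loss_raises(self):
        x = np.array([[np.nan, 1.0], [0.0, 1.0]])
        y = np.zeros((2, 2))
        with pytest.raises(FloatingPointError):
            train_mlp(x, y, hidden=(8,), epochs=5, seed=0)


class TestSVR:
    def test_dual_form_oracle(self, grid8_m4, svr_model):
        # re-evaluate Eq-style dual form sum_i (a_i - a_i*) K(x_i, x) + b
        z = (grid8_m4.features - svr_model.x_mean) / svr_model.x_std
        for col, s in enumerate(svr_model.svrs):
            d2 = ((z[:, None, :] - s.support_vectors_[None]) ** 2).sum(-1)
            manual = np.exp(-s._gamma * d2) @ s.dual_coef_[0] + s.intercept_[0]
            assert np.allclose(manual, s.predict(z), atol=1e-10)

    def test_epsilon_insensitive_at_support_vectors(self, grid8_m4,
                                                    svr_model):
        # training-point residuals bounded near the eps-tube (scaled units)
        z = (grid8_m4.features - svr_model.x_mean) / svr_model.x_std
        span = svr_model.y_max - svr_model.y_min
        y_scaled = (grid8_m4.thicknesses - svr_model.y_min) / span
        for col, s in enumerate(svr_model.svrs):
            resid = np.abs(s.predict(z) - y_scaled[:, col])
            assert resid.max() < 0.010 + 5e-3

    def test_degenerate_grid_rejected(self):
        grid = CalibrationGrid(thicknesses=np.zeros((9, 2)),
                               features=np.ones((9, 4)), g=3,
                               al_range=(0, 1), pmma_range=(0, 1))
        with pytest.raises(ValueError):
            p.fit_svr(grid)

    def test_train_rmse_not_worse_on_denser_grid(self, spectrum, drf,
                                                 thresholds_m4, grid8_m4):
        g3 = p.make_calibration_grid(3, spectrum, drf, thresholds_m4)
        m3, m8 = p.fit_svr(g3), p.fit_svr(grid8_m4)

        def train_rmse(m, g):
            return np.sqrt(((m.predict(g.features) - g.thicknesses) ** 2
                            ).mean())

        assert train_rmse(m8, grid8_m4) <= train_rmse(m3, g3) + 1e-9


class TestDecompose:
    def test_constant_features_give_constant_maps(self, poly_model):
        f = p.FeatureImage(np.tile([0.5, 1.0, 1.5, 2.0], (6, 6, 1)), 1.0)
        maps = p.decompose(poly_model, f)
        assert np.ptp(maps.al_map) == 0 and np.ptp(maps.pmma_map) == 0

    def test_pixelwise_permutation_equivariance(self, svr_model, rng):
        feats = rng.uniform(0, 2, size=(4, 5, 4))
        maps = p.decompose(svr_model, p.FeatureImage(feats, 1.0))
        flat = feats.reshape(-1, 4)
        perm = rng.permutation(flat.shape[0])
        maps_p = p.decompose(svr_model,
                             p.FeatureImage(flat[perm].reshape(4, 5, 4), 1.0))
        assert np.allclose(maps_p.al_map.ravel(),
                           maps.al_map.ravel()[perm], rtol=1e-12)

    def test_bin_mismatch_rejected(self, poly_model):
        f = p.FeatureImage(np.zeros((2, 2, 3)), 1.0)
        with pytest.raises(ValueError):
            p.decompose(poly_model, f)

    def test_predictions_passed_through_unclipped(self, poly_model):
        # decompose returns raw model output; negative extrapolations survive
        f = p.FeatureImage(np.full((2, 3, 4), -0.8), 1.0)
        maps = p.decompose(poly_model, f)
        raw = poly_model.predict(f.flat())
        assert np.array_equal(maps.al_map.ravel(), raw[:, 0])
        assert np.array_equal(maps.pmma_map.ravel(), raw[:, 1])


class TestPersistence:
    def test_roundtrip_all_kinds(self, grid8_m4, poly_model, svr_model,
                                 tmp_path, rng):
        mlp = fit_mlp(grid8_m4, MLPHyper(hidden=(8, 8), epochs=100, seed=2))
        x = rng.uniform(0, 2, size=(20, 4))
        for name, model in (("poly", poly_model), ("svr", svr_model),
                            ("mlp", mlp)):
            path = str(tmp_path / f"{name}.h5")
            save_model(model, path)
            loaded = load_model(path)
            assert np.allclose(loaded.predict(x), model.predict(x),
                               atol=1e-10)
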