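"""NIPALS PLS1: fitting, prediction, LOO PRESS, factor selection."""

import numpy as np
import pytest

from nirfly.errors import ConfigError, ValidationError
from nirfly.pls import (PLSModel, fit_pls1, loo_cross_validate, predict,
                        regression_coefficients, select_factors)


def loo_press_naive(X, y, k_max):
    """Independent oracle: explicit refit loop, no algebraic shortcuts."""
    n = len(y)
    pred = np.empty((n, k_max))
    for i in range(n):
        keep = np.r_[0:i, i + 1:n]
        for k in range(1, k_max + 1):
            m = fit_pls1(X[keep], y[keep], k)
            pred[i, k - 1] = predict(m, X[i:i + 1])[0]
    press = ((pred - y[:, None]) ** 2).sum(axis=0)
    return press, pred


class TestFit:
    def test_univariate_proportionality(self):
        x = np.array([[-1.0], [0.0], [1.0], [2.0]])
        y = 2.0 * x.ravel()
        m = fit_pls1(x, y, 1)
        assert m.b[0] == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(predict(m, x), y, atol=1e-12)

    def test_full_rank_equals_ols(self, rng):
        n, p = 40, 8
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        m = fit_pls1(X, y, p)
        Xc = X - X.mean(axis=0)
        b_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
        np.testing.assert_allclose(predict(m, X), Xc @ b_ols + y.mean(),
                                   atol=1e-8)

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.cross_decomposition import PLSRegression
        X = rng.normal(size=(30, 12))
        y = X @ rng.normal(size=12) + rng.normal(size=30)
        m = fit_pls1(X, y, 4)
        sk = PLSRegression(n_components=4, scale=False).fit(X, y)
        np.testing.assert_allclose(predict(m, X), sk.predict(X).ravel(),
                                   atol=1e-10)

    def test_orthogonal_response_gives_zero_coefficients(self, rng):
        X = rng.normal(size=(12, 3))
        Xc = X - X.mean(axis=0)
        raw = rng.normal(size=12)
        raw -= raw.mean()
        y = raw - Xc @ np.linalg.lstsq(Xc, raw, rcond=None)[0]
        y += 5.0  # nonzero mean, zero covariance with X
        m = fit_pls1(X, y, 2)
        np.testing.assert_allclose(m.b, 0.0, atol=1e-8)
        np.testing.assert_allclose(predict(m, X), y.mean(), atol=1e-8)

    def test_scores_orthogonal_and_weights_unit_norm(self, rng):
        X = rng.normal(size=(25, 40))
        y = rng.normal(size=25)
        m = fit_pls1(X, y, 6)
        norms = np.linalg.norm(m.T, axis=0)
        cross = np.abs(m.T.T @ m.T - np.diag(norms**2))
        assert cross.max() / np.outer(norms, norms).max() < 1e-8
        np.testing.assert_allclose(np.linalg.norm(m.W, axis=0), 1.0, atol=1e-12)

    def test_training_rss_nonincreasing_in_k(self, rng):
        X = rng.normal(size=(20, 15))
        y = rng.normal(size=20)
        rss = [np.sum((predict(fit_pls1(X, y, k), X) - y) ** 2)
               for k in range(1, 8)]
        assert all(a >= b - 1e-10 for a, b in zip(rss, rss[1:]))

    def test_degenerate_inputs_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValidationError):
            fit_pls1(X, np.ones(10), 2)        # zero-variance response
        with pytest.raises(ConfigError):
            fit_pls1(X, rng.normal(size=10), 5)  # k > p
        with pytest.raises(ValidationError):
            fit_pls1(X, rng.normal(size=9), 2)   # length mismatch


class TestPredict:
    def test_training_rows_reproduce_fitted_values(self, rng):
        X = rng.normal(size=(15, 10))
        y = rng.normal(size=15)
        m = fit_pls1(X, y, 3)
        np.testing.assert_allclose(predict(m, X), m.fitted, atol=1e-10)

    def test_mean_spectrum_predicts_mean_response(self, rng):
        X = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        m = fit_pls1(X, y, 2)
        assert predict(m, m.x_mean[None, :])[0] == pytest.approx(m.y_mean,
                                                                 abs=1e-12)

    def test_duplicated_rows_predict_identically(self, rng):
        X = rng.normal(size=(8, 5))
        m = fit_pls1(X, rng.normal(size=8), 2)
        row = X[3:4]
        out = predict(m, np.vstack([row, row]))
        assert out[0] == out[1]

    def test_fingerprint_and_grid_mismatch_rejected(self, rng):
        X = rng.normal(size=(8, 5))
        m = fit_pls1(X, rng.normal(size=8), 2, fingerprint="abc")
        with pytest.raises(ValidationError):
            predict(m, X, fingerprint="other")
        with pytest.raises(ValidationError):
            predict(m, rng.normal(size=(2, 6)))

    def test_save_load_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(9, 7))
        m = fit_pls1(X, rng.normal(size=9), 3, wavelengths=np.arange(7.0),
                     fingerprint="fp")
        path = tmp_path / "model.json"
        m.save(path)
        back = PLSModel.load(path)
        np.testing.assert_allclose(back.b, m.b)
        np.testing.assert_allclose(predict(back, X), predict(m, X))
        assert back.fingerprint == "fp" and back.k == m.k


class TestLeaveOneOut:
    def test_press_equals_naive_refit_loop(self, rng):
        X = rng.normal(size=(10, 6))
        y = X @ rng.normal(size=6) + 0.5 * rng.normal(size=10)
        curve = loo_cross_validate(X, y, 3)
        press, pred = loo_press_naive(X, y, 3)
        np.testing.assert_allclose(curve.loo_pred, pred, atol=1e-10)
        np.testing.assert_allclose(curve.press, press, atol=1e-10)

    def test_noiseless_rank_one_has_zero_press(self, rng):
        t = rng.normal(size=12)
        X = np.outer(t, rng.normal(size=20))
        y = 3.0 * t
        curve = loo_cross_validate(X, y, 1)
        assert curve.press[0] < 1e-16

    def test_permutation_invariance(self, rng):
        X = rng.normal(size=(14, 9))
        y = rng.normal(size=14)
        perm = rng.permutation(14)
        a = loo_cross_validate(X, y, 4).press
        b = loo_cross_validate(X[perm], y[perm], 4).press
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_infeasible_k_max_rejected(self, rng):
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        with pytest.raises(ConfigError):
            loo_cross_validate(X, y, 5)  # k_max > n - 2
        with pytest.raises(ValidationError):
            loo_cross_validate(X[:2], y[:2], 1)


class TestSelectFactors:
    @pytest.mark.parametrize("press, tol, expected", [
        ([10, 4, 4.02, 4.1], 0.02, 2),   # near-tie resolved to fewer factors
        ([5, 4, 3], 0.0, 3),              # strictly decreasing: global min
        ([3, 3, 3], 0.5, 1),              # ties break to the smallest k
    ])
    def test_selection_rule(self, press, tol, expected):
        assert select_factors(np.asarray(press, dtype=float), tol) == expected

    def test_empty_curve_rejected(self):
        with pytest.raises(ConfigError):
            select_factors(np.array([]))


class TestRegressionCoefficients:
    def test_single_band_difference_localised(self, rng):
        # two classes differing only in a Gaussian band at 1450 nm
        wl = np.arange(1300.0, 1601.0)
        band = np.exp(-0.5 * ((wl - 1450.0) / 20.0) ** 2)
        amp = np.repeat([0.0, 0.05], 10) + rng.normal(0, 0.002, 20)
        X = 0.5 + np.outer(amp, band) + rng.normal(0, 1e-4, (20, wl.size))
        y = np.repeat([1.0, 2.0], 10)
        m = fit_pls1(X, y, 1, wavelengths=wl)
        coef = regression_coefficients(m)
        peak = coef.loc[coef["coefficient"].abs().idxmax(), "wavelength_nm"]
        assert abs(peak - 1450.0) <= 30.0

    def test_zero_coefficients_export_flat(self, rng):
        X = rng.normal(size=(12, 3))
        Xc = X - X.mean(axis=0)
        raw = rng.normal(size=12)
        raw -= raw.mean()
        y = raw - Xc @ np.linalg.lstsq(Xc, raw, rcond=None)[0] + 2.0
        m = fit_pls1(X, y, 2)
        coef = regression_coefficients(m)
        np.testing.assert_allclose(coef["coefficient"], 0.0, atol=1e-8)

    def test_smoothing_window_one_is_identity(self, rng):
        m = fit_pls1(rng.normal(size=(10, 8)), rng.normal(size=10), 2)
        a = regression_coefficients(m)["coefficient"]
        b = regression_coefficients(m, smooth_window=1)["coefficient"]
        np.testing.assert_array_equal(a, b)
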