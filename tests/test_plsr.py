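"""NIPALS core: oracle equivalence, CV, diagnostics and model identities."""

import numpy as np
import pytest

from leafspec.plsr import (
    PLSModel,
    fit_nipals,
    loo_cross_validate,
    outlier_diagnostics,
    select_components,
    beta_spectrum,
)

sklearn = pytest.importorskip("sklearn")
from sklearn.cross_decomposition import PLSRegression  # noqa: E402


class TestFitNipals:
    def test_rank_one_data_fits_in_one_component(self, rng):
        # X varies along a single direction and y is linear in it
        t = rng.normal(size=15)
        v = rng.normal(size=8)
        X = np.outer(t, v)
        y = 2.0 * t + 1.0
        model = fit_nipals(X, y, 1)
        assert np.max(np.abs(model.predict(X) - y)) <= 1e-10

    def test_one_component_weight_closed_form(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        model = fit_nipals(X, y, 1)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w = Xc.T @ yc
        w /= np.linalg.norm(w)
        np.testing.assert_allclose(model.W[:, 0], w, atol=1e-10)

    @pytest.mark.parametrize("n_components", [1, 2, 3])
    def test_matches_reference_pls_on_random_problems(self, n_components):
        # independent oracle: scikit-learn's PLS with centering only
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(8, 21))
            p = int(rng.integers(4, 16))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            model = fit_nipals(X, y, n_components)
            ref = PLSRegression(n_components=n_components, scale=False)
            ref.fit(X, y[:, None])
            np.testing.assert_allclose(
                model.predict(X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_score_orthogonality(self, rng):
        X = rng.normal(size=(25, 12))
        y = rng.normal(size=25)
        model = fit_nipals(X, y, 5)
        t = model.scores(X)
        gram = t.T @ t
        off_diag = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off_diag)) <= 1e-8

    def test_full_rank_equals_least_squares(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        model = fit_nipals(X, y, 5)
        design = np.column_stack([np.ones(12), X])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        np.testing.assert_allclose(model.predict(X), design @ coef, atol=1e-6)

    def test_beta_form_equals_scores_form(self, rng):
        X = rng.normal(size=(18, 9))
        y = rng.normal(size=18)
        model = fit_nipals(X, y, 3)
        X_new = rng.normal(size=(6, 9))
        np.testing.assert_allclose(
            model.predict(X_new), model.predict_from_scores(X_new), atol=1e-10
        )

    def test_unit_norm_weights(self, rng):
        model = fit_nipals(rng.normal(size=(15, 7)), rng.normal(size=15), 4)
        np.testing.assert_allclose(
            np.linalg.norm(model.W, axis=0), 1.0, atol=1e-12
        )

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            fit_nipals(rng.normal(size=(10, 4)), np.ones(10), 2)

    def test_rank_deficient_truncates_with_warning(self, rng):
        x = rng.normal(size=(10, 1))
        X = np.hstack([x, x, x])  # rank 1
        y = x[:, 0] + rng.normal(size=10) * 0.1
        with pytest.warns(UserWarning, match="rank"):
            model = fit_nipals(X, y, 3)
        assert model.n_components == 1

    def test_centering_identity(self, rng):
        X = rng.normal(size=(14, 6))
        y = rng.normal(size=14)
        model = fit_nipals(X, y, 2)
        assert model.predict(X.mean(axis=0)[None, :])[0] == pytest.approx(
            y.mean(), abs=1e-10
        )

    def test_shift_linearity(self, rng):
        X = rng.normal(size=(14, 6))
        y = rng.normal(size=14)
        model = fit_nipals(X, y, 2)
        delta = rng.normal(size=6)
        shift = model.predict(X + delta) - model.predict(X)
        np.testing.assert_allclose(shift, delta @ model.beta, atol=1e-10)


class TestLooCrossValidate:
    def test_equals_brute_force_refit(self, rng):
        X = rng.normal(size=(8, 5))
        y = rng.normal(size=8)
        preds, rmse = loo_cross_validate(X, y, 3)
        for i in range(8):
            keep = np.arange(8) != i
            for a in range(1, 4):
                expected = fit_nipals(X[keep], y[keep], a).predict(
                    X[i][None, :]
                )[0]
                assert preds[i, a - 1] == pytest.approx(expected, abs=1e-12)
        assert np.all(rmse >= 0)

    def test_matches_reference_loo(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        preds, _ = loo_cross_validate(X, y, 2)
        for i in range(10):
            keep = np.arange(10) != i
            ref = PLSRegression(n_components=2, scale=False)
            ref.fit(X[keep], y[keep, None])
            assert preds[i, 1] == pytest.approx(
                ref.predict(X[i][None, :]).ravel()[0], abs=1e-8
            )

    def test_near_interpolation_on_duplicated_data(self, rng):
        X = rng.normal(size=(6, 3))
        y = X[:, 0] * 2.0
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, y])
        _, rmse = loo_cross_validate(X2, y2, 3)
        assert rmse.min() <= 1e-8

    def test_too_many_components_truncated(self, rng):
        X = rng.normal(size=(6, 10))
        y = rng.normal(size=6)
        with pytest.warns(UserWarning, match="truncating"):
            preds, _ = loo_cross_validate(X, y, 8)
        assert preds.shape[1] == 3

    def test_deterministic(self, rng):
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        p1, r1 = loo_cross_validate(X, y, 3)
        p2, r2 = loo_cross_validate(X, y, 3)
        np.testing.assert_array_equal(p1, p2)


class TestSelectComponents:
    @pytest.mark.parametrize(
        "curve, n, expected",
        [
            ([0.9, 0.4, 0.41, 0.39], 100, 4),
            ([0.5, 0.5], 100, 1),  # tie -> smaller
            (list(np.linspace(1.0, 0.1, 12)), 100, 10),  # cap
        ],
    )
    def test_argmin_with_cap(self, curve, n, expected):
        assert select_components(np.asarray(curve), n_samples=n) == expected

    def test_small_n_caps_at_third(self):
        curve = np.linspace(1.0, 0.1, 10)
        assert select_components(curve, n_samples=12) == 4


class TestOutlierDiagnostics:
    def test_leverage_sums_to_components_plus_one(self, rng):
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        model = fit_nipals(X, y, 3)
        report = outlier_diagnostics(model, X)
        assert report.leverage.sum() == pytest.approx(3 + 1, abs=1e-8)

    def test_centroid_sample_has_minimal_influence(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        model = fit_nipals(X, y, 2)
        centroid = X.mean(axis=0)[None, :]
        rep = outlier_diagnostics(model, np.vstack([X, centroid]))
        assert rep.leverage[-1] == pytest.approx(1 / 21, abs=1e-10)
        assert rep.hotelling_t2[-1] == pytest.approx(0.0, abs=1e-10)

    def test_gross_outlier_flagged_by_both_criteria(self, default_study):
        from leafspec.pipeline import build_design_matrix

        X = build_design_matrix(default_study.dataset, "absorbance").copy()
        y = default_study.pigments["car_g_m2"].to_numpy()
        X[0] *= 10.0  # inject a 10x spectral-amplitude outlier
        model = fit_nipals(X, y, 3)
        rep = outlier_diagnostics(model, X)
        assert rep.leverage[0] > rep.leverage_limit
        assert rep.hotelling_t2[0] > rep.t2_limit
        assert rep.flags[0]

    def test_limits_positive(self, rng):
        model = fit_nipals(rng.normal(size=(15, 5)), rng.normal(size=15), 2)
        rep = outlier_diagnostics(model, rng.normal(size=(15, 5)))
        assert rep.leverage_limit > 0 and rep.t2_limit > 0


class TestBetaSpectrumAndSerialization:
    def test_beta_spectrum_length_and_round_trip(self, tmp_path, rng):
        from leafspec.spectra import DEFAULT_GRID

        X = rng.normal(size=(20, 301))
        y = rng.normal(size=20)
        model = fit_nipals(X, y, 2)
        table = beta_spectrum(model, DEFAULT_GRID)
        assert len(table) == 301
        path = tmp_path / "beta.csv"
        table.to_csv(path, index=False, float_format="%.12g")
        import pandas as pd

        back = pd.read_csv(path)
        np.testing.assert_allclose(back["beta"], table["beta"], atol=1e-9)

    def test_beta_mass_concentrates_at_chl_a_bands(self):
        # population varying only in Chl a: coefficients live near its peaks
        from leafspec.pipeline import build_design_matrix
        from leafspec.spectra import DEFAULT_GRID
        from leafspec.synthetic import GeneratorConfig, generate_dataset

        cfg = GeneratorConfig(
            n_samples=40, chl_b_ratio_range=(0.399, 0.401),
            car_ratio_range=(0.249, 0.251), structural_amplitude=1e-6,
            backscatter_range=(0.499, 0.501), sensor_noise_sd=1e-5,
            seed=3,
        )
        study = generate_dataset(cfg)
        X = build_design_matrix(study.dataset, "absorbance")
        y = study.truth.chl_a
        model = fit_nipals(X, y, 2)
        wl = DEFAULT_GRID.wavelengths()
        weight = np.abs(model.beta)
        near_peaks = (np.abs(wl - 430) <= 40) | (np.abs(wl - 662) <= 40)
        assert weight[near_peaks].sum() > 0.5 * weight.sum()

    def test_json_round_trip(self, rng):
        X = rng.normal(size=(15, 8))
        y = rng.normal(size=15)
        model = fit_nipals(X, y, 3)
        back = PLSModel.from_json(model.to_json())
        X_new = rng.normal(size=(4, 8))
        np.testing.assert_allclose(
            back.predict(X_new), model.predict(X_new), atol=1e-12
        )
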