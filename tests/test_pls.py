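from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ivspec import fit_pls, kfold_cv, predict, q2, rmse, sd_over_runs
from ivspec.dataset import CenteringTransform
from ivspec.pls import dump_model

from _oracles import naive_pls1, ols_fit


def centered(rng, n, p):
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    return X - X.mean(axis=0), y - y.mean()


class TestFit:
    def test_single_informative_channel_is_exact_with_one_factor(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=20)
        Xc = np.column_stack([x1, np.zeros(20), np.zeros(20)])
        Xc -= Xc.mean(axis=0)
        yc = 2.0 * Xc[:, 0]
        model = fit_pls(Xc, yc, 1)
        assert rmse(yc, Xc @ model.coef_b) <= 1e-10

    def test_full_component_model_matches_least_squares(self, rng):
        for _ in range(5):
            Xc, yc = centered(rng, 30, 6)
            model = fit_pls(Xc, yc, 6)
            beta = ols_fit(Xc, yc)
            np.testing.assert_allclose(model.coef_b, beta, rtol=1e-6, atol=1e-8)

    def test_score_decomposition_agrees_with_coefficients(self, rng):
        Xc, yc = centered(rng, 25, 8)
        model = fit_pls(Xc, yc, 4)
        via_scores = model.scores_T @ model.y_loadings_q
        via_coef = Xc @ model.coef_b
        np.testing.assert_allclose(via_scores, via_coef, rtol=1e-8, atol=1e-10)

    def test_matches_independent_nipals(self, rng):
        Xc, yc = centered(rng, 25, 10)
        model = fit_pls(Xc, yc, 3)
        coef, _, _ = naive_pls1(Xc, yc, 3)
        np.testing.assert_allclose(model.coef_b, coef, rtol=1e-9, atol=1e-12)

    def test_matches_sklearn_predictions(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        Xc, yc = centered(rng, 30, 12)
        model = fit_pls(Xc, yc, 4)
        ref = sklearn.PLSRegression(n_components=4, scale=False).fit(Xc, yc)
        np.testing.assert_allclose(
            Xc @ model.coef_b, ref.predict(Xc).ravel(), rtol=1e-6, atol=1e-8
        )

    def test_training_rmse_non_increasing_in_components(self, rng):
        Xc, yc = centered(rng, 30, 10)
        errs = [rmse(yc, Xc @ fit_pls(Xc, yc, a).coef_b) for a in range(1, 9)]
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))

    def test_rank_deficiency_stops_early(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(12, 2))
        Xc = np.hstack([base, base @ rng.normal(size=(2, 3))])  # rank 2
        Xc -= Xc.mean(axis=0)
        yc = Xc[:, 0] - Xc[:, 3]
        model = fit_pls(Xc, yc, 5)
        assert model.n_lv <= 2

    def test_invalid_component_counts(self, rng):
        Xc, yc = centered(rng, 10, 4)
        with pytest.raises(ValueError):
            fit_pls(Xc, yc, 0)
        with pytest.raises(ValueError):
            fit_pls(Xc, yc, 10)


class TestPredict:
    def test_calibration_predictions_reproduced(self, rng):
        X = rng.normal(size=(15, 5)) + 3.0
        y = rng.normal(size=15) + 100.0
        tr = CenteringTransform(X.mean(axis=0), float(y.mean()))
        model = fit_pls(tr.center_x(X), tr.center_y(y), 3, centering=tr)
        np.testing.assert_allclose(
            predict(model, X), tr.center_x(X) @ model.coef_b + tr.y_mean
        )

    def test_mean_spectrum_predicts_mean_response(self, rng):
        X = rng.normal(size=(15, 5))
        y = rng.normal(size=15) + 50.0
        tr = CenteringTransform(X.mean(axis=0), float(y.mean()))
        model = fit_pls(tr.center_x(X), tr.center_y(y), 2, centering=tr)
        np.testing.assert_allclose(predict(model, X.mean(axis=0)), [tr.y_mean], atol=1e-10)

    def test_hand_computed_case(self):
        # one channel, slope exactly y = 3x: b = cov/var = 3
        Xc = np.array([[-1.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        yc = np.array([-3.0, 0.0, 3.0])
        model = fit_pls(Xc, yc, 1)
        np.testing.assert_allclose(model.coef_b, [3.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(predict(model, [[2.0, 5.0]]), [6.0], atol=1e-12)

    def test_channel_count_mismatch(self, rng):
        Xc, yc = centered(rng, 10, 4)
        model = fit_pls(Xc, yc, 2)
        with pytest.raises(ValueError):
            predict(model, np.zeros((3, 5)))


class TestCrossValidation:
    def test_same_seed_reproduces_folds_and_curve(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        a = kfold_cv(X, y, 5, 6, seed=42)
        b = kfold_cv(X, y, 5, 6, seed=42)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
        np.testing.assert_array_equal(a.rmsecv_by_nlv, b.rmsecv_by_nlv)

    def test_every_sample_predicted_once(self, rng):
        X = rng.normal(size=(17, 4))
        y = rng.normal(size=17)
        cv = kfold_cv(X, y, 5, 3, seed=0)
        counts = np.bincount(cv.fold_assignment, minlength=5)
        assert counts.sum() == 17 and counts.min() >= 3

    def test_one_factor_data_prefers_one_component(self, rng):
        # rank-1 X driven by a single latent factor that also drives y:
        # one component is exact, and ties at higher counts break low
        t = rng.normal(size=20)
        X = np.outer(t, rng.normal(size=5))
        y = 2.0 + 3.0 * t
        cv = kfold_cv(X, y, 5, 5, seed=0)
        assert cv.chosen_nlv == 1
        assert cv.rmsecv <= 1e-8

    def test_duplicated_samples_give_near_training_error(self, rng):
        # duplicate every sample; folds separating the two copies make the
        # out-of-fold prediction a training prediction of the other copy
        X0 = rng.normal(size=(10, 4))
        y0 = X0 @ rng.normal(size=4) + rng.normal(scale=0.05, size=10)
        X = np.vstack([X0, X0])
        y = np.concatenate([y0, y0])
        from ivspec import _kernels

        fold_ids = np.concatenate([np.zeros(10, np.int64), np.ones(10, np.int64)])
        preds, cap = _kernels.cv_predictions(X, y, fold_ids, 2, 4)
        # training the full model on one copy and predicting the other is the
        # same fit: out-of-fold error equals the training error of that fit
        from _oracles import naive_pls1

        xm = X0.mean(axis=0)
        coef, _, _ = naive_pls1(X0 - xm, y0 - y0.mean(), 4)
        train_pred = (X0 - xm) @ coef + y0.mean()
        np.testing.assert_allclose(preds[:10, 3], train_pred, rtol=1e-8)

    def test_max_nlv_capped_by_fold_capacity(self, rng):
        X = rng.normal(size=(8, 6))
        y = rng.normal(size=8)
        cv = kfold_cv(X, y, 4, 10, seed=0)
        # smallest training fold has 6 samples -> at most 5 components
        assert cv.rmsecv_by_nlv.size == 5


class TestMetrics:
    def test_hand_computed_cases(self):
        y = np.array([1.0, 2.0, 3.0])
        yhat = np.array([1.0, 2.0, 6.0])
        assert abs(rmse(y, yhat) - np.sqrt(3.0)) <= 1e-12
        assert abs(q2(y, yhat) - (-3.5)) <= 1e-12
        assert abs(sd_over_runs(y) - 1.0) <= 1e-12

    def test_perfect_and_mean_predictors(self, rng):
        y = rng.normal(size=10)
        assert rmse(y, y) == 0.0
        assert q2(y, y) == 1.0
        assert abs(q2(y, np.full(10, y.mean()))) <= 1e-12

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            q2(np.ones(5), np.zeros(5))

    def test_sd_requires_two_values(self):
        assert sd_over_runs([4.0, 4.0, 4.0]) == 0.0
        with pytest.raises(ValueError):
            sd_over_runs([1.0])

    @given(st.integers(0, 2**31 - 1))
    def test_q2_rmse_identity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        y = rng.normal(size=n)
        yhat = rng.normal(size=n)
        tss = np.sum((y - y.mean()) ** 2)
        expected = 1.0 - n * rmse(y, yhat) ** 2 / tss
        assert abs(q2(y, yhat) - expected) <= 1e-10

    @given(st.floats(0.01, 100.0), st.integers(0, 2**31 - 1))
    def test_scale_equivariance(self, s, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=12)
        yhat = rng.normal(size=12)
        assert np.isclose(rmse(s * y, s * yhat), s * rmse(y, yhat), rtol=1e-10)
        assert np.isclose(q2(s * y, s * yhat), q2(y, yhat), rtol=1e-9, atol=1e-9)


def test_model_dump_contains_coefficients(rng):
    Xc = rng.normal(size=(10, 3))
    Xc -= Xc.mean(axis=0)
    yc = rng.normal(size=10)
    yc -= yc.mean()
    model = fit_pls(Xc, yc, 2)
    text = dump_model(model)
    assert text.startswith("n_lv=2")
    assert "coef_b=" in text
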