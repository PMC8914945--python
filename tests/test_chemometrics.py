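"""Calibration-model tests against independent linear-algebra oracles."""

from __future__ import annotations

import numpy as np
import pytest

import lsratio as lr
from lsratio.errors import (
    InvalidParameterError,
    UndefinedMetricError,
)


def _ols_oracle(X, Y):
    """Least squares via normal equations on centered data (pinv for rank)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    B = np.linalg.pinv(Xc.T @ Xc) @ Xc.T @ Yc
    return lambda Xn: (Xn - X.mean(axis=0)) @ B + Y.mean(axis=0)


def _random_instance(rng, n, p, m=1, rank=None):
    rank = rank or min(n - 1, p)
    X = rng.normal(size=(n, rank)) @ rng.normal(size=(rank, p))
    B = rng.normal(size=(p, m))
    Y = X @ B + 0.1 * rng.normal(size=(n, m))
    return X, Y


class TestPCR:
    def test_exact_linear_recovery_at_rank(self, rng):
        X = rng.normal(size=(12, 2)) @ rng.normal(size=(2, 6))
        Y = X @ rng.normal(size=(6, 2))
        model = lr.fit_pcr(X, Y, 2)
        np.testing.assert_allclose(lr.predict(model, X), Y, atol=1e-8)

    def test_full_rank_matches_least_squares_oracle(self, rng):
        X, Y = _random_instance(rng, 10, 4, m=2)
        model = lr.fit_pcr(X, Y, 4)
        oracle = _ols_oracle(X, Y)
        Xn = rng.normal(size=(5, 4))
        np.testing.assert_allclose(lr.predict(model, Xn), oracle(Xn), rtol=1e-8, atol=1e-10)

    def test_constant_response_predicts_its_mean(self, rng):
        X = rng.normal(size=(9, 5))
        Y = np.full((9, 1), 3.3)
        model = lr.fit_pcr(X, Y, 3)
        assert np.allclose(model.coefficients, 0.0)
        np.testing.assert_allclose(lr.predict(model, rng.normal(size=(4, 5))), 3.3)

    def test_factor_count_bounds_enforced(self, rng):
        X, Y = _random_instance(rng, 8, 5)
        with pytest.raises(InvalidParameterError):
            lr.fit_pcr(X, Y, 8)

    def test_zero_variance_inputs_rejected(self):
        X = np.ones((6, 4))
        Y = np.arange(6.0)[:, None]
        with pytest.raises(lr.errors.DegenerateInputError):
            lr.fit_pcr(X, Y, 1)


class TestPLSR:
    def test_full_rank_matches_least_squares_oracle(self, rng):
        X, Y = _random_instance(rng, 12, 5, m=1)
        model = lr.fit_plsr(X, Y, 5)
        oracle = _ols_oracle(X, Y)
        Xn = rng.normal(size=(6, 5))
        np.testing.assert_allclose(lr.predict(model, Xn), oracle(Xn), rtol=1e-6, atol=1e-8)

    def test_first_weight_is_dominant_singular_vector_of_cross_covariance(self, rng):
        X, Y = _random_instance(rng, 8, 6, m=2)
        model = lr.fit_plsr(X, Y, 2)
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        U, _, _ = np.linalg.svd(Xc.T @ Yc, full_matrices=False)
        w1 = model.weights[:, 0]
        cosine = abs(w1 @ U[:, 0]) / (np.linalg.norm(w1) * np.linalg.norm(U[:, 0]))
        assert cosine == pytest.approx(1.0, abs=1e-8)

    def test_constant_response_gives_zero_coefficients(self, rng):
        X = rng.normal(size=(10, 6))
        Y = np.full((10, 2), 1.0)
        model = lr.fit_plsr(X, Y, 3)
        assert np.allclose(model.coefficients, 0.0)
        np.testing.assert_allclose(lr.predict(model, rng.normal(size=(3, 6))), 1.0)

    def test_mixed_constant_and_varying_responses(self, rng):
        """A zero-variance column (fixed SM) must not disturb the other."""
        X, y = _random_instance(rng, 15, 7, m=1)
        Y = np.hstack([y, np.ones((15, 1))])
        model = lr.fit_plsr(X, Y, 4)
        pred = lr.predict(model, X)
        assert np.array_equal(pred[:, 1], np.ones(15))
        solo = lr.fit_plsr(X, y, 4)
        np.testing.assert_allclose(pred[:, 0], lr.predict(solo, X)[:, 0], rtol=1e-8)

    def test_pcr_plsr_ols_coincide_at_full_rank(self, rng):
        """At full rank all three linear fits give the same predictions."""
        for trial in range(3):
            n, p = rng.integers(8, 20), rng.integers(3, 8)
            X, Y = _random_instance(rng, int(n), int(p), m=2)
            k = min(int(n) - 1, int(p))
            oracle = _ols_oracle(X, Y)(X)
            np.testing.assert_allclose(
                lr.predict(lr.fit_pcr(X, Y, k), X), oracle, rtol=1e-6, atol=1e-8
            )
            np.testing.assert_allclose(
                lr.predict(lr.fit_plsr(X, Y, k), X), oracle, rtol=1e-6, atol=1e-8
            )


class TestModelAlgebra:
    def test_training_mse_nonincreasing_in_factor_count(self, rng):
        X, Y = _random_instance(rng, 20, 8, m=1)
        for fit in (lr.fit_pcr, lr.fit_plsr):
            model = fit(X, Y, 6)
            mses = []
            for k in range(1, 7):
                pred = (X - model.x_mean) @ model.coefficients_for(k) + model.y_mean
                mses.append(float(np.mean((Y - pred) ** 2)))
            assert all(b <= a + 1e-12 for a, b in zip(mses, mses[1:]))

    def test_scale_equivariance(self, rng):
        X, Y = _random_instance(rng, 10, 5, m=1)
        for fit in (lr.fit_pcr, lr.fit_plsr):
            base = lr.predict(fit(X, Y, 3), X)
            scaled = lr.predict(fit(X, 7.5 * Y, 3), X)
            np.testing.assert_allclose(scaled, 7.5 * base, rtol=1e-9)

    def test_row_permutation_invariance(self, rng):
        X, Y = _random_instance(rng, 11, 5, m=2)
        perm = rng.permutation(11)
        for fit in (lr.fit_pcr, lr.fit_plsr):
            a = fit(X, Y, 3).coefficients
            b = fit(X[perm], Y[perm], 3).coefficients
            np.testing.assert_allclose(a, b, atol=1e-10)

    def test_predict_training_mean_returns_y_mean(self, rng):
        X, Y = _random_instance(rng, 10, 4, m=2)
        model = lr.fit_plsr(X, Y, 2)
        np.testing.assert_allclose(
            lr.predict(model, X.mean(axis=0)[None, :]), Y.mean(axis=0)[None, :], atol=1e-12
        )

    def test_batch_prediction_matches_row_at_a_time(self, rng):
        X, Y = _random_instance(rng, 10, 4)
        model = lr.fit_pcr(X, Y, 3)
        Xn = rng.normal(size=(6, 4))
        batch = lr.predict(model, Xn)
        rows = np.vstack([lr.predict(model, Xn[i : i + 1]) for i in range(6)])
        # identical up to BLAS summation order
        np.testing.assert_allclose(batch, rows, rtol=1e-12)

    def test_feature_mismatch_raises(self, rng):
        X, Y = _random_instance(rng, 10, 4)
        model = lr.fit_pcr(X, Y, 2)
        with pytest.raises(InvalidParameterError):
            lr.predict(model, np.zeros((2, 5)))

    def test_json_round_trip(self, tmp_path, rng):
        X, Y = _random_instance(rng, 10, 4, m=2)
        model = lr.fit_plsr(X, Y, 3, response_names=("DPPC", "SM"))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = lr.LatentModel.from_json(path)
        assert back.kind == "plsr" and back.n_factors == 3
        assert back.response_names == ("DPPC", "SM")
        np.testing.assert_array_equal(back.coefficients, model.coefficients)
        Xn = rng.normal(size=(4, 4))
        np.testing.assert_array_equal(lr.predict(back, Xn), lr.predict(model, Xn))


class TestAgainstSklearnOracle:
    """Cross-checks against scikit-learn's independent implementations."""

    def test_plsr_matches_sklearn_pls2(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X, Y = _random_instance(rng, 18, 9, m=2)
        for k in (1, 2, 3):
            ours = lr.predict(lr.fit_plsr(X, Y, k), X)
            ref = (
                PLSRegression(n_components=k, scale=False, tol=1e-12, max_iter=2000)
                .fit(X, Y)
                .predict(X)
            )
            # both stop their inner power iterations at finite tolerance,
            # so agreement is to ~1e-5, not machine precision
            np.testing.assert_allclose(ours, ref, rtol=1e-4, atol=1e-5)

    def test_pcr_matches_pca_plus_ols(self, rng):
        from sklearn.decomposition import PCA
        from sklearn.linear_model import LinearRegression

        X, Y = _random_instance(rng, 15, 7, m=2)
        for k in (1, 3, 5):
            ours = lr.predict(lr.fit_pcr(X, Y, k), X)
            scores = PCA(n_components=k).fit_transform(X)
            ref = LinearRegression().fit(scores, Y).predict(scores)
            np.testing.assert_allclose(ours, ref, rtol=1e-6, atol=1e-8)


class TestScore:
    def test_perfect_prediction(self):
        m = lr.score([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.r2, m.mse) == (1.0, 0.0)

    def test_mean_prediction_scores_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = lr.score(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0)

    def test_hand_computed_example(self):
        m = lr.score([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert m.mse == pytest.approx(1.0 / 3.0)
        assert m.r2 == pytest.approx(0.5)

    def test_constant_truth_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            lr.score([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
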