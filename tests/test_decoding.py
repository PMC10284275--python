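"""LASSO fitting, penalty selection, repeated CV and correlation maps."""

import numpy as np
import pytest

from elevdec.decoding import (
    CVConfig,
    DecodingError,
    correlation_map,
    cross_validated_decode,
    fit_lasso,
    lambda_max,
    make_lambda_grid,
    nmse,
    select_lambda,
)


def ista_lasso(X, y, lam, n_iter=200_000, tol=1e-14):
    """Independent proximal-gradient reference for
    min ||y - Xw - b||^2 + lam*||w||_1 (used only as a test oracle)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    w = np.zeros(p)
    b = y.mean()
    step = 1.0 / (2 * np.linalg.norm(X, 2) ** 2)
    for _ in range(n_iter):
        grad = 2 * X.T @ (X @ w + b - y)
        w_new = np.sign(w - step * grad) * np.maximum(
            np.abs(w - step * grad) - step * lam, 0.0)
        b_new = float(np.mean(y - X @ w_new))
        if max(np.max(np.abs(w_new - w)), abs(b_new - b)) < tol:
            w, b = w_new, b_new
            break
        w, b = w_new, b_new
    return w, b


def planted_data(rng, n=300, p=8, k=5, r2=0.25):
    """y = X w* + noise with population R^2 = r2 (unit signal variance)."""
    X = rng.normal(size=(n, p))
    w = np.zeros(p)
    w[:k] = rng.choice([-1.0, 1.0], k) / np.sqrt(k)
    noise_sd = np.sqrt((1 - r2) / r2)
    y = X @ w + noise_sd * rng.normal(size=n)
    return X, y, w


class TestFitLasso:
    def test_zero_penalty_equals_least_squares(self, rng):
        X = rng.normal(size=(60, 5))
        y = rng.normal(size=60)
        m = fit_lasso(X, y, 0.0)
        A = np.column_stack([X, np.ones(60)])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(m.coef, beta[:-1], rtol=1e-6)
        assert m.intercept == pytest.approx(beta[-1], rel=1e-6)

    def test_above_lambda_max_all_zero_and_mean_prediction(self, rng):
        X = rng.normal(size=(50, 6))
        X = (X - X.mean(0)) / X.std(0)
        y = rng.normal(size=50)
        lmax = lambda_max(X, y)
        m = fit_lasso(X, y, lmax * 1.001)
        assert np.all(m.coef == 0)
        np.testing.assert_allclose(m.predict(X), np.full(50, y.mean()))

    def test_path_support_non_increasing_in_lambda(self, rng):
        """Support size shrinks (allowing ties) as the penalty grows."""
        X, y, _ = planted_data(rng, n=80)
        grid = make_lambda_grid(X, y, n_lambdas=25)  # descending
        counts = [np.count_nonzero(fit_lasso(X, y, lam).coef) for lam in grid]
        assert all(c0 <= c1 for c0, c1 in zip(counts, counts[1:]))
        assert counts[0] == 0  # at lambda_max nothing enters

    def test_matches_independent_proximal_gradient(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        lmax = lambda_max(X, y)
        for lam in (0.5 * lmax, 0.1 * lmax, 0.01 * lmax):
            m = fit_lasso(X, y, lam)
            w_ref, b_ref = ista_lasso(X, y, lam)
            np.testing.assert_allclose(m.coef, w_ref, atol=1e-5)
            assert m.intercept == pytest.approx(b_ref, abs=1e-5)

    def test_planted_sparse_support_recovered(self, rng):
        X = rng.normal(size=(300, 20))
        w_true = np.zeros(20)
        w_true[:5] = [2.0, -1.5, 1.0, 2.5, -2.0]
        y = X @ w_true + 0.1 * rng.normal(size=300)
        grid = make_lambda_grid(X, y)
        lam = select_lambda(X, y, grid, rng_seed=0)
        m = fit_lasso(X, y, lam)
        assert set(np.flatnonzero(w_true)) <= set(np.flatnonzero(m.coef))
        assert np.all(np.sign(m.coef[:5]) == np.sign(w_true[:5]))

    def test_input_validation(self, rng):
        with pytest.raises(DecodingError):
            fit_lasso(np.zeros((0, 3)), np.zeros(0), 1.0)
        with pytest.raises(DecodingError):
            fit_lasso(np.full((5, 2), np.nan), np.zeros(5), 1.0)
        with pytest.raises(DecodingError):
            fit_lasso(rng.normal(size=(5, 2)), np.zeros(5), -1.0)


class TestNMSE:
    def test_conventions(self, rng):
        y = rng.normal(size=40)
        assert nmse(y, y) == 0.0
        assert nmse(y, np.full(40, y.mean())) == pytest.approx(1.0)
        assert nmse(np.array([0.0, 2.0]), np.array([1.0, 1.0])) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DecodingError):
            nmse(np.ones(5), np.zeros(5))


class TestSelectLambda:
    def test_single_point_grid(self, rng):
        X, y, _ = planted_data(rng, n=50)
        assert select_lambda(X, y, [0.7]) == 0.7

    def test_noiseless_data_prefers_small_lambda(self, rng):
        X = rng.normal(size=(100, 6))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 0.0, 3.0])
        grid = make_lambda_grid(X, y, n_lambdas=30)
        lam = select_lambda(X, y, grid, rng_seed=1)
        assert lam <= grid[len(grid) // 2]  # lower half of the grid

    def test_pure_noise_prefers_large_lambda(self, rng):
        X = rng.normal(size=(100, 6))
        y = rng.normal(size=100)
        grid = make_lambda_grid(X, y, n_lambdas=30)
        lam = select_lambda(X, y, grid, rng_seed=1)
        assert lam >= grid[len(grid) // 2]  # upper half of the grid

    def test_degenerate_target_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(DecodingError):
            select_lambda(X, np.ones(20), [1.0, 0.5])


class TestCrossValidatedDecode:
    def test_deterministic_under_fixed_seed(self, rng):
        X, y, _ = planted_data(rng, n=60, p=6)
        cfg = CVConfig(n_repeats=3, rng_seed=42)
        a = cross_validated_decode(X, y, cfg)
        b = cross_validated_decode(X, y, cfg)
        assert a.fold_metrics.equals(b.fold_metrics)
        np.testing.assert_array_equal(a.final_model.coef, b.final_model.coef)

    def test_null_data_mean_r_near_zero(self, rng):
        """Decoding pure noise gives mean r consistent with 0.

        Fold-level r values within one dataset are correlated (repeats
        re-partition the same data), so the 2-SE check is made across
        independent datasets.
        """
        means = []
        for _ in range(6):
            X = rng.normal(size=(120, 10))
            y = rng.normal(size=120)
            res = cross_validated_decode(X, y,
                                         CVConfig(n_repeats=5, rng_seed=3))
            r = res.fold_metrics["r"].dropna()
            if len(r):
                means.append(r.mean())
        assert len(means) >= 4
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 2 * se + 0.02

    def test_planted_r2_recovered(self, rng):
        """Mean CV r approaches sqrt(R^2) = 0.5 averaged over data draws."""
        means = []
        for _ in range(5):
            X, y, _ = planted_data(rng, n=300, p=8, k=5, r2=0.25)
            res = cross_validated_decode(X, y,
                                         CVConfig(n_repeats=4, rng_seed=7))
            means.append(res.summary()["r_mean"])
        # draw-level sd of r is ~0.05, so the mean of 5 draws has SE ~0.025
        assert np.mean(means) == pytest.approx(0.5, abs=0.06)

    def test_shuffled_target_degrades_r(self, rng):
        X, y, _ = planted_data(rng, n=200, p=8, r2=0.5)
        cfg = CVConfig(n_repeats=5, rng_seed=11)
        real = cross_validated_decode(X, y, cfg).summary()["r_mean"]
        y_perm = y[rng.permutation(len(y))]
        shuf = cross_validated_decode(X, y_perm, cfg).fold_metrics["r"].dropna()
        assert real > 0.5
        shuf_mean = float(shuf.abs().mean()) if len(shuf) else 0.0
        assert shuf_mean < real - 0.2

    def test_misaligned_inputs_rejected(self, rng):
        with pytest.raises(DecodingError):
            cross_validated_decode(rng.normal(size=(20, 3)),
                                   rng.normal(size=19), CVConfig(n_repeats=1))


class TestCorrelationMap:
    def test_identical_column_is_significant(self, rng):
        X = rng.normal(size=(50, 6))
        y = X[:, 2].copy()
        out = correlation_map(X, y)
        assert out.loc[2, "r"] == pytest.approx(1.0)
        assert out.loc[2, "significant"]

    def test_constant_column_gets_nan(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 1] = 5.0
        out = correlation_map(X, X[:, 0] + rng.normal(size=30))
        assert np.isnan(out.loc[1, "r"]) and not out.loc[1, "significant"]

    def test_planted_negative_modulation_flagged(self, rng):
        n = 300
        latent = np.sin(np.linspace(0, 8 * np.pi, n))
        X = rng.normal(size=(n, 12))
        X[:, 4] = -latent + 0.4 * rng.normal(size=n)
        X[:, 9] = -latent + 0.4 * rng.normal(size=n)
        out = correlation_map(X, latent)
        assert out.loc[4, "significant"] and out.loc[4, "r"] < 0
        assert out.loc[9, "significant"] and out.loc[9, "r"] < 0

    def test_familywise_error_controlled_under_null(self, rng):
        """Bonferroni keeps the expected significant count near alpha."""
        n_sims, counts = 100, []
        for _ in range(n_sims):
            X = rng.normal(size=(60, 20))
            y = rng.normal(size=60)
            counts.append(int(correlation_map(X, y)["significant"].sum()))
        rate = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(n_sims)
        assert rate <= 0.05 + 2 * se + 1e-9

    def test_matches_scipy_pearson(self, rng):
        from scipy import stats

        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        out = correlation_map(X, y)
        for j in range(3):
            r_ref, p_ref = stats.pearsonr(X[:, j], y)
            assert out.loc[j, "r"] == pytest.approx(r_ref)
            assert out.loc[j, "p"] == pytest.approx(p_ref)
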