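"""NIPALS PLS: identities, invariants, oracle equivalence, LOO selection."""

import numpy as np
import pytest
from scipy import stats

from ctxpls import (
    explained_variance,
    fit_pls,
    gene_weights,
    loo_cv,
    score_response_report,
)

from _oracles import svd_pls_predict


def random_instance(rng, n=None, m=None, p=None):
    n = n or int(rng.integers(6, 21))
    m = m or int(rng.integers(3, 16))
    p = p or int(rng.integers(1, 4))
    return rng.normal(size=(n, m)), rng.normal(size=(n, p))


class TestFit:
    def test_noiseless_single_factor_reproduced_with_one_component(self, rng):
        t = rng.normal(size=15)
        a = rng.normal(size=8)
        X = np.outer(t, a)  # rank-1 predictors
        c = rng.normal(size=8)
        y = X @ c
        fit = fit_pls(X, y, 1)
        np.testing.assert_allclose(fit.predict(X)[:, 0], y, atol=1e-8)
        r = stats.pearsonr(fit.T[:, 0], y)[0]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_single_response_weight_is_normalized_cross_covariance(self, rng):
        X, _ = random_instance(rng, n=14, m=9)
        y = rng.normal(size=14)
        fit = fit_pls(X, y, 3)
        Xc = X - X.mean(axis=0)
        w1 = Xc.T @ (y - y.mean())
        w1 /= np.linalg.norm(w1)
        np.testing.assert_allclose(fit.W[:, 0], w1, atol=1e-10)

    def test_full_rank_limit_equals_least_squares(self, rng):
        for _ in range(20):
            X = rng.normal(size=(12, 5))
            Y = rng.normal(size=(12, 2))
            fit = fit_pls(X, Y, 5)
            design = np.column_stack([np.ones(12), X])
            coefs, *_ = np.linalg.lstsq(design, Y, rcond=None)
            np.testing.assert_allclose(fit.predict(X), design @ coefs, atol=1e-8)

    def test_predictions_match_svd_reference(self, rng):
        for _ in range(10):
            X, Y = random_instance(rng)
            K = int(min(rng.integers(1, 4), X.shape[0] - 1, X.shape[1]))
            fit = fit_pls(X, Y, K)
            np.testing.assert_allclose(
                fit.predict(X), svd_pls_predict(X, Y, K), atol=1e-8
            )

    def test_structural_invariants(self, rng):
        X, Y = random_instance(rng, n=18, m=12, p=3)
        fit = fit_pls(X, Y, 3)
        G = fit.T.T @ fit.T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-10 * np.max(np.diag(G))
        np.testing.assert_allclose(np.linalg.norm(fit.W, axis=0), 1.0, atol=1e-12)
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(Xc @ fit.R, fit.T, atol=1e-8)
        assert fit.x_explained.sum() <= 1 + 1e-8
        assert fit.y_explained.sum() <= 1 + 1e-8
        # scores positively correlated with their Y-scores by convention
        for k in range(3):
            assert fit.T[:, k] @ fit.U[:, k] >= -1e-10

    def test_centering_contract(self, rng):
        X, Y = random_instance(rng, n=15, m=8, p=2)
        fit = fit_pls(X, Y, 2)
        X2 = X.copy()
        X2[:, 3] += 100.0
        Y2 = Y + 7.5
        fit2 = fit_pls(X2, Y2, 2)
        np.testing.assert_allclose(
            fit.predict(X) + 7.5, fit2.predict(X2), atol=1e-8
        )

    def test_zero_variance_gene_gets_zero_weight(self, rng):
        X, y = random_instance(rng, n=12, m=6, p=1)
        X[:, 2] = 3.14
        fit = fit_pls(X, y, 2)
        np.testing.assert_allclose(fit.W[2, :], 0.0, atol=1e-12)
        np.testing.assert_allclose(fit.R[2, :], 0.0, atol=1e-12)

    def test_validation_errors(self, rng):
        X, Y = random_instance(rng, n=6, m=4, p=1)
        with pytest.raises(ValueError):
            fit_pls(X, Y, 6)  # K > min(n - 1, m)
        Xbad = X.copy()
        Xbad[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_pls(Xbad, Y, 1)
        with pytest.raises(ValueError):
            fit_pls(X[:2], Y[:2], 1)


class TestGeneWeights:
    def test_single_component_single_response_weight_proportional_to_w(self, rng):
        X, y = random_instance(rng, n=12, m=7, p=1)
        fit = fit_pls(X, y, 1)
        w1 = gene_weights(fit, 1)
        ratio = w1 / fit.W[:, 0]
        np.testing.assert_allclose(ratio, ratio[0], atol=1e-10)

    def test_component_out_of_range(self, rng):
        X, y = random_instance(rng, n=10, m=5, p=1)
        fit = fit_pls(X, y, 2)
        with pytest.raises(ValueError):
            gene_weights(fit, 3)
        with pytest.raises(ValueError):
            gene_weights(fit, 0)


class TestExplainedVariance:
    def test_rank_one_predictors_fully_explained_by_first_component(self, rng):
        t = rng.normal(size=10)
        X = np.outer(t, rng.normal(size=6))
        y = t + rng.normal(0, 0.1, 10)
        fit = fit_pls(X, y, 1)
        assert explained_variance(fit)["x_pct"][0] == pytest.approx(100.0, abs=1e-6)

    def test_full_rank_fractions_sum_to_one(self, rng):
        X = rng.normal(size=(10, 4))
        Y = rng.normal(size=(10, 2))
        fit = fit_pls(X, Y, 4)
        assert explained_variance(fit)["x_pct"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_noise_response_column_lowers_component1_y_fraction(self, rng):
        lower = 0
        n_seeds = 100
        for _ in range(n_seeds):
            X = rng.normal(size=(12, 6))
            y = X @ rng.normal(size=6) + rng.normal(0, 0.5, 12)
            fit1 = fit_pls(X, y, 1)
            Y2 = np.column_stack([y, rng.normal(size=12)])
            fit2 = fit_pls(X, Y2, 1)
            if fit2.y_explained[0] < fit1.y_explained[0]:
                lower += 1
        assert lower >= 0.95 * n_seeds


class TestLOO:
    def test_rmsep_press_bookkeeping_with_duplicated_rows(self, rng):
        X, Y = random_instance(rng, n=8, m=5, p=2)
        X2, Y2 = np.vstack([X, X]), np.vstack([Y, Y])
        cv = loo_cv(X2, Y2, 3)
        assert cv.n_folds_used == 16 and cv.n_folds_skipped == 0
        np.testing.assert_allclose(
            cv.rmsep, np.sqrt(cv.press / (cv.n_folds_used * 2))
        )

    def test_planted_rank_one_signal_selects_one_component(self, rng):
        hits = 0
        n_seeds = 10
        for _ in range(n_seeds):
            g = rng.normal(size=20)
            a = rng.normal(size=60)
            X = np.outer(g, a) + rng.normal(0, 0.5, (20, 60))
            y = g + rng.normal(0, 0.5 * g.std(), 20)
            cv = loo_cv(X, y, 4)
            hits += cv.optimal_components == 1
        assert hits >= 8

    def test_planted_rank_two_signal_keeps_second_component(self, rng):
        hits = 0
        for _ in range(10):
            g1, g2 = rng.normal(size=(2, 20))
            a1, a2 = rng.normal(size=(2, 60))
            sig = np.outer(g1, a1) + np.outer(g2, a2)
            X = sig + rng.normal(0, 0.1 * sig.std(), (20, 60))
            y = g1 + g2 + rng.normal(0, 0.05 * np.std(g1 + g2), 20)
            hits += loo_cv(X, y, 4).optimal_components >= 2
        assert hits >= 8

    def test_press_matches_independent_sklearn_refit_loo(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        for _ in range(3):
            X = rng.normal(size=(12, 20))
            y = X @ rng.normal(size=20) * 0.2 + rng.normal(size=12)
            cv = loo_cv(X, y, 3)
            press = np.zeros(3)
            for i in range(12):
                mask = np.ones(12, bool)
                mask[i] = False
                for k in range(1, 4):
                    model = PLSRegression(n_components=k, scale=False)
                    model.fit(X[mask], y[mask])
                    pred = float(np.ravel(model.predict(X[i : i + 1]))[0])
                    press[k - 1] += (y[i] - pred) ** 2
            # sklearn's inner loop converges to ~1e-3; agreement is at
            # that precision, and the argmin ranking must coincide
            np.testing.assert_allclose(cv.press[1:], press, rtol=1e-4)
            assert cv.argmin_components == 1 + int(np.argmin(press))

    def test_pure_noise_response_prefers_few_components(self, rng):
        optima = []
        for _ in range(20):
            X = rng.normal(size=(15, 10))
            y = rng.normal(size=15)
            cv = loo_cv(X, y, 4)
            optima.append(cv.optimal_components)
            assert 1 <= cv.optimal_components <= cv.argmin_components
        assert np.median(optima) <= 2
        assert (np.asarray(optima) == 1).mean() >= 0.5

    def test_validation(self, rng):
        X, y = random_instance(rng, n=10, m=6, p=1)
        with pytest.raises(ValueError):
            loo_cv(X, y, 9)
        with pytest.raises(ValueError):
            loo_cv(X[:3], y[:3], 1)


class TestScoreResponseReport:
    def test_single_response_r_equals_score_correlation(self, rng):
        X, y = random_instance(rng, n=14, m=8, p=1)
        fit = fit_pls(X, y, 1)
        comps, resps = score_response_report(fit, y)
        direct = stats.pearsonr(fit.T[:, 0], y[:, 0])[0]
        assert resps.r.iloc[0] == pytest.approx(direct, abs=1e-12)
        # u_1 is proportional to the centered single response
        assert comps.r_t_u.iloc[0] == pytest.approx(abs(direct), abs=1e-10)

    def test_q_sign_matches_correlation_sign(self, rng):
        for _ in range(20):
            X, Y = random_instance(rng, n=16, m=10, p=3)
            fit = fit_pls(X, Y, 2)
            _, resps = score_response_report(fit, Y)
            strong = resps[resps.r.abs() > 0.15]
            assert (np.sign(strong.q_loading) == np.sign(strong.r)).all()

    def test_duplicated_response_column_reports_identically(self, rng):
        X, y = random_instance(rng, n=12, m=6, p=1)
        Y = np.column_stack([y, y])
        fit = fit_pls(X, Y, 2)
        _, resps = score_response_report(fit, Y)
        for k in (1, 2):
            sub = resps[resps.component == k]
            assert sub.r.iloc[0] == pytest.approx(sub.r.iloc[1], abs=1e-12)
            assert sub.q_loading.iloc[0] == pytest.approx(sub.q_loading.iloc[1], abs=1e-12)

    def test_zero_variance_response_flagged(self, rng):
        X, y = random_instance(rng, n=10, m=5, p=1)
        Y = np.column_stack([y, np.full(10, 2.0)])
        fit = fit_pls(X, Y, 1)
        _, resps = score_response_report(fit, Y)
        assert resps.flag.iloc[1] == "zero-variance"
        assert np.isnan(resps.r.iloc[1])
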