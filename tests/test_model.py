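import numpy as np
import pytest

from phredlogit.model import (
    CollinearityError,
    SeparationError,
    aic,
    backward_eliminate,
    bic,
    drop_aliased_columns,
    fit_l1,
    fit_mle,
    l1_path,
    log_likelihood,
    select_lambda_cv,
    t_scores,
)


def simulate_logistic(seed, n, beta, intercept=0.0):
    rng = np.random.default_rng(seed)
    p = len(beta)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
    full = np.r_[intercept, beta]
    prob = 1 / (1 + np.exp(-(X @ full)))
    y = (rng.random(n) < prob).astype(int)
    return X, y, full


class TestLogLikelihood:
    def test_symmetric_point(self):
        assert log_likelihood([0.0], np.ones((1, 1)), [1]) == pytest.approx(np.log(0.5))

    def test_additivity(self):
        ll = log_likelihood([0.0], np.ones((2, 1)), [1, 0])
        assert ll == pytest.approx(2 * np.log(0.5))

    def test_perfect_prediction_limit(self):
        assert log_likelihood([50.0], np.ones((1, 1)), [1]) == pytest.approx(0.0, abs=1e-12)

    def test_wrong_saturation_is_minus_inf(self):
        assert log_likelihood([np.inf], np.ones((1, 1)), [0]) == -np.inf


class TestFitMle:
    def test_intercept_only_closed_form(self):
        m, rep = fit_mle(np.ones((4, 1)), [1, 1, 1, 0])
        assert rep.converged
        assert m.beta[0] == pytest.approx(np.log(3), abs=1e-6)

    def test_constant_labels_raise_separation(self):
        with pytest.raises(SeparationError):
            fit_mle(np.ones((5, 1)), [1, 1, 1, 1, 1])

    def test_separable_data_detected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        X = np.column_stack([np.ones(200), x])
        with pytest.raises(SeparationError):
            fit_mle(X, (x > 0).astype(int))

    def test_collinear_design_named(self):
        X = np.column_stack([np.ones(50), np.arange(50.0), 2 * np.arange(50.0)])
        y = (np.arange(50) % 2).astype(int)
        with pytest.raises(CollinearityError, match="f2|f1"):
            fit_mle(X, y, feature_names=["f0", "f1", "f2"])

    def test_parameter_recovery_within_three_se(self):
        X, y, truth = simulate_logistic(5, 50_000, [0.8, -0.5, 0.0], intercept=1.0)
        m, rep = fit_mle(X, y)
        prob = 1 / (1 + np.exp(-(X @ m.beta)))
        H = (X * (prob * (1 - prob))[:, None]).T @ X
        se = np.sqrt(np.diag(np.linalg.inv(H)))
        assert np.all(np.abs(m.beta - truth) < 3 * se)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        X, y, _ = simulate_logistic(7, 2_000, [0.5, -1.0, 0.2])
        m, _ = fit_mle(X, y)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.allclose(m.beta, ref.params, atol=1e-6)

    def test_matches_grid_search_oracle_on_tiny_problem(self):
        """Iteratively refined 2-D grid search over the likelihood agrees
        with IRLS to 1e-3."""
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(15), rng.normal(size=15)])
        y = (rng.random(15) < 0.5).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        center, width = np.zeros(2), 8.0
        for _ in range(7):
            g0 = np.linspace(center[0] - width, center[0] + width, 21)
            g1 = np.linspace(center[1] - width, center[1] + width, 21)
            lls = [[log_likelihood([a, b], X, y) for b in g1] for a in g0]
            i, j = np.unravel_index(np.argmax(lls), (21, 21))
            center, width = np.array([g0[i], g1[j]]), width / 5
        m, _ = fit_mle(X, y)
        assert np.allclose(m.beta, center, atol=1e-3)


def test_information_criteria_formulas():
    assert aic(2, -50.0) == 104.0
    assert bic(2, 100, -50.0) == pytest.approx(2 * np.log(100) + 100)
    assert aic(0, -50.0) == 100.0


class TestBackwardElimination:
    def test_pure_noise_column_removed_under_bic(self):
        X, y, _ = simulate_logistic(11, 5_000, [1.0, 0.0])
        m, rep = backward_eliminate(X, y, criterion="bic",
                                    feature_names=["x0", "sig", "noise"])
        assert "noise" not in m.support
        assert "sig" in m.support

    def test_strong_column_retained_by_both_criteria(self):
        X, y, _ = simulate_logistic(13, 10_000, [1.5])
        for crit in ("aic", "bic"):
            m, _ = backward_eliminate(X, y, criterion=crit)
            assert m.k == 2

    def test_already_minimal_model_has_empty_trace(self):
        X, y, _ = simulate_logistic(17, 10_000, [1.5])
        _, rep = backward_eliminate(X, y, criterion="aic")
        assert rep.deletion_trace == []

    def test_criterion_strictly_decreases_along_trace(self):
        X, y, _ = simulate_logistic(19, 3_000, [1.0, 0.0, 0.0, 0.1, 0.0])
        m, rep = backward_eliminate(X, y, criterion="bic")
        crits = [c for _, c in rep.deletion_trace]
        assert all(b < a for a, b in zip(crits, crits[1:]))
        # and the returned model beats every intermediate value
        assert all(bic(m.k, len(y), m.loglik) <= c + 1e-9 for c in crits)

    def test_intercept_never_removed(self):
        X, y, _ = simulate_logistic(23, 2_000, [0.0, 0.0])
        m, _ = backward_eliminate(X, y, criterion="bic")
        assert "x0" in m.support


class TestL1:
    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            fit_l1(np.ones((4, 1)), [0, 1, 0, 1], -1.0)

    def test_large_lambda_gives_null_model_with_mle_intercept(self):
        X, y, _ = simulate_logistic(29, 1_000, [0.5, -0.5])
        m = fit_l1(X, y, 1e8)
        assert m.support == ["x0"]
        pbar = y.mean()
        assert m.beta[0] == pytest.approx(np.log(pbar / (1 - pbar)), abs=1e-5)

    def test_lambda_zero_matches_mle(self):
        X, y, _ = simulate_logistic(31, 2_000, [0.7, -0.3, 0.1])
        m0 = fit_l1(X, y, 0.0)
        mm, _ = fit_mle(X, y)
        assert np.allclose(m0.beta, mm.beta, atol=1e-4)

    def test_sparsity_monotone_along_lambda_grid(self):
        X, y, _ = simulate_logistic(37, 5_000, [1.0, -0.8, 0.5, 0.0, 0.0, 0.2])
        grid = [0.1, 1.0, 10.0, 100.0, 1000.0]
        ks = [m.k for m in l1_path(X, y, grid)]
        assert all(b <= a for a, b in zip(ks, ks[1:]))

    def test_matches_sklearn_saga_oracle(self):
        from sklearn.linear_model import LogisticRegression

        X, y, _ = simulate_logistic(41, 3_000, [1.0, -0.8, 0.0, 0.3])
        lam = 20.0
        m = fit_l1(X, y, lam)
        ref = LogisticRegression(penalty="l1", C=1.0 / lam, solver="saga",
                                 tol=1e-8, max_iter=20_000)
        ref.fit(X[:, 1:], y)
        expected = np.r_[ref.intercept_, ref.coef_[0]]
        assert np.allclose(m.beta, expected, atol=2e-3)

    def test_elastic_net_matches_sklearn(self):
        from sklearn.linear_model import LogisticRegression

        X, y, _ = simulate_logistic(43, 3_000, [1.0, -0.8, 0.0, 0.3])
        lam, alpha = 20.0, 0.5
        m = fit_l1(X, y, lam, alpha=alpha)
        assert m.method == "elastic_net"
        ref = LogisticRegression(penalty="elasticnet", C=1.0 / lam,
                                 l1_ratio=alpha, solver="saga", tol=1e-8,
                                 max_iter=20_000)
        ref.fit(X[:, 1:], y)
        expected = np.r_[ref.intercept_, ref.coef_[0]]
        assert np.allclose(m.beta, expected, atol=2e-3)


class TestSelectLambdaCV:
    def test_single_value_grid_returned(self):
        X, y, _ = simulate_logistic(47, 600, [1.0])
        assert select_lambda_cv(X, y, [3.5], folds=3, seed=0) == 3.5

    def test_deterministic_given_seed(self):
        X, y, _ = simulate_logistic(53, 2_000, [1.0, 0.0, 0.5])
        grid = [0.5, 5.0, 50.0, 500.0]
        a = select_lambda_cv(X, y, grid, seed=7)
        b = select_lambda_cv(X, y, grid, seed=7)
        assert a == b

    def test_cv_choice_beats_null_model(self):
        X, y, _ = simulate_logistic(59, 4_000, [1.2, 0.0, -0.9] + [0.0] * 10)
        grid = [1.0, 10.0, 100.0, 1e6]
        lam, info = select_lambda_cv(X, y, grid, seed=3, full_output=True)
        aucs = dict(zip(info["lambdas"], info["mean_auc"]))
        assert aucs[lam] >= aucs[1e6]

    def test_single_class_fold_impossible(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = np.array([1] * 9 + [0])
        with pytest.raises(ValueError, match="folds"):
            select_lambda_cv(X, y, [1.0], folds=5, seed=0)


class TestTScores:
    def test_intercept_only_closed_form(self):
        n = 400
        y = np.r_[np.ones(300), np.zeros(100)].astype(int)
        m, _ = fit_mle(np.ones((n, 1)), y, feature_names=["x0"])
        t = t_scores(m, np.ones((n, 1)), y)
        phat = 0.75
        expected = np.log(phat / (1 - phat)) * np.sqrt(n * phat * (1 - phat))
        assert t["x0"] == pytest.approx(expected, rel=1e-6)

    def test_unsupported_features_have_no_t_score(self):
        X, y, _ = simulate_logistic(61, 2_000, [1.0, 0.0])
        m = fit_l1(X, y, 200.0, feature_names=["x0", "a", "b"])
        t = t_scores(m, X, y)
        assert set(t) == set(m.support)

    def test_strong_positive_effect_has_positive_t(self):
        X, y, _ = simulate_logistic(67, 5_000, [1.5])
        m, _ = fit_mle(X, y, feature_names=["x0", "sig"])
        assert t_scores(m, X, y)["sig"] > 10


def test_drop_aliased_columns_finds_design_alias(noisy_design):
    fm, _ = noisy_design
    kept, dropped = drop_aliased_columns(fm.X, fm.feature_names)
    # the 48 context dummies + cycle-1 indicator sum to the intercept:
    # exactly one column must go, and never the intercept
    assert len(dropped) == 1
    assert "x0" not in dropped
    sub = fm.X[:, kept]
    assert np.linalg.matrix_rank(sub) == sub.shape[1]


def test_irls_loglik_non_decreasing_on_tile_design(noisy_design):
    """End-to-end MLE on the de-aliased tile design converges with a
    finite, reproducible likelihood."""
    fm, y = noisy_design
    kept, _ = drop_aliased_columns(fm.X, fm.feature_names)
    names = [fm.feature_names[j] for j in kept]
    m, rep = fit_mle(fm.X[:, kept], y, feature_names=names, metadata=fm)
    assert rep.converged
    assert np.isfinite(m.loglik) and m.loglik <= 0
    m2, _ = fit_mle(fm.X[:, kept], y, feature_names=names, metadata=fm)
    assert np.array_equal(m.beta, m2.beta)
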