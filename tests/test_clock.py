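"""Elastic-net clock: optimization oracles, split, importance, evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaboclock import (
    MetabolicAgeClock,
    compare_correlations,
    evaluate_clock,
    fisher_ci,
    importance_scores,
    split_train_test,
)


def _make_linear_problem(rng, n=60, p=4):
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"x{j}" for j in range(p)])
    beta = np.array([2.0, -1.0, 0.5, 0.0])
    y = 50 + X.to_numpy() @ beta
    return X, y, beta


class TestSplit:
    def test_overall_fraction(self, rng):
        cohort = pd.DataFrame({
            "age": rng.uniform(35, 85, 100),
            "sex": rng.choice(["male", "female"], 100),
            "cohort": "healthy",
        }, index=[f"s{i}" for i in range(100)])
        split = split_train_test(cohort, 0.75, seed=1)
        assert abs((split == "train").sum() - 75) <= 4  # rounding per stratum

    def test_deterministic(self, rng):
        cohort = pd.DataFrame({
            "age": rng.uniform(35, 85, 50),
            "sex": rng.choice(["male", "female"], 50),
        }, index=[f"s{i}" for i in range(50)])
        pd.testing.assert_series_equal(split_train_test(cohort, seed=9),
                                       split_train_test(cohort, seed=9))

    def test_per_stratum_fraction_within_one_subject(self, healthy_sim):
        cohort, _, _, _ = healthy_sim
        split = split_train_test(cohort, 0.75, seed=3)
        decade = (cohort["age"] // 10).astype(int)
        for (_, _), idx in cohort.groupby([cohort["sex"], decade]).groups.items():
            n = len(idx)
            n_train = (split[list(idx)] == "train").sum()
            assert abs(n_train - 0.75 * n) <= 1.0

    def test_rejects_diseased(self):
        cohort = pd.DataFrame({"age": [50.0, 60.0], "sex": ["male", "male"],
                               "cohort": ["healthy", "CRC_I"]},
                              index=["a", "b"])
        with pytest.raises(ValueError, match="healthy"):
            split_train_test(cohort)


class TestElasticNetOracles:
    def test_ols_limit_recovers_exact_coefficients(self, rng):
        X, y, beta = _make_linear_problem(rng)
        model = MetabolicAgeClock(lam=0.0).fit(X, y)
        # raw-scale coefficients must match the generating ones
        np.testing.assert_allclose(model.coef_raw_, beta, atol=1e-8)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-8)

    def test_full_shrinkage_limit(self, rng):
        X, y, _ = _make_linear_problem(rng)
        model = MetabolicAgeClock(lam=1e6).fit(X, y)
        np.testing.assert_allclose(model.coef_, 0.0)
        np.testing.assert_allclose(model.predict(X), np.mean(y), atol=1e-8)

    def test_single_predictor_soft_threshold(self, rng):
        # lasso on one standardized predictor: beta = S(<x,y_c>/n, lam)
        n = 200
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        y = 55 + 1.3 * x + rng.normal(0, 0.5, n)
        rho = x @ (y - y.mean()) / n
        for lam in (0.05, 0.5, abs(rho) + 0.1):
            model = MetabolicAgeClock(l1_ratio=1.0, lam=lam, tol=1e-12).fit(
                pd.DataFrame({"x": x}), y)
            expected = np.sign(rho) * max(abs(rho) - lam, 0.0)
            assert model.coef_[0] == pytest.approx(expected, abs=1e-5)

    def test_kkt_conditions_at_solution(self, rng):
        # subgradient: (1/n) X^T (y - yhat) = lam*(alpha*s + (1-alpha)*beta)
        n, p, lam, alpha = 120, 6, 0.3, 0.5
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(0, 1, n)
        model = MetabolicAgeClock(l1_ratio=alpha, lam=lam, tol=1e-12,
                                  max_iter=200_000).fit(
            pd.DataFrame(X, columns=[f"x{j}" for j in range(p)]), y)
        Z = (X - model.mean_) / model.scale_
        resid = y - model.predict(pd.DataFrame(
            X, columns=model.predictor_ids_))
        grad = Z.T @ resid / n - lam * (1 - alpha) * model.coef_
        for j in range(p):
            if model.coef_[j] != 0:
                assert abs(grad[j] - lam * alpha * np.sign(model.coef_[j])) < 1e-6
            else:
                assert abs(grad[j]) <= lam * alpha + 1e-6

    def test_objective_no_worse_than_null_model(self, rng):
        n, p = 80, 5
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        for lam in (0.01, 0.1, 1.0, 10.0):
            model = MetabolicAgeClock(l1_ratio=0.5, lam=lam).fit(
                pd.DataFrame(X), y)
            Z = (X - model.mean_) / model.scale_

            def obj(beta, b0):
                r = y - b0 - Z @ beta
                pen = lam * (0.5 * np.abs(beta).sum()
                             + 0.25 * (beta ** 2).sum())
                return r @ r / (2 * n) + pen

            assert (obj(model.coef_, model.intercept_)
                    <= obj(np.zeros(p), y.mean()) + 1e-10)

    def test_cv_selects_lambda_from_grid(self, rng):
        X, y, _ = _make_linear_problem(rng, n=100)
        y = y + rng.normal(0, 2, 100)
        grid = np.logspace(-3, 1, 20)
        model = MetabolicAgeClock(lambda_grid=grid, cv=5,
                                  random_state=0).fit(X, y)
        assert model.lambda_ in grid

    def test_nonfinite_predictor_named(self, rng):
        X, y, _ = _make_linear_problem(rng)
        X.loc[X.index[0], "x2"] = np.nan
        with pytest.raises(ValueError, match="x2"):
            MetabolicAgeClock(lam=0.1).fit(X, y)

    def test_empty_lambda_grid_rejected(self, rng):
        X, y, _ = _make_linear_problem(rng)
        with pytest.raises(ValueError, match="grid"):
            MetabolicAgeClock(lambda_grid=[]).fit(X, y)


class TestImportanceAndPredict:
    def test_importance_formula_and_sign_invariance(self, rng):
        X, y, _ = _make_linear_problem(rng)
        model = MetabolicAgeClock(lam=0.0).fit(X, y)
        model.coef_ = np.array([2.0, -1.0, 0.0, 0.5])
        scores = importance_scores(model)
        np.testing.assert_allclose(scores, [100.0, 50.0, 0.0, 25.0])
        # ranking matches |coef| ranking
        assert (np.argsort(scores) == np.argsort(np.abs(model.coef_))).all()

    def test_all_zero_model_warns(self, rng, caplog):
        X, y, _ = _make_linear_problem(rng)
        model = MetabolicAgeClock(lam=1e6).fit(X, y)
        with caplog.at_level("WARNING", logger="metaboclock"):
            scores = importance_scores(model)
        np.testing.assert_allclose(scores, 0.0)

    def test_strict_predict_schema(self, rng):
        X, y, _ = _make_linear_problem(rng)
        model = MetabolicAgeClock(lam=0.0).fit(X, y)
        with pytest.raises(ValueError, match="missing"):
            model.predict(X.drop(columns=["x1"]))
        extra = X.copy()
        extra["unrelated"] = 1.0
        with pytest.raises(ValueError, match="extra"):
            model.predict(extra)

    def test_json_round_trip_predictions(self, rng, tmp_path):
        X, y, _ = _make_linear_problem(rng)
        model = MetabolicAgeClock(lam=0.05).fit(X, y)
        path = tmp_path / "clock.json"
        model.to_json(path)
        back = MetabolicAgeClock.from_json(path)
        np.testing.assert_allclose(back.predict(X), model.predict(X),
                                   atol=1e-12)


class TestEvaluation:
    def test_identity_prediction(self):
        y = np.array([40.0, 50.0, 60.0, 70.0, 80.0])
        ev = evaluate_clock(y, y)
        assert ev.r == pytest.approx(1.0)
        assert ev.slope == pytest.approx(1.0)

    def test_anti_identity(self):
        y = np.array([40.0, 50.0, 60.0, 70.0, 80.0])
        ev = evaluate_clock(-y, y)
        assert ev.r == pytest.approx(-1.0)
        assert ev.slope == pytest.approx(-1.0)

    def test_fisher_ci_closed_form(self):
        # atanh(0.5) +/- 1.96/sqrt(100), back through tanh
        lo, hi = fisher_ci(0.5, 103)
        z = stats.norm.ppf(0.975)
        assert lo == pytest.approx(np.tanh(np.arctanh(0.5) - z / 10), abs=1e-12)
        assert hi == pytest.approx(np.tanh(np.arctanh(0.5) + z / 10), abs=1e-12)
        assert (lo, hi) == pytest.approx((0.339, 0.632), abs=1e-3)

    def test_constant_prediction_degenerate(self):
        ev = evaluate_clock(np.full(10, 60.0), np.linspace(40, 80, 10))
        assert ev.degenerate and np.isnan(ev.r)

    def test_compare_correlations_identical_inputs(self):
        evals = [evaluate_clock(*_corr_sample(0.6, 200, s)) for s in (1, 1)]
        q, p = compare_correlations([evals[0], evals[0]])
        assert q == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_compare_correlations_hand_computed(self):
        from metaboclock.clock import ClockEvaluation

        def ev(r, n):
            return ClockEvaluation("x", n, r, (0, 1), 1.0, (0, 2))

        q, p = compare_correlations([ev(0.9, 500), ev(0.5, 500)])
        z = np.arctanh([0.9, 0.5])
        zbar = z.mean()
        q_hand = 497 * ((z - zbar) ** 2).sum()
        assert q == pytest.approx(q_hand, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(q_hand, 1), rel=1e-12)

    def test_two_group_reduces_to_z_test(self):
        # chi-square(1) statistic equals the squared two-sample z statistic
        from metaboclock.clock import ClockEvaluation
        r1, r2, n1, n2 = 0.7, 0.55, 300, 450
        evals = [ClockEvaluation("a", n1, r1, (0, 1), 1, (0, 2)),
                 ClockEvaluation("b", n2, r2, (0, 1), 1, (0, 2))]
        q, p = compare_correlations(evals)
        z_stat = ((np.arctanh(r1) - np.arctanh(r2))
                  / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3)))
        assert q == pytest.approx(z_stat ** 2, rel=1e-10)

    def test_small_n_rejected(self):
        from metaboclock.clock import ClockEvaluation
        evals = [ClockEvaluation("a", 3, 0.5, (0, 1), 1, (0, 2)),
                 ClockEvaluation("b", 50, 0.5, (0, 1), 1, (0, 2))]
        with pytest.raises(ValueError):
            compare_correlations(evals)


def _corr_sample(r, n, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = r * x + np.sqrt(1 - r * r) * rng.normal(size=n)
    return x, y
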