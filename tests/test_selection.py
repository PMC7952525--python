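import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from ductus.closure_model import published_model
from ductus.errors import RankDeficiencyError, SeparationWarning
from ductus.selection import (
    backward_eliminate,
    bernoulli_log_likelihood,
    fit_logistic,
    wald_test,
)
from ductus.simulate import default_config, generate_cohort, simulate_outcomes_from_model


def _neg_loglik(beta, X, y):
    eta = X @ beta
    return -(np.sum(y * eta - np.logaddexp(0.0, eta)))


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 30 + [0] * 70)
        m = fit_logistic(pd.DataFrame(index=range(100)), y, columns=[])
        assert m.intercept == pytest.approx(math.log(30 / 70), abs=1e-8)
        assert m.fit_info["converged"]

    def test_null_covariate_estimates_near_zero(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.normal(size=n)
        y = (rng.random(n) < 0.5).astype(int)  # independent of x
        m = fit_logistic(pd.DataFrame({"x": x}), y)
        assert abs(m.coefficients["x"]) < 3 * m.standard_error("x")

    def test_matches_direct_numerical_maximization(self):
        """IRLS agrees with a generic numerical maximizer of the same
        likelihood to 1e-6 in the coefficients on 20 random small datasets."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(40, 120))
            k = int(rng.integers(1, 4))
            X = rng.normal(size=(n, k))
            beta_true = rng.normal(scale=0.8, size=k + 1)
            eta = beta_true[0] + X @ beta_true[1:]
            y = (rng.random(n) < expit(eta)).astype(int)
            if y.min() == y.max():
                continue
            m = fit_logistic(X, y)
            Xd = np.column_stack([np.ones(n), X])
            res = minimize(
                _neg_loglik,
                np.zeros(k + 1),
                args=(Xd, y),
                method="BFGS",
                options={"gtol": 1e-10, "maxiter": 500},
            )
            ours = np.array([m.intercept, *m.coefficients.values()])
            assert np.allclose(ours, res.x, atol=1e-6)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 2))
        y = (rng.random(200) < expit(0.3 + X @ [0.8, -0.5])).astype(int)
        m = fit_logistic(pd.DataFrame(X, columns=["a", "b"]), y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(
            [m.intercept, m.coefficients["a"], m.coefficients["b"]], ref.params, atol=1e-6
        )
        assert np.allclose(np.sqrt(np.diag(m.covariance)), ref.bse, rtol=1e-4)

    def test_fit_never_worse_than_null(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(150, 3))
        y = (rng.random(150) < 0.4).astype(int)
        m = fit_logistic(X, y)
        null_ll = bernoulli_log_likelihood(np.zeros(150), y)
        assert m.fit_info["log_likelihood"] >= null_ll

    def test_separation_warning(self):
        x = np.concatenate([np.linspace(-3, -1, 25), np.linspace(1, 3, 25)])
        y = (x > 0).astype(int)  # perfectly separated
        with pytest.warns(SeparationWarning):
            m = fit_logistic(pd.DataFrame({"x": x}), y)
        assert m.fit_info["separation"]

    def test_rank_deficiency(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=80)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = (rng.random(80) < 0.5).astype(int)
        with pytest.raises(RankDeficiencyError):
            fit_logistic(X, y)

    def test_parameter_recovery_from_published_model(self):
        """Refitting outcomes simulated from the published equation on a
        n=2000 synthetic cohort recovers every coefficient within its 95%
        Wald interval."""
        cohort = generate_cohort(default_config(seed=11, n_conservative=1333, n_treated=667))
        model = published_model()
        y = simulate_outcomes_from_model(cohort, model, seed=12)
        X = cohort[["ga_weeks", "pda_score"]].rename(
            columns={"ga_weeks": "gestational_age_weeks"}
        )
        fit = fit_logistic(X, y)
        truths = {
            "intercept": model.intercept,
            "gestational_age_weeks": 1.23,
            "pda_score": -0.87,
        }
        for name, truth in truths.items():
            est = fit.intercept if name == "intercept" else fit.coefficients[name]
            se = fit.standard_error(name)
            assert est - 1.96 * se <= truth <= est + 1.96 * se


class TestWald:
    def test_examples(self):
        se = 0.5
        for ratio, stat, p in [(0.0, 0.0, 1.0), (1.96, 3.8416, 0.0500), (3.0, 9.0, 0.0027)]:
            cov = np.diag([1.0, se**2])
            from ductus.closure_model import LogisticModel

            m = LogisticModel(
                intercept=0.0, coefficients={"x": ratio * se}, covariance=cov
            )
            s, pv = wald_test(m, "x")
            assert s == pytest.approx(stat, abs=1e-4)
            assert pv == pytest.approx(p, abs=5e-4)


class TestBackwardElimination:
    def test_empty_candidates_gives_intercept_only(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.normal(size=60)})
        y = (rng.random(60) < 0.5).astype(int)
        trace = backward_eliminate(X, y, candidates=[])
        assert trace.steps == []
        assert trace.final_model.coefficients == {}

    def test_strong_predictor_survives_noise(self):
        """One real effect (beta=2) among three pure-noise covariates: the
        signal is always retained, and the noise-only survivors appear at
        roughly the nominal 5%-per-covariate rate (so "exactly the signal"
        in about 0.95^3 ~ 86% of replicates)."""
        exact = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 500
            X = pd.DataFrame(
                {
                    "signal": rng.normal(size=n),
                    "noise1": rng.normal(size=n),
                    "noise2": rng.normal(size=n),
                    "noise3": rng.normal(size=n),
                }
            )
            y = (rng.random(n) < expit(2.0 * X["signal"])).astype(int)
            trace = backward_eliminate(X, y)
            assert "signal" in trace.retained
            assert len(trace.retained) <= 2  # at most one false survivor seen
            if trace.retained == ["signal"]:
                exact += 1
        assert exact >= 15

    def test_loglik_never_increases_along_trace(self):
        """Removing a covariate cannot improve the maximized likelihood."""
        rng = np.random.default_rng(21)
        n = 300
        X = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        y = (rng.random(n) < expit(0.6 * X["a"] + 0.05 * X["b"])).astype(int)
        full = fit_logistic(X, y)
        trace = backward_eliminate(X, y, alpha_stay=1e-9)  # force removals
        lls = [full.fit_info["log_likelihood"]] + [s.log_likelihood_after for s in trace.steps]
        assert all(lls[i] >= lls[i + 1] - 1e-9 for i in range(len(lls) - 1))

    def test_synthetic_cohort_retains_ga_and_score(self, default_cohort):
        """On the calibrated synthetic cohort, gestational age and the
        staging score survive elimination while birth weight drops."""
        cohort = generate_cohort(default_config(seed=7))
        y = (cohort["group"] == "CM").astype(int).to_numpy()
        trace = backward_eliminate(
            cohort[["ga_weeks", "pda_score", "birth_weight_g"]], y
        )
        assert sorted(trace.retained) == ["ga_weeks", "pda_score"]
        assert trace.removed == ["birth_weight_g"]

    def test_report_lists_steps(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["u", "v"])
        y = (rng.random(200) < 0.5).astype(int)
        trace = backward_eliminate(X, y)
        report = trace.to_report()
        assert "retained:" in report
        for step in trace.steps:
            assert step.removed in report
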