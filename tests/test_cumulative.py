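"""Cumulative-model fitting: oracle equivalence, recovery, probability laws."""

import numpy as np
import pytest
from scipy import optimize, special, stats

from oksmap.cumulative import CumulativeFit, fit_cumulative_core, nll_parallel
from oksmap.links import LINK_NAMES


def _binary_logistic_oracle(X, y01):
    """Direct Newton optimization of the binary logistic likelihood,
    independent of the cumulative-model code path."""
    Xd = np.hstack([np.ones((len(X), 1)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(200):
        p = special.expit(Xd @ beta)
        grad = Xd.T @ (y01 - p)
        W = p * (1 - p)
        H = Xd.T @ (Xd * W[:, None])
        step = np.linalg.solve(H + 1e-10 * np.eye(len(beta)), grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


@pytest.fixture(scope="module")
def fixture_30_rows():
    """A frozen 30-row, 2-predictor, 3-level data set."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(30, 2))
    latent = 1.2 * X[:, 0] - 0.7 * X[:, 1] + rng.normal(size=30)
    y = np.digitize(latent, [-0.8, 0.9]) + 1
    return X, y


class TestParallelLogit:
    def test_two_level_outcome_matches_binary_logistic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(400, 3))
        y01 = (rng.random(400) < special.expit(X @ [0.8, -0.5, 0.3] - 0.2)).astype(int)
        fit = fit_cumulative_core(X, y01, parallel=True, link="logit")
        oracle = _binary_logistic_oracle(X, y01)
        # P(y <= 0) = F(theta - x beta) means theta = -intercept, beta = slope
        assert fit.theta[0] == pytest.approx(-oracle[0], abs=1e-4)
        assert np.allclose(fit.beta, oracle[1:], atol=1e-4)

    def test_nll_matches_brute_force_optimum(self, fixture_30_rows):
        X, y = fixture_30_rows
        fit = fit_cumulative_core(X, y, parallel=True, link="logit")
        _, codes = np.unique(y, return_inverse=True)

        def nm_obj(q):
            theta = np.array([q[0], q[0] + np.exp(q[1])])
            return nll_parallel(theta, q[2:], X, codes, 3, "logit")

        res = optimize.minimize(
            nm_obj, np.array([-0.5, 0.0, 0.0, 0.0]), method="Nelder-Mead",
            options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
        )
        assert fit.nll == pytest.approx(res.fun, abs=1e-6)

    def test_agrees_with_statsmodels_ordered_model(self, estimation_cohort):
        sm_miss = pytest.importorskip("statsmodels.miscmodels.ordinal_model")
        X = estimation_cohort.oks_items[:300, :4].astype(float)
        y = estimation_cohort.eq_levels[:300, 0]
        fit = fit_cumulative_core(X, y, parallel=True, link="logit")
        sm_fit = sm_miss.OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=False)
        # both parameterize P(y<=k) = F(theta_k - x'beta)
        assert np.allclose(fit.beta, sm_fit.params[:4], atol=1e-3)

    def test_parameter_recovery_probit(self):
        rng = np.random.default_rng(9)
        n = 5000
        X = rng.normal(size=(n, 3))
        beta_true = np.array([0.9, -0.6, 0.4])
        theta_true = np.array([-1.0, 0.4, 1.3])
        latent = X @ beta_true + rng.normal(size=n)
        y = np.digitize(latent, theta_true)
        fit = fit_cumulative_core(X, y, parallel=True, link="probit", compute_se=True)
        assert fit.converged
        z_beta = np.abs(fit.beta - beta_true) / fit.se_beta
        z_theta = np.abs(fit.theta - theta_true) / fit.se_theta
        assert np.all(z_beta < 3.0)
        assert np.all(z_theta < 3.0)


class TestProbabilityLaws:
    @pytest.mark.parametrize("link", LINK_NAMES)
    @pytest.mark.parametrize("parallel", [True, False])
    def test_per_level_probabilities_sum_to_one(self, estimation_cohort, link, parallel):
        X = estimation_cohort.oks_items[:200, :5].astype(float)
        y = estimation_cohort.eq_levels[:200, 3]
        fit = fit_cumulative_core(X, y, parallel=parallel, link=link, max_restarts=1, maxiter=200)
        proba = fit.predict_proba(X)
        assert np.all(proba >= -1e-12)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-8)

    def test_cumulative_probabilities_monotone_in_level(self, estimation_cohort):
        X = estimation_cohort.oks_items[:200, :5].astype(float)
        y = estimation_cohort.eq_levels[:200, 0]
        for parallel in (True, False):
            fit = fit_cumulative_core(X, y, parallel=parallel, link="logit")
            cum = fit.cumulative_probs(X)
            assert np.all(np.diff(cum, axis=1) >= -1e-12)

    def test_zero_slope_model_predicts_marginal_mode(self):
        # a cumulative model with all slopes 0 is the marginal distribution
        labels = np.array([1, 2, 3])
        fit = CumulativeFit(
            link="logit", parallel=True, level_labels=labels,
            theta=np.array([np.log(0.2 / 0.8), np.log(0.7 / 0.3)]),  # P(1)=.2, P(2)=.5
            beta=np.zeros(4), nll=0.0, converged=True,
        )
        X = np.random.default_rng(0).normal(size=(50, 4))
        assert np.all(fit.predict(X) == 2)

    def test_predictions_within_training_levels(self, estimation_cohort):
        X = estimation_cohort.oks_items[:200, :5].astype(float)
        y = estimation_cohort.eq_levels[:200, 1]
        fit = fit_cumulative_core(X, y, parallel=True, link="cauchit")
        assert set(fit.predict(X)) <= set(np.unique(y))


class TestErrorHandling:
    def test_single_level_outcome_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        with pytest.raises(ValueError, match="single level"):
            fit_cumulative_core(X, np.ones(30, dtype=int))

    def test_nonfinite_predictors_rejected(self):
        X = np.full((30, 2), np.nan)
        with pytest.raises(ValueError, match="finite"):
            fit_cumulative_core(X, np.tile([1, 2], 15))

    def test_separation_is_flagged_not_silent(self):
        # perfectly separated binary outcome: likelihood has no finite optimum
        X = np.linspace(-1, 1, 40).reshape(-1, 1)
        y = (X[:, 0] > 0).astype(int)
        fit = fit_cumulative_core(X, y, parallel=True, link="logit", maxiter=50, max_restarts=0)
        assert isinstance(fit.converged, bool)  # flag present and honest
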