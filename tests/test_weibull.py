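"""Weibull proportional-hazards fitting: MLE correctness, covariance,
posterior draws, and degenerate inputs."""

import numpy as np
import pytest
from sklearn.base import clone

from survref import (DegenerateDataError, ScenarioConfig, SurvivalData,
                     WeibullPH, fit_weibull_ph, generate_trial, survivor)
from survref.weibull import _ll_grad_hess, censored_weibull_loglik


def _theta_tdz(data, fit):
    Z = data.design_matrix()
    return fit.theta_, data.times, data.events.astype(float), Z


class TestMLE:
    def test_score_vanishes_at_optimum(self, censored_trial, fitted_model):
        theta, t, d, Z = _theta_tdz(censored_trial, fitted_model)
        _, g, _ = _ll_grad_hess(theta[None], t[None], d[None], Z, np.log(t[None]))
        assert np.max(np.abs(g)) < 1e-6 * len(t)

    def test_agrees_with_lifelines_aft(self, censored_trial):
        """Independent oracle: lifelines' Weibull AFT fit, reparameterised.

        AFT: S(t)=exp(-(t/lam)^rho), log lam = mu0 + mu1*arm. PH mapping:
        kappa=rho, alpha=-rho*mu0, beta=-rho*mu1.
        """
        lifelines = pytest.importorskip("lifelines")
        df = censored_trial.frame[["time", "event", "arm"]]
        aft = lifelines.WeibullAFTFitter().fit(df, "time", "event")
        rho = float(np.exp(aft.params_[("rho_", "Intercept")]))
        mu0 = float(aft.params_[("lambda_", "Intercept")])
        mu1 = float(aft.params_[("lambda_", "arm")])
        ours = fit_weibull_ph(censored_trial)
        assert ours.kappa_ == pytest.approx(rho, abs=5e-4)
        assert ours.alpha_ == pytest.approx(-rho * mu0, abs=5e-4)
        assert ours.beta_[0] == pytest.approx(-rho * mu1, abs=5e-4)

    def test_vcov_matches_finite_difference_hessian(self, censored_trial,
                                                    fitted_model):
        theta, t, d, Z = _theta_tdz(censored_trial, fitted_model)
        q = len(theta)
        h = 1e-5
        H = np.empty((q, q))
        for i in range(q):
            for j in range(q):
                pts = []
                for si in (1, -1):
                    for sj in (1, -1):
                        th = theta.copy()
                        th[i] += si * h
                        th[j] += sj * h
                        pts.append(si * sj * censored_weibull_loglik(th, t, d, Z))
                H[i, j] = sum(pts) / (4 * h * h)
        vcov_fd = np.linalg.inv(-H)
        assert np.allclose(vcov_fd, fitted_model.vcov_, rtol=1e-3)

    def test_parameter_recovery_large_exponential_sample(self):
        """kappa=1, h0=0.01, HR=0.8 at n=1e5/arm: estimates within 3 SE."""
        cfg = ScenarioConfig(n_per_arm=100_000, master_seed=12)
        fit = fit_weibull_ph(generate_trial(cfg, np.random.default_rng(12)))
        se_lk = np.sqrt(fit.vcov_[1, 1])
        se_b = np.sqrt(fit.vcov_[2, 2])
        assert abs(fit.log_kappa_) < 3 * se_lk
        assert abs(fit.beta_[0] - np.log(0.8)) < 3 * se_b

    def test_loglik_value_consistency(self, censored_trial, fitted_model):
        theta, t, d, Z = _theta_tdz(censored_trial, fitted_model)
        assert fitted_model.loglik_ == pytest.approx(
            censored_weibull_loglik(theta, t, d, Z), rel=1e-12)


class TestSurvivor:
    def test_closed_form_values(self, fitted_model):
        # exact evaluation with known parameters, not the fitted ones
        from survref.study import _fit_shell
        shell = _fit_shell(np.array([np.log(0.01), 0.0, np.log(0.8)]),
                           np.zeros((3, 3)), 1)
        s = survivor(shell, 100.0, np.array([1]))
        assert s[0] == pytest.approx(np.exp(-0.8), rel=1e-12)
        assert survivor(shell, 0.0, np.array([1]))[0] == 1.0
        assert survivor(shell, 1e9, np.array([0]))[0] < 1e-300

    def test_strictly_decreasing(self, fitted_model):
        t = np.linspace(0.0, 400.0, 50)
        s = fitted_model.survival_function(t, np.ones(50, int))
        assert np.all(np.diff(s) < 0)

    def test_negative_time_rejected(self, fitted_model):
        with pytest.raises(ValueError):
            survivor(fitted_model, -1.0, np.array([0]))


class TestDraws:
    def test_zero_covariance_returns_mle(self, fitted_model):
        import copy
        frozen = copy.deepcopy(fitted_model)
        frozen.vcov_ = np.zeros_like(frozen.vcov_)
        draw = frozen.draw_parameters(random_state=0)
        assert np.allclose(draw, frozen.theta_)

    def test_same_seed_reproduces(self, fitted_model):
        d1 = fitted_model.draw_parameters(random_state=42)
        d2 = fitted_model.draw_parameters(random_state=42)
        assert np.array_equal(d1, d2)

    def test_moments_match_mle_and_vcov(self, fitted_model):
        draws = fitted_model.draw_parameters(random_state=3, size=100_000)
        se = np.sqrt(np.diag(fitted_model.vcov_))
        # sample mean within 4 Monte-Carlo SEs of the MLE, componentwise
        assert np.all(np.abs(draws.mean(0) - fitted_model.theta_)
                      < 4 * se / np.sqrt(100_000))
        cov = np.cov(draws.T)
        assert np.allclose(cov, fitted_model.vcov_, rtol=0.05,
                           atol=0.05 * se.max() ** 2)


class TestDegenerate:
    def test_all_censored_arm_raises(self):
        import pandas as pd
        n = 40
        frame = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(2 * n)],
            "time": np.linspace(1, 80, 2 * n),
            "event": [1] * n + [0] * n,
            "arm": [0] * n + [1] * n,
        })
        with pytest.raises(DegenerateDataError):
            fit_weibull_ph(SurvivalData.from_frame(frame))

    def test_identical_event_times_terminates_with_boundary_flag(self):
        import pandas as pd
        frame = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(30)],
            "time": 5.0, "event": 1, "arm": 0,
        })
        data = SurvivalData.from_frame(frame)
        with pytest.warns(RuntimeWarning, match="boundary"):
            fit = fit_weibull_ph(data)
        assert fit.boundary_
        assert fit.kappa_ > 100  # shape escapes toward the boundary

    def test_stratified_requires_events_in_each_arm(self):
        import pandas as pd
        frame = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(40)],
            "time": np.linspace(1, 40, 40),
            "event": [1] * 20 + [0] * 20,
            "arm": [0] * 20 + [1] * 20,
        })
        with pytest.raises(DegenerateDataError):
            fit_weibull_ph(SurvivalData.from_frame(frame), stratify_by_arm=True)


class TestStratified:
    def test_arm_specific_parameters_recover_truth(self):
        cfg = ScenarioConfig(n_per_arm=40_000, master_seed=5)
        trial = generate_trial(cfg, np.random.default_rng(5))
        fit = fit_weibull_ph(trial, stratify_by_arm=True)
        # arm 0: rate 0.01; arm 1: rate 0.008; kappa 1 in both
        truth = {0: np.log(0.01), 1: np.log(0.008)}
        for a in (0, 1):
            se_a = np.sqrt(fit.vcov_by_arm_[a][0, 0])
            se_k = np.sqrt(fit.vcov_by_arm_[a][1, 1])
            assert fit.alpha_by_arm_[a] == pytest.approx(truth[a],
                                                         abs=3.5 * se_a)
            assert abs(fit.log_kappa_by_arm_[a]) < 3.5 * se_k

    def test_sklearn_contract(self, censored_trial):
        model = WeibullPH(stratify_by_arm=True)
        assert clone(model).get_params() == model.get_params()
        model.set_params(stratify_by_arm=False)
        fitted = model.fit(censored_trial.design_matrix(),
                           (censored_trial.times,
                            censored_trial.events.astype(float)))
        assert hasattr(fitted, "vcov_")
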