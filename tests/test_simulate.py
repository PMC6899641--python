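"""Trial generator, CAR censoring mechanisms, and oracle recreation."""

import numpy as np
import pytest

from survref import (Assumption, ScenarioConfig, SpecificationError,
                     apply_car_censoring, event_times_from_uniforms,
                     fit_weibull_ph, generate_trial, recreate_under_assumption)


class TestGenerator:
    def test_inverse_cdf_arithmetic(self):
        # U = e^-1 at the control rate 0.01 gives exactly T = 100
        assert event_times_from_uniforms(np.exp(-1), 0.01) == pytest.approx(100.0)
        # Weibull shape: T = (-log u / rate)**(1/kappa)
        assert event_times_from_uniforms(np.exp(-1), 0.01, kappa=2.0) == \
            pytest.approx(10.0)

    def test_balanced_arms_all_events(self):
        cfg = ScenarioConfig(n_per_arm=250, master_seed=0)
        d = generate_trial(cfg, np.random.default_rng(0))
        assert d.n == 500
        assert (d.arms == 1).sum() == 250
        assert d.events.sum() == 500

    def test_exponential_means_by_arm(self):
        cfg = ScenarioConfig(n_per_arm=100_000, master_seed=1)
        d = generate_trial(cfg, np.random.default_rng(1))
        act = d.times[d.arms == 1]
        ctl = d.times[d.arms == 0]
        assert act.mean() == pytest.approx(125.0, abs=3 * 125 / np.sqrt(act.size))
        assert ctl.mean() == pytest.approx(100.0, abs=3 * 100 / np.sqrt(ctl.size))

    def test_empirical_survivor_closed_form(self):
        # under HR=1 both arms have S(100) = exp(-1)
        cfg = ScenarioConfig(n_per_arm=50_000, hazard_ratio=1.0, master_seed=2)
        d = generate_trial(cfg, np.random.default_rng(2))
        for a in (0, 1):
            t = d.times[d.arms == a]
            p = (t > 100).mean()
            se = np.sqrt(np.exp(-1) * (1 - np.exp(-1)) / t.size)
            assert p == pytest.approx(np.exp(-1), abs=3 * se)


class TestCensoring:
    def test_zero_fraction_is_identity(self, censored_trial):
        assert apply_car_censoring(censored_trial, 0.0, rng=0) is censored_trial

    def test_uniform_exact_counts(self):
        cfg = ScenarioConfig(n_per_arm=250, master_seed=3)
        d = generate_trial(cfg, np.random.default_rng(3))
        c = apply_car_censoring(d, 0.5, arm=1, rng=np.random.default_rng(4),
                                mechanism="uniform_exact")
        assert (c.events[c.arms == 1] == 0).sum() == 125
        assert (c.events[c.arms == 0] == 0).sum() == 0

    def test_uniform_exact_selection_independent_of_event_time(self):
        cfg = ScenarioConfig(n_per_arm=10_000, master_seed=5)
        d = generate_trial(cfg, np.random.default_rng(5))
        c = apply_car_censoring(d, 0.4, arm=1, rng=np.random.default_rng(6),
                                mechanism="uniform_exact")
        act = d.arms == 1
        sel = (c.events[act] == 0).astype(float)
        corr = np.corrcoef(sel, d.times[act])[0, 1]
        assert abs(corr) < 3 / np.sqrt(act.sum())

    def test_exponential_fraction_near_target(self):
        cfg = ScenarioConfig(n_per_arm=20_000, master_seed=7)
        d = generate_trial(cfg, np.random.default_rng(7))
        for f in (0.2, 0.5, 0.8):
            c = apply_car_censoring(d, f, arm=1, rng=np.random.default_rng(8),
                                    event_rate=0.008)
            frac = (c.events[c.arms == 1] == 0).mean()
            assert frac == pytest.approx(f, abs=4 * np.sqrt(f * (1 - f) / 20_000))

    def test_exponential_censoring_noninformative_for_mle(self):
        """The censored-data Weibull MLE stays consistent (the CAR property)."""
        cfg = ScenarioConfig(n_per_arm=40_000, master_seed=9)
        rng = np.random.default_rng(9)
        d = generate_trial(cfg, rng)
        c = apply_car_censoring(d, 0.5, arm=1, rng=rng, event_rate=0.008)
        fit = fit_weibull_ph(c)
        se = np.sqrt(fit.vcov_[2, 2])
        assert fit.beta_[0] == pytest.approx(np.log(0.8), abs=3.5 * se)

    def test_times_bounded_by_event_times(self):
        cfg = ScenarioConfig(n_per_arm=500, master_seed=10)
        d = generate_trial(cfg, np.random.default_rng(10))
        c = apply_car_censoring(d, 0.6, arm=1, rng=np.random.default_rng(11))
        cens = c.events == 0
        assert np.all(c.times[cens] < d.times[cens])

    def test_bad_fraction_rejected(self, censored_trial):
        with pytest.raises(SpecificationError):
            apply_car_censoring(censored_trial, 1.0)


class TestRecreation:
    def test_nothing_censored_identity(self):
        cfg = ScenarioConfig(n_per_arm=100, master_seed=12)
        d = generate_trial(cfg, np.random.default_rng(12))
        out = recreate_under_assumption(d, cfg.truth, Assumption("CAR"),
                                        np.random.default_rng(0))
        assert out is d

    def test_car_recreation_restores_generating_law(self):
        """Generate -> censor -> recreate under CAR, then fit: estimates match
        the generating parameters within Monte-Carlo error."""
        cfg = ScenarioConfig(n_per_arm=50_000, censor_fraction=0.5,
                             master_seed=13)
        rng = np.random.default_rng(13)
        d = generate_trial(cfg, rng)
        c = apply_car_censoring(d, 0.5, arm=1, rng=rng, event_rate=0.008)
        r = recreate_under_assumption(c, cfg.truth, Assumption("CAR"), rng)
        assert (r.events == 1).all()
        fit = fit_weibull_ph(r)
        assert fit.beta_[0] == pytest.approx(np.log(0.8),
                                             abs=3.5 * np.sqrt(fit.vcov_[2, 2]))
        assert abs(fit.log_kappa_) < 3.5 * np.sqrt(fit.vcov_[1, 1])

    def test_j2r_attenuates_monotonically_with_censoring(self):
        """Table-row pattern: the implied J2R log HR shrinks toward 0."""
        betas = []
        for i, f in enumerate((0.2, 0.5, 0.8)):
            cfg = ScenarioConfig(n_per_arm=30_000, censor_fraction=f,
                                 master_seed=14)
            rng = np.random.default_rng([14, i])
            d = generate_trial(cfg, rng)
            c = apply_car_censoring(d, f, arm=1, rng=rng, event_rate=0.008)
            r = recreate_under_assumption(c, cfg.truth, Assumption("J2R"), rng)
            betas.append(fit_weibull_ph(r).beta_[0])
        assert betas[0] < betas[1] < betas[2] < 0

    def test_imputed_part_exceeds_censoring_times(self):
        cfg = ScenarioConfig(n_per_arm=2_000, censor_fraction=0.4,
                             master_seed=15)
        rng = np.random.default_rng(15)
        d = generate_trial(cfg, rng)
        c = apply_car_censoring(d, 0.4, arm=1, rng=rng)
        r = recreate_under_assumption(c, cfg.truth,
                                      Assumption("DELTA", delta=3.0), rng)
        cens = c.events == 0
        assert np.all(r.times[cens] > c.times[cens])


class TestConfigValidation:
    def test_bad_values_rejected(self):
        with pytest.raises(SpecificationError):
            ScenarioConfig(n_per_arm=1)
        with pytest.raises(SpecificationError):
            ScenarioConfig(censor_fraction=1.0)
        with pytest.raises(SpecificationError):
            ScenarioConfig(hazard_ratio=-1.0)
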