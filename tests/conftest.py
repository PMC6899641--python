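import numpy as np
import pytest

from survref import (ScenarioConfig, apply_car_censoring, fit_weibull_ph,
                     generate_trial)


@pytest.fixture(scope="session")
def censored_trial():
    """A 300/arm exponential trial with ~30% of the active arm censored."""
    cfg = ScenarioConfig(n_per_arm=300, censor_fraction=0.3, master_seed=7)
    rng = np.random.default_rng(7)
    trial = generate_trial(cfg, rng)
    return apply_car_censoring(trial, 0.3, arm=1, rng=rng, event_rate=0.008)


@pytest.fixture(scope="session")
def fitted_model(censored_trial):
    return fit_weibull_ph(censored_trial)
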