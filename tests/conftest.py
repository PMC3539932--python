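import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from cvdineq import coding, followup
from cvdineq.synthetic_cohort import SimulationConfig, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Raw synthetic cohort, small enough for per-test model fitting."""
    cfg = SimulationConfig()
    cfg.n = {"male": 1500, "female": 1500}
    return generate_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def male_analysis_frames(small_cohort):
    """(survival, coded) frames for the male analytic subset."""
    analytic, _ = followup.apply_exclusions(small_cohort)
    sub = analytic[analytic["sex"] == "male"].reset_index(drop=True)
    coded = coding.code_cohort(sub)
    surv = followup.derive_survival(sub)
    return surv, coded


def simulate_exponential(n, log_hr, event_frac_target, seed, p_x=0.5):
    """One binary covariate, exponential baseline, administrative censoring.

    Utility for parameter-recovery tests: the baseline rate is chosen so the
    expected event fraction is roughly ``event_frac_target``.
    """
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, p_x, n).astype(float)
    T_admin = 10.0
    lam0 = -np.log(1 - event_frac_target) / T_admin / np.exp(log_hr * p_x)
    t = rng.exponential(1.0 / (lam0 * np.exp(log_hr * x)))
    time = np.minimum(t, T_admin)
    event = (t <= T_admin).astype(int)
    return time, event, x
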