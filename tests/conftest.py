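import numpy as np
import pandas as pd
import pytest

from mrsurv.dataset import SurvivalDataset


def simulate_ph(seed, n, betas, lambda0=1.0, gamma0=1.0, censor_max=1.5,
                covariate_sampler=None, names=None):
    """Weibull-PH cohort with standard-normal covariates (test helper).

    Independent of the package generator so it can serve as a second route
    for parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    betas = np.asarray(betas, float)
    p = betas.size
    X = rng.normal(size=(n, p)) if covariate_sampler is None else covariate_sampler(rng, n, p)
    lp = X @ betas
    u = rng.uniform(size=n)
    true_t = (1.0 / lambda0) * (-np.log(u) * np.exp(-lp)) ** (1.0 / gamma0)
    cens = rng.uniform(0, censor_max, size=n)
    time = np.minimum(true_t, cens)
    event = (true_t <= cens).astype(int)
    names = names or [f"x{j}" for j in range(p)]
    return SurvivalDataset(time, event, pd.DataFrame(X, columns=names))


@pytest.fixture(scope="session")
def study_cohort_large():
    """Large cohort from the study-parameter generator (shared, read-only)."""
    from mrsurv.synthetic import generate_cohort, study_cohort_spec

    return generate_cohort(study_cohort_spec(n_patients=5000, seed=314))


@pytest.fixture(scope="session")
def simple_cohort():
    """Small complete-case cohort with one strong predictor."""
    return simulate_ph(seed=7, n=120, betas=[0.8], censor_max=2.0)
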