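"""Shared fixtures: small known-truth cohorts generated at test time."""

import numpy as np
import pytest

from agemine.config import CategoricalCensus, SyntheticConfig
from agemine.synthetic import generate_cohort, inject_missingness


def small_config(**kw):
    base = dict(
        n_subjects=500,
        n_continuous=12,
        n_ordinal=4,
        categorical_census=CategoricalCensus(n_binary=6, n_three_level=2,
                                             n_four_level=1),
        n_informative=5,
        n_heavy_tailed=3,
        n_high_missing=2,
        survivor_outcomes=True,
        seed=11,
    )
    base.update(kw)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """Complete (no missingness) 500-subject cohort with 5 informative
    variables and known truth."""
    return generate_cohort(small_config(), return_truth=True)


@pytest.fixture(scope="session")
def small_cohort_missing():
    cfg = small_config()
    return inject_missingness(generate_cohort(cfg), cfg), cfg


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no predictor-outcome association at all."""
    cfg = small_config(true_betas={}, latent_hazard_coef=0.0, seed=19)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def toy_survival():
    """Weibull PH toy data with a single standardized predictor, no ties."""
    rng = np.random.default_rng(7)
    n = 400
    x = rng.normal(size=n)
    eta = 0.7 * x
    T = 10.0 * (rng.exponential(size=n) / np.exp(eta)) ** 0.5
    C = rng.uniform(5, 25, size=n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    return x, time, event
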