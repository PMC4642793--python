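"""Shared fixtures: small synthetic cohorts and pre-computed fits.

Heavy MCMC fits are session-scoped so unit tests can share them; the
fits use reduced chain lengths that keep the suite fast while still
converging on these small, well-separated fixtures.
"""

import numpy as np
import pytest

import respmix as rm
from respmix.trial_data import impute_covariates, standardize_covariates

# a compact covariate set for recovery fixtures: one binary effect carrier,
# one continuous effect carrier, one continuous null, no missingness
RECOVERY_SPECS = [
    rm.CovariateSpec("marital", "binary", p=0.5),
    rm.CovariateSpec("swls", "continuous", mean=16.7, sd=5.1),
    rm.CovariateSpec("audit", "continuous", mean=5.0, sd=4.1),
]

LIGHT = dict(chains=2, warmup=500, draws=800)


def make_separated_config(seed, n=100, beta_swls=1.0):
    """Well-separated responder/nonresponder cohort (exponential world).

    The class-membership signal rides on a continuous covariate because the
    logit coefficients are per-standardized-unit effects; a centered binary
    covariate (SD 0.5) would carry only half the per-unit signal.
    """
    return rm.GeneratorConfig(
        seed=seed, n_subjects=n, responder_intercept=float(np.log(3)),
        responder_decay_mean=0.15, responder_decay_sd=0.03,
        nonresponder_decay_mean=0.0, nonresponder_decay_sd=0.01,
        residual_sd=3.0, covariate_specs=RECOVERY_SPECS,
        true_beta={"swls": beta_swls, "audit": 0.0},
    )


def make_quadratic_config(seed, n=100, alpha_swls=0.25):
    """Single-population quadratic cohort with a slope-level covariate effect."""
    return rm.GeneratorConfig(
        seed=seed, n_subjects=n, family="quadratic", responder_intercept=50.0,
        responder_slope_mean=-1.2, responder_slope_sd=0.3,
        curvature_mean=0.04, curvature_sd=0.02, residual_sd=3.0,
        covariate_specs=RECOVERY_SPECS,
        true_alpha={"swls": alpha_swls, "audit": 0.0},
    )


def standardized(dataset):
    table, _ = standardize_covariates(dataset.covariates)
    return impute_covariates(table, "mean")


@pytest.fixture(scope="session")
def separated_cohort():
    cfg = make_separated_config(seed=11)
    dataset, truth = rm.generate(cfg)
    return dataset, truth


@pytest.fixture(scope="session")
def separated_fit(separated_cohort):
    dataset, _ = separated_cohort
    sampler = rm.SamplerConfig(seed=5, **LIGHT)
    return rm.fit_latent_class(dataset, standardized(dataset), sampler=sampler)


@pytest.fixture(scope="session")
def exponential_cohort():
    """Single-population exponential cohort with known group decay 0.12."""
    cfg = rm.GeneratorConfig(
        seed=7, n_subjects=80, responder_intercept=50.0,
        responder_decay_mean=0.12, responder_decay_sd=0.03,
        residual_sd=3.0, covariate_specs=RECOVERY_SPECS,
    )
    return rm.generate(cfg)


@pytest.fixture(scope="session")
def exponential_fit(exponential_cohort):
    dataset, _ = exponential_cohort
    sampler = rm.SamplerConfig(seed=5, **LIGHT)
    return rm.fit_hierarchical(dataset, "exponential", sampler=sampler)
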