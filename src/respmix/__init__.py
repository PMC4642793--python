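"""respmix: Bayesian latent-class growth mixture modelling of treatment response.

Hierarchical nonlinear trajectory models for repeated depression scores,
a restricted 2-class responder/nonresponder mixture with covariates on
class membership, a slope-level covariate regression, and posterior
evidence summaries (modes, HDIs, directional odds ratios, Savage-Dickey
Bayes factors), plus a seeded synthetic-cohort generator with ground truth.
"""

from ._mcmc import FitError, PosteriorDraws, PriorConfig, SamplerConfig
from .diagnostics import (
    ConvergenceReport,
    PpcReport,
    convergence_report,
    gelman_rubin,
    posterior_predictive,
)
from .evidence import (
    EvidenceSummary,
    directional_odds,
    evidence_table,
    hdi,
    jeffreys_category,
    posterior_mode,
    savage_dickey_bf10,
    write_evidence_csv,
)
from .growth_models import (
    FAMILIES,
    fit_hierarchical,
    log_likelihood,
    mean_trajectory,
    select_family,
)
from .mixture_model import (
    ClassPosterior,
    class_membership_prob,
    classify,
    fit_latent_class,
    response_probability_curve,
)
from .slope_model import SlopeRegressionPosterior, fit_slope_regression
from .synthetic_cohort import (
    CovariateSpec,
    GeneratorConfig,
    GroundTruth,
    default_covariate_specs,
    generate,
)
from .trial_data import (
    CovariateTable,
    FormatError,
    MeasurementSeries,
    ScalingRecord,
    StudyDataset,
    ValidationError,
    impute_covariates,
    read_covariates_csv,
    read_long_csv,
    standardize_covariates,
    write_covariates_csv,
    write_long_csv,
)

__version__ = "0.1.0"
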