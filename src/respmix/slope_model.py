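"""Strength-of-response analysis: covariates on the individual slope.

A hierarchical quadratic trajectory model in which each subject's linear
slope b1_i is regressed on standardized baseline covariates:

    b1_i ~ normal(alpha_0 + sum_k alpha_k_raw * x_ik, tau^2)

The curvature b2_i and baseline b0_i keep covariate-free group priors.
Because a more negative slope means faster symptom decline, reported
coefficients are sign-flipped (alpha_k = -alpha_k_raw) so that a positive
coefficient always reads as "faster decline" — matching the convention of
the directional odds-ratio tables.  The standard-normal coefficient prior
on standardized covariates is what the Savage-Dickey Bayes factors divide
against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mcmc import PosteriorDraws, PriorConfig, SamplerConfig
from .growth_models import fit_hierarchical
from .mixture_model import _covariate_matrix
from .trial_data import CovariateTable, StudyDataset

__all__ = ["SlopeRegressionPosterior", "fit_slope_regression"]


@dataclass
class SlopeRegressionPosterior:
    """Posterior of the slope-covariate regression inside the quadratic model."""

    draws: PosteriorDraws              # full quadratic chain incl. "alpha_raw"
    covariate_names: list[str] = field(default_factory=list)

    @property
    def alpha0(self) -> np.ndarray:
        """Slope intercept draws (raw slope scale, BDI-II points/week)."""
        return self.draws["alpha_raw"][..., 0]

    @property
    def alpha(self) -> np.ndarray:
        """Covariate coefficient draws, shape (chain, draw, K), in the
        "+ = faster symptom decline" reporting convention."""
        return -self.draws["alpha_raw"][..., 1:]

    def alpha_draws(self, name: str) -> np.ndarray:
        """Pooled reporting-convention draws for one covariate."""
        j = self.covariate_names.index(name)
        return self.alpha.reshape(-1, len(self.covariate_names))[:, j]

    def summary_frame(self) -> pd.DataFrame:
        flat = self.alpha.reshape(-1, len(self.covariate_names))
        return pd.DataFrame(flat, columns=self.covariate_names)


def fit_slope_regression(
    dataset: StudyDataset,
    covariates: CovariateTable | None = None,
    priors: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
) -> SlopeRegressionPosterior:
    """Fit the quadratic hierarchical model with covariates on the slope.

    ``covariates`` must be standardized and imputed; with no covariates the
    model reduces to the plain hierarchical quadratic fit (the slope
    intercept then coincides with the slope group mean).
    """
    priors = priors or PriorConfig()
    X, names = _covariate_matrix(dataset, covariates)
    coef_scales = np.concatenate(
        [[priors.slope_mean_scale], np.full(X.shape[1] - 1, priors.coef_scale)]
    )
    draws = fit_hierarchical(
        dataset, "quadratic", priors=priors, sampler=sampler,
        _X=X, _coef_prior_scales=coef_scales,
    )
    draws.coef_names = ["intercept"] + names
    draws.meta["slope_regression"] = True
    return SlopeRegressionPosterior(draws=draws, covariate_names=names)
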