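"""Hierarchical trajectory models for repeated depression scores.

Three mean-function families are supported for subject i at week t:

* linear:       b0_i + b1_i * t
* quadratic:    b0_i + b1_i * t + b2_i * t^2
* exponential:  b0_i * exp(-decay_i * t),  decay_i >= 0

Subject-level coefficients are constrained by group-level normal
distributions (truncated at zero for the exponential decay rate), and
observations get a common-variance normal likelihood.  Fitting is by the
in-package adaptive Metropolis-within-Gibbs engine; family comparison uses
WAIC, a penalized pointwise out-of-sample predictive criterion estimated
from the posterior draws.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import log_ndtr as _lnd

from ._mcmc import (
    FitError,
    PackedData,
    PosteriorDraws,
    PriorConfig,
    SamplerConfig,
    _Adapt,
    chain_rng,
    conj_normal_mean,
    halfnormal_lp,
    mh_scalar,
    mh_vector,
    normal_lp,
    truncnorm_pos_lp,
)
from .trial_data import StudyDataset

__all__ = [
    "FAMILIES",
    "PriorConfig",
    "SamplerConfig",
    "PosteriorDraws",
    "FitError",
    "mean_trajectory",
    "log_likelihood",
    "fit_hierarchical",
    "pointwise_log_likelihood",
    "select_family",
]

FAMILIES = ("linear", "quadratic", "exponential")

_POLY_COEFS = {"linear": ("b0", "b1"), "quadratic": ("b0", "b1", "b2")}


def mean_trajectory(family: str, params: Mapping[str, float], t):
    """Expected score of one subject at week(s) ``t`` under a family."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative (weeks from baseline)")
    if family == "linear":
        return params["b0"] + params["b1"] * t
    if family == "quadratic":
        return params["b0"] + params["b1"] * t + params["b2"] * t**2
    if family == "exponential":
        lam = params["decay"] if "decay" in params else params["lam"]
        if lam < 0:
            raise ValueError("exponential decay rate must be >= 0")
        return params["b0"] * np.exp(-lam * t)
    raise ValueError(f"unknown family {family!r}")


def log_likelihood(dataset: StudyDataset, family: str, params: Mapping) -> float:
    """Total Gaussian log likelihood of a dataset under explicit parameters.

    ``params`` holds ``sigma`` plus per-subject parameter sequences aligned
    with ``dataset.series`` order (e.g. ``b0``, ``decay``).
    """
    sigma = float(params["sigma"])
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    names = ("b0", "decay") if family == "exponential" else _POLY_COEFS[family]
    total = 0.0
    for i, s in enumerate(dataset.series):
        subject = {k: np.asarray(params[k], dtype=float)[i] for k in names}
        mu = mean_trajectory(family, subject, s.times)
        total += float(np.sum(normal_lp(s.scores, mu, sigma)))
    return total


# ---------------------------------------------------------------------------
# Fitters


def _init_sigma(rng) -> float:
    return 3.0 * math.exp(0.1 * rng.standard_normal())


def _exponential_chain(packed: PackedData, priors: PriorConfig, warmup: int,
                       draws: int, rng: np.random.Generator, thin: int = 1):
    N, y, t, idx = packed.n_subjects, packed.y, packed.t, packed.idx

    b0 = np.clip(packed.first, 1.0, 63.0) + rng.normal(0.0, 1.0, N)
    with np.errstate(divide="ignore", invalid="ignore"):
        naive = np.log((packed.first + 1.0) / (packed.last + 1.0)) / packed.span
    lam = np.clip(np.nan_to_num(naive, nan=0.05), 1e-3, 1.0) * np.exp(
        rng.normal(0.0, 0.2, N)
    )
    mu_b0 = float(np.mean(b0))
    sd_b0 = float(np.std(b0) + 1.0)
    mu_lam = max(float(np.mean(lam)), 0.01)
    sd_lam = 0.05
    sigma = _init_sigma(rng)

    a_b0 = _Adapt(np.full(N, 1.0), 0.44)
    a_lam = _Adapt(np.full(N, 0.02), 0.44)
    a_sd_b0 = _Adapt(0.3, 0.44)
    a_mu_lam = _Adapt(0.02, 0.44)
    a_sd_lam = _Adapt(0.3, 0.44)
    a_sd_int = _Adapt(0.3, 0.44)
    a_sigma = _Adapt(0.1, 0.44)

    out = {k: np.empty((draws,) + shape) for k, shape in {
        "b0": (N,), "decay": (N,), "mu_b0": (), "sd_b0": (),
        "mu_decay": (), "sd_decay": (), "sigma": (),
    }.items()}

    for it in range(warmup + draws * thin):
        adapting = it < warmup

        def ll_b0(b0p):
            mu = b0p[idx] * np.exp(-lam[idx] * t)
            return packed.per_subject_sumsq(y - mu, sigma) + normal_lp(b0p, mu_b0, sd_b0)

        b0 = mh_vector(b0, a_b0.scale, ll_b0, rng, a_b0 if adapting else None)

        def ll_lam(lamp):
            mu = b0[idx] * np.exp(-lamp[idx] * t)
            return packed.per_subject_sumsq(y - mu, sigma) + truncnorm_pos_lp(
                lamp, mu_lam, sd_lam
            )

        lam = mh_vector(lam, a_lam.scale, ll_lam, rng, a_lam if adapting else None)

        mu_b0 = conj_normal_mean(b0, sd_b0, priors.b0_mean_loc, priors.b0_mean_scale, rng)
        sd_b0 = mh_scalar(
            sd_b0, a_sd_b0.scale,
            lambda s: float(np.sum(normal_lp(b0, mu_b0, s)) + halfnormal_lp(s, priors.b0_sd_scale)),
            rng, a_sd_b0 if adapting else None, log_scale=True,
        )
        mu_lam = mh_scalar(
            mu_lam, a_mu_lam.scale,
            lambda m: float(
                np.sum(truncnorm_pos_lp(lam, m, sd_lam))
                + truncnorm_pos_lp(m, priors.decay_mean_loc, priors.decay_mean_scale)
            ),
            rng, a_mu_lam if adapting else None,
        )
        sd_lam = mh_scalar(
            sd_lam, a_sd_lam.scale,
            lambda s: float(
                np.sum(truncnorm_pos_lp(lam, mu_lam, s))
                + halfnormal_lp(s, priors.decay_sd_scale)
            ),
            rng, a_sd_lam if adapting else None, log_scale=True,
        )
        # interweaved non-centered move on the decay SD: rescale all decay
        # deviations jointly with the SD to cross the hierarchy's funnel
        e = (lam - mu_lam) / sd_lam
        prop = sd_lam * math.exp(a_sd_int.scale * rng.standard_normal())
        lam_prop = mu_lam + prop * e
        if np.all(lam_prop >= 0.0):
            r_cur = y - b0[idx] * np.exp(-lam[idx] * t)
            r_prop = y - b0[idx] * np.exp(-lam_prop[idx] * t)
            delta = (
                (np.dot(r_cur, r_cur) - np.dot(r_prop, r_prop)) / (2.0 * sigma**2)
                + N * (float(_lnd(mu_lam / sd_lam)) - float(_lnd(mu_lam / prop)))
                + float(halfnormal_lp(prop, priors.decay_sd_scale))
                - float(halfnormal_lp(sd_lam, priors.decay_sd_scale))
                + math.log(prop) - math.log(sd_lam)
            )
        else:
            delta = -math.inf
        if adapting:
            a_sd_int.update(math.exp(min(delta, 0.0)) if math.isfinite(delta) else 0.0)
        if math.log(rng.random()) < delta:
            lam, sd_lam = lam_prop, prop

        resid = y - b0[idx] * np.exp(-lam[idx] * t)
        sse = float(np.dot(resid, resid))
        sigma = mh_scalar(
            sigma, a_sigma.scale,
            lambda s: -packed.n_obs * math.log(s) - sse / (2.0 * s * s)
            + float(halfnormal_lp(s, priors.sigma_scale)),
            rng, a_sigma if adapting else None, log_scale=True,
        )

        k_rec = it - warmup + 1
        if not adapting and k_rec % thin == 0:
            j = k_rec // thin - 1
            out["b0"][j] = b0
            out["decay"][j] = lam
            out["mu_b0"][j] = mu_b0
            out["sd_b0"][j] = sd_b0
            out["mu_decay"][j] = mu_lam
            out["sd_decay"][j] = sd_lam
            out["sigma"][j] = sigma
    return out


def _polynomial_chain(packed: PackedData, degree: int, priors: PriorConfig,
                      warmup: int, draws: int, rng: np.random.Generator,
                      X: np.ndarray | None = None,
                      coef_prior_scales: np.ndarray | None = None, thin: int = 1):
    """Linear (degree 1) or quadratic (degree 2) hierarchical chain.

    When ``X`` is given (subjects x regressors, intercept included), the
    slope prior mean is X @ alpha with conjugately updated regression
    coefficients — the strength-of-response model.
    """
    from ._mcmc import conj_linear_coefs

    N, y, t, idx = packed.n_subjects, packed.y, packed.t, packed.idx
    ncoef = degree + 1
    mean_locs = [priors.b0_mean_loc, priors.slope_mean_loc, priors.curv_mean_loc][:ncoef]
    mean_scales = [priors.b0_mean_scale, priors.slope_mean_scale, priors.curv_mean_scale][:ncoef]
    sd_scales = [priors.b0_sd_scale, priors.slope_sd_scale, priors.curv_sd_scale][:ncoef]

    b = np.zeros((ncoef, N))
    b[0] = np.clip(packed.first, 1.0, 63.0) + rng.normal(0.0, 1.0, N)
    b[1] = (packed.last - packed.first) / packed.span + rng.normal(0.0, 0.1, N)
    if ncoef > 2:
        b[2] = rng.normal(0.0, 0.01, N)

    mu = np.array([np.mean(b[c]) for c in range(ncoef)])
    sd = np.array([max(np.std(b[c]), 0.1) for c in range(ncoef)])
    sigma = _init_sigma(rng)
    alpha = None
    if X is not None:
        alpha = np.zeros(X.shape[1])
        alpha[0] = mu[1]

    powers = np.vstack([t**c for c in range(ncoef)])  # (ncoef, n_obs)
    # constant per-subject Gram blocks for the exact conjugate coefficient draws
    P = powers.T  # (n_obs, ncoef)
    PtP = np.zeros((N, ncoef, ncoef))
    Pty = np.zeros((N, ncoef))
    np.add.at(PtP, idx, P[:, :, None] * P[:, None, :])
    np.add.at(Pty, idx, P * y[:, None])

    a_sd = [_Adapt(0.3, 0.44) for _ in range(ncoef)]
    a_sigma = _Adapt(0.1, 0.44)

    keys = ["b0", "b1", "b2"][:ncoef]
    out = {k: np.empty((draws, N)) for k in keys}
    for k in keys:
        out[f"mu_{k}"] = np.empty(draws)
        out[f"sd_{k}"] = np.empty(draws)
    out["sigma"] = np.empty(draws)
    if X is not None:
        out["alpha_raw"] = np.empty((draws, X.shape[1]))

    def fitted():
        return (b[:, idx] * powers).sum(axis=0)

    eye = np.eye(ncoef)

    for it in range(warmup + draws * thin):
        adapting = it < warmup

        # subject coefficients: the model is linear-Gaussian given sigma and
        # the group level, so draw (b0_i, ..) jointly from the exact
        # multivariate-normal conditional (batched over subjects)
        prior_mean = np.tile(mu, (N, 1))
        if X is not None:
            prior_mean[:, 1] = X @ alpha
        prior_prec = 1.0 / sd**2
        A = PtP / sigma**2 + prior_prec * eye
        rhs = Pty / sigma**2 + prior_mean * prior_prec
        mean = np.linalg.solve(A, rhs[:, :, None])[:, :, 0]
        L = np.linalg.cholesky(A)
        zdraw = rng.standard_normal((N, ncoef, 1))
        b = (mean + np.linalg.solve(np.transpose(L, (0, 2, 1)), zdraw)[:, :, 0]).T

        for c in range(ncoef):
            if c == 1 and X is not None:
                alpha = conj_linear_coefs(b[1], X, sd[1], coef_prior_scales, rng)
                resid_c = b[1] - X @ alpha
                sd[c] = mh_scalar(
                    sd[c], a_sd[c].scale,
                    lambda s, r=resid_c: float(
                        np.sum(normal_lp(r, 0.0, s)) + halfnormal_lp(s, sd_scales[1])
                    ),
                    rng, a_sd[c] if adapting else None, log_scale=True,
                )
                continue
            mu[c] = conj_normal_mean(b[c], sd[c], mean_locs[c], mean_scales[c], rng)
            sd[c] = mh_scalar(
                sd[c], a_sd[c].scale,
                lambda s, c=c: float(
                    np.sum(normal_lp(b[c], mu[c], s)) + halfnormal_lp(s, sd_scales[c])
                ),
                rng, a_sd[c] if adapting else None, log_scale=True,
            )

        resid = y - fitted()
        sse = float(np.dot(resid, resid))
        sigma = mh_scalar(
            sigma, a_sigma.scale,
            lambda s: -packed.n_obs * math.log(s) - sse / (2.0 * s * s)
            + float(halfnormal_lp(s, priors.sigma_scale)),
            rng, a_sigma if adapting else None, log_scale=True,
        )

        k_rec = it - warmup + 1
        if not adapting and k_rec % thin == 0:
            j = k_rec // thin - 1
            for c, k in enumerate(keys):
                out[k][j] = b[c]
                out[f"sd_{k}"][j] = sd[c]
                out[f"mu_{k}"][j] = mu[c]
            out["sigma"][j] = sigma
            if X is not None:
                out["alpha_raw"][j] = alpha
                out["mu_b1"][j] = alpha[0]
    return out


def fit_hierarchical(
    dataset: StudyDataset,
    family: str,
    priors: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
    _X: np.ndarray | None = None,
    _coef_prior_scales: np.ndarray | None = None,
) -> PosteriorDraws:
    """Fit the single-population hierarchical model of one family by MCMC.

    Returns draws for all subject- and group-level parameters and sigma.
    Convergence is *not* asserted here; run the diagnostics module on the
    result.  Identical seed and config give identical draws.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if dataset.n_subjects == 0:
        raise ValueError("empty dataset")
    priors = priors or PriorConfig()
    sampler = sampler or SamplerConfig()
    packed = PackedData(dataset)

    chains = []
    for c in range(sampler.chains):
        rng = chain_rng(sampler.seed, c)
        if family == "exponential":
            chains.append(_exponential_chain(packed, priors, sampler.warmup, sampler.draws, rng,
                                             thin=sampler.thin))
        else:
            degree = 1 if family == "linear" else 2
            chains.append(
                _polynomial_chain(packed, degree, priors, sampler.warmup, sampler.draws,
                                  rng, X=_X, coef_prior_scales=_coef_prior_scales,
                                  thin=sampler.thin)
            )
    stacked = {k: np.stack([ch[k] for ch in chains]) for k in chains[0]}
    for k, v in stacked.items():
        if not np.all(np.isfinite(v)):
            raise FitError(f"non-finite draws for {k}")
    return PosteriorDraws(
        draws=stacked,
        subject_ids=list(packed.subject_ids),
        meta={
            "family": family,
            "seed": sampler.seed,
            "warmup": sampler.warmup,
            "chains": sampler.chains,
            "priors": priors,
        },
    )


# ---------------------------------------------------------------------------
# Family selection


def pointwise_log_likelihood(dataset: StudyDataset, draws: PosteriorDraws) -> np.ndarray:
    """Per-draw, per-observation log likelihood, shape (chain, draw, obs)."""
    packed = PackedData(dataset)
    idx, t, y = packed.idx, packed.t, packed.y
    family = draws.meta.get("family")
    sigma = draws["sigma"][..., None]
    if family == "exponential":
        mu = draws["b0"][:, :, idx] * np.exp(-draws["decay"][:, :, idx] * t)
    elif family in ("linear", "quadratic"):
        mu = draws["b0"][:, :, idx] + draws["b1"][:, :, idx] * t
        if family == "quadratic":
            mu = mu + draws["b2"][:, :, idx] * t**2
    elif family == "mixture_exponential":
        lam_eff = draws["decay"][:, :, idx] * draws["z"][:, :, idx]
        mu = draws["b0"][:, :, idx] * np.exp(-lam_eff * t)
    else:
        raise ValueError(f"cannot compute pointwise likelihood for {family!r}")
    return normal_lp(y, mu, sigma)


def select_family(
    dataset: StudyDataset,
    families: Sequence[str] = FAMILIES,
    sampler: SamplerConfig | None = None,
    priors: PriorConfig | None = None,
) -> pd.DataFrame:
    """Rank trajectory families by WAIC (higher elpd is better).

    Returns a table with one row per family: the estimated expected log
    pointwise predictive density (``elpd``), its standard error, the
    effective-parameter penalty, and the rank (1 = best).  Failed fits are
    retained with a note rather than aborting the comparison.
    """
    import arviz as az

    families = list(families)
    if len(families) < 2:
        raise ValueError(">=2 families required for model selection")
    rows = []
    for fam in families:
        try:
            draws = fit_hierarchical(dataset, fam, priors=priors, sampler=sampler)
            ll = pointwise_log_likelihood(dataset, draws)
            idata = az.from_dict(log_likelihood={"y": ll})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w = az.waic(idata, pointwise=False)
            elpd = float(w["elpd_waic"]) if "elpd_waic" in w.index else float(w["waic"])
            rows.append({"family": fam, "elpd": elpd,
                         "p_eff": float(w["p_waic"]), "se": float(w["se"]), "note": ""})
        except FitError as exc:
            rows.append({"family": fam, "elpd": float("nan"), "p_eff": float("nan"),
                         "se": float("nan"), "note": f"fit failed: {exc}"})
    table = pd.DataFrame(rows)
    table = table.sort_values("elpd", ascending=False, na_position="last").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table.attrs["criterion"] = (
        "WAIC: elpd = sum_i [log mean_s p(y_i | theta_s)] - p_eff, "
        "p_eff = sum_i var_s [log p(y_i | theta_s)]; higher elpd is better"
    )
    return table
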