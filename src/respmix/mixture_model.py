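"""Restricted 2-class latent growth mixture model of treatment response.

Subjects belong to a latent responder or nonresponder class.  The
nonresponder trajectory is restricted to be flat (exponential decay rate
fixed at 0, or zero slope/curvature in the quadratic variant) while the
responder class has a free, positive group-level decay — the restriction
that gives the classes their responder/nonresponder meaning and removes
label switching by construction.  Baseline levels share one group
distribution across classes.

Standardized baseline covariates enter the probability of responder
membership through a logit link:

    P(z_i = 1) = logistic(beta_0 + sum_k beta_k x_ik)

The sampler augments the chain with the class indicators z_i (Gibbs) and
updates the membership coefficients by Laplace-approximation independence
Metropolis steps.  A subject's responder probability P_resp is the
posterior mean of z_i, so classification uncertainty is fully propagated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, log_ndtr as _lnd

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
    laplace_logistic_mh,
    mh_scalar,
    mh_vector,
    normal_lp,
    truncnorm_pos_lp,
)
from .evidence import hdi as _hdi
from .trial_data import CovariateTable, StudyDataset, ValidationError

__all__ = [
    "ClassPosterior",
    "class_membership_prob",
    "fit_latent_class",
    "classify",
    "response_probability_curve",
]


@dataclass
class ClassPosterior:
    """Posterior of the latent-class model: membership and coefficients."""

    p_resp: pd.Series                 # per-subject posterior responder probability
    draws: PosteriorDraws             # full chain (beta, z, trajectory parameters)
    covariate_names: list[str] = field(default_factory=list)

    @property
    def beta(self) -> np.ndarray:
        """Membership coefficient draws, shape (chain, draw, 1 + n_covariates)."""
        return self.draws["beta"]

    def beta_draws(self, name: str) -> np.ndarray:
        """Pooled draws of one covariate's membership coefficient."""
        if name == "intercept":
            return self.draws.flat("beta")[:, 0]
        j = self.covariate_names.index(name)
        return self.draws.flat("beta")[:, 1 + j]


def class_membership_prob(x_row, beta_draw) -> float:
    """Responder probability for one standardized covariate row and one
    coefficient draw (intercept first)."""
    x = np.asarray(x_row, dtype=float)
    b = np.asarray(beta_draw, dtype=float)
    if len(b) != len(x) + 1:
        raise ValueError("beta_draw must hold intercept plus one coefficient per covariate")
    if np.any(np.isnan(x)):
        raise ValidationError("covariate row has missing values — impute first")
    return float(expit(b[0] + x @ b[1:]))


def _covariate_matrix(dataset: StudyDataset, covariates: CovariateTable | None):
    order = dataset.subject_ids
    if covariates is None:
        return np.ones((len(order), 1)), []
    pos = {s: i for i, s in enumerate(covariates.subject_ids)}
    rows = np.array([pos[s] for s in order])
    vals = covariates.values[rows]
    if np.any(np.isnan(vals)):
        raise ValidationError("covariates contain missing values — impute first")
    return np.column_stack([np.ones(len(order)), vals]), list(covariates.names)


#: quadrature nodes for integrating a subject's decay rate over its group
#: distribution in the class-indicator update (equal-probability-mass nodes)
_QUAD_NODES = 32


def _truncnorm_equal_mass_nodes(mu, sd, n, offset=None):
    """Equal-mass quantile nodes of normal(mu, sd) truncated to [0, inf).

    With ``offset`` in [0,1)^n the nodes are jittered inside their mass bins,
    which turns a categorical node draw into a continuous draw from the
    piecewise approximation.
    """
    from scipy.special import ndtr, ndtri

    base = float(ndtr(-mu / sd))  # mass below zero of the untruncated normal
    u = (np.arange(n) + 0.5) / n if offset is None else offset
    q = base + u * (1.0 - base)
    q = np.clip(q, 1e-12, 1.0 - 1e-12)
    return np.maximum(mu + sd * ndtri(q), 0.0)


def _mixture_exponential_chain(packed: PackedData, X, priors: PriorConfig,
                               warmup: int, draws: int, rng: np.random.Generator,
                               thin: int = 1):
    from scipy.special import logsumexp

    N, y, t, idx = packed.n_subjects, packed.y, packed.t, packed.idx
    K1 = X.shape[1]

    b0 = np.clip(packed.first, 1.0, 63.0) + rng.normal(0.0, 1.0, N)
    rel_drop = (packed.first - packed.last) / np.maximum(packed.first, 1.0)
    z = (rel_drop > 0.3).astype(float)
    lam = np.clip(rel_drop / packed.span, 1e-3, 1.0) * np.exp(rng.normal(0.0, 0.2, N))
    beta = rng.normal(0.0, 0.1, K1)
    mu_b0 = float(np.mean(b0))
    sd_b0 = float(np.std(b0) + 1.0)
    mu_lam = max(float(np.mean(lam[z == 1])) if np.any(z == 1) else 0.1, 0.01)
    sd_lam = 0.05
    sigma = 3.0 * math.exp(0.1 * rng.standard_normal())

    a_b0 = _Adapt(np.full(N, 1.0), 0.44)
    a_lam = _Adapt(np.full(N, 0.02), 0.44)
    a_sd_b0 = _Adapt(0.3, 0.44)
    a_mu_lam = _Adapt(0.02, 0.44)
    a_sd_lam = _Adapt(0.3, 0.44)
    a_sd_int = _Adapt(0.3, 0.44)
    a_sigma = _Adapt(0.1, 0.44)

    out = {
        "b0": np.empty((draws, N)), "decay": np.empty((draws, N)),
        "z": np.empty((draws, N)), "beta": np.empty((draws, K1)),
        "mu_b0": np.empty(draws), "sd_b0": np.empty(draws),
        "mu_decay": np.empty(draws), "sd_decay": np.empty(draws),
        "sigma": np.empty(draws),
    }

    for it in range(warmup + draws * thin):
        adapting = it < warmup

        # --- collapsed class-indicator update -------------------------------
        # Integrate each subject's decay over its group distribution (equal-
        # mass quadrature) so a flat subject cannot ride a near-zero decay
        # into the responder class; then redraw decay | z=1 from the same
        # piecewise-approximated conditional.
        nodes = _truncnorm_equal_mass_nodes(mu_lam, sd_lam, _QUAD_NODES)
        ll_nodes = np.empty((_QUAD_NODES, N))
        for q in range(_QUAD_NODES):
            mu = b0[idx] * np.exp(-nodes[q] * t)
            ll_nodes[q] = packed.per_subject_sumsq(y - mu, sigma)
        m1 = logsumexp(ll_nodes, axis=0) - math.log(_QUAD_NODES)
        m0 = packed.per_subject_sumsq(y - b0[idx], sigma)
        z = (rng.random(N) < expit(X @ beta + m1 - m0)).astype(float)

        w = np.exp(ll_nodes - ll_nodes.max(axis=0))
        cdf = np.cumsum(w, axis=0)
        u = rng.random(N) * cdf[-1]
        node_pick = (u[None, :] > cdf).sum(axis=0)
        jitter = (node_pick + rng.random(N)) / _QUAD_NODES
        lam = np.where(z == 1, _truncnorm_equal_mass_nodes(mu_lam, sd_lam, N, jitter), 0.0)

        # refine responders' decay under the exact conditional
        def ll_lam(lamp):
            mu = b0[idx] * np.exp(-lamp[idx] * t)
            ll = packed.per_subject_sumsq(y - mu, sigma)
            return np.where(z == 1, ll + truncnorm_pos_lp(lamp, mu_lam, sd_lam), -np.inf)

        lam_ref = mh_vector(np.where(z == 1, lam, mu_lam), a_lam.scale, ll_lam, rng,
                            a_lam if adapting else None)
        lam = np.where(z == 1, lam_ref, 0.0)

        def ll_b0(b0p):
            mu = b0p[idx] * np.exp(-lam[idx] * t)
            return packed.per_subject_sumsq(y - mu, sigma) + normal_lp(b0p, mu_b0, sd_b0)

        b0 = mh_vector(b0, a_b0.scale, ll_b0, rng, a_b0 if adapting else None)

        beta = laplace_logistic_mh(beta, z, X, priors.coef_scale, rng)

        mu_b0 = conj_normal_mean(b0, sd_b0, priors.b0_mean_loc, priors.b0_mean_scale, rng)
        sd_b0 = mh_scalar(
            sd_b0, a_sd_b0.scale,
            lambda s: float(np.sum(normal_lp(b0, mu_b0, s)) + halfnormal_lp(s, priors.b0_sd_scale)),
            rng, a_sd_b0 if adapting else None, log_scale=True,
        )
        resp = z == 1
        lam_resp = lam[resp]
        mu_lam = mh_scalar(
            mu_lam, a_mu_lam.scale,
            lambda m: float(
                np.sum(truncnorm_pos_lp(lam_resp, m, sd_lam))
                + truncnorm_pos_lp(m, priors.decay_mean_loc, priors.decay_mean_scale)
            ),
            rng, a_mu_lam if adapting else None,
        )
        sd_lam = mh_scalar(
            sd_lam, a_sd_lam.scale,
            lambda s: float(
                np.sum(truncnorm_pos_lp(lam_resp, mu_lam, s))
                + halfnormal_lp(s, priors.decay_sd_scale)
            ),
            rng, a_sd_lam if adapting else None, log_scale=True,
        )
        # interweaved non-centered scale move on the decay SD: rescale the
        # responders' decay deviations with the SD to cross the funnel
        n_resp = int(resp.sum())
        if n_resp:
            e = np.where(resp, (lam - mu_lam) / sd_lam, 0.0)
            prop = sd_lam * math.exp(a_sd_int.scale * rng.standard_normal())
            lam_prop = np.where(resp, mu_lam + prop * e, 0.0)
            if np.all(lam_prop >= 0.0):
                r_cur = y - b0[idx] * np.exp(-lam[idx] * t)
                r_prop = y - b0[idx] * np.exp(-lam_prop[idx] * t)
                delta = (
                    (np.dot(r_cur, r_cur) - np.dot(r_prop, r_prop)) / (2 * sigma**2)
                    + n_resp * (float(_lnd(mu_lam / sd_lam)) - float(_lnd(mu_lam / prop)))
                    + float(halfnormal_lp(prop, priors.decay_sd_scale))
                    - float(halfnormal_lp(sd_lam, priors.decay_sd_scale))
                    + math.log(prop) - math.log(sd_lam)
                )
            else:
                delta = -np.inf
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
            out["b0"][j], out["decay"][j], out["z"][j] = b0, lam, z
            out["beta"][j] = beta
            out["mu_b0"][j], out["sd_b0"][j] = mu_b0, sd_b0
            out["mu_decay"][j], out["sd_decay"][j] = mu_lam, sd_lam
            out["sigma"][j] = sigma
    return out


def _mixture_quadratic_chain(packed: PackedData, X, priors: PriorConfig,
                             warmup: int, draws: int, rng: np.random.Generator,
                             thin: int = 1):
    """Quadratic variant: responders follow b0 + b1 t + b2 t^2, nonresponders
    stay flat at b0.

    Given b0 and sigma the responder trajectory is linear-Gaussian in
    (b1, b2), so the class-indicator update uses the exact marginal
    likelihood (integrating (b1, b2) over their group normals) and the
    responder coefficients are redrawn from their exact bivariate-normal
    conditional — no Metropolis step is needed for them.
    """
    N, y, t, idx = packed.n_subjects, packed.y, packed.t, packed.idx
    K1 = X.shape[1]
    counts = packed.counts
    # constant per-subject sufficient statistics of the (slope, curvature) block
    T2 = np.column_stack([t, t**2])
    Sy = np.bincount(idx, weights=y, minlength=N)
    Syy = np.bincount(idx, weights=y * y, minlength=N)
    G = np.zeros((N, 2, 2))
    gy = np.zeros((N, 2))
    g1 = np.zeros((N, 2))
    np.add.at(G, idx, T2[:, :, None] * T2[:, None, :])
    np.add.at(gy, idx, T2 * y[:, None])
    np.add.at(g1, idx, T2)

    b0 = np.clip(packed.first, 1.0, 63.0) + rng.normal(0.0, 1.0, N)
    slope0 = (packed.last - packed.first) / packed.span
    z = (slope0 < -0.3).astype(float)
    b1 = np.where(z == 1, slope0, 0.0)
    b2 = np.zeros(N)
    beta = rng.normal(0.0, 0.1, K1)
    mu_b0, sd_b0 = float(np.mean(b0)), float(np.std(b0) + 1.0)
    mu_b1 = float(np.mean(slope0[z == 1])) if np.any(z == 1) else -0.5
    sd_b1, mu_b2, sd_b2 = 0.3, 0.0, 0.05
    sigma = 3.0 * math.exp(0.1 * rng.standard_normal())

    a_b0 = _Adapt(np.full(N, 1.0), 0.44)
    a_sds = {k: _Adapt(0.3, 0.44) for k in ("b0", "b1", "b2")}
    a_int = {1: _Adapt(0.3, 0.44), 2: _Adapt(0.3, 0.44)}
    a_sigma = _Adapt(0.1, 0.44)

    out = {
        "b0": np.empty((draws, N)), "b1": np.empty((draws, N)), "b2": np.empty((draws, N)),
        "z": np.empty((draws, N)), "beta": np.empty((draws, K1)),
        "mu_b0": np.empty(draws), "sd_b0": np.empty(draws),
        "mu_b1": np.empty(draws), "sd_b1": np.empty(draws),
        "mu_b2": np.empty(draws), "sd_b2": np.empty(draws),
        "sigma": np.empty(draws),
    }

    for it in range(warmup + draws * thin):
        adapting = it < warmup

        # --- collapsed (z, b1, b2) update -----------------------------------
        # marginal responder likelihood via the Woodbury identity and matrix
        # determinant lemma on the 2x2 (slope, curvature) block, batched
        prior_mean = np.array([mu_b1, mu_b2])
        prior_var = np.array([sd_b1**2, sd_b2**2])
        s2 = sigma**2
        gr = gy - b0[:, None] * g1                      # T' r  with r = y - b0
        rr = Syy - 2.0 * b0 * Sy + b0**2 * counts       # r' r
        m0 = -0.5 * rr / s2 - counts * (math.log(sigma) + 0.5 * math.log(2 * math.pi))
        Td = gr - G @ prior_mean                        # T' (r - T m)
        dd = rr - 2.0 * gr @ prior_mean + prior_mean @ G @ prior_mean
        M = s2 * np.diag(1.0 / prior_var) + G           # (N, 2, 2)
        sol = np.linalg.solve(M, Td[:, :, None])[:, :, 0]
        qf = (dd - np.einsum("ni,ni->n", Td, sol)) / s2
        B = np.eye(2) + prior_var[:, None] * G / s2
        logdetC = 2.0 * counts * math.log(sigma) + np.log(
            B[:, 0, 0] * B[:, 1, 1] - B[:, 0, 1] * B[:, 1, 0]
        )
        m1 = -0.5 * qf - 0.5 * logdetC - 0.5 * counts * math.log(2 * math.pi)
        z = (rng.random(N) < expit(X @ beta + m1 - m0)).astype(float)

        # exact bivariate-normal conditional draw of (b1, b2) for responders
        A = G / s2 + np.diag(1.0 / prior_var)
        rhs = gr / s2 + prior_mean / prior_var
        mean = np.linalg.solve(A, rhs[:, :, None])[:, :, 0]
        L = np.linalg.cholesky(A)
        bdraw = mean + np.linalg.solve(
            np.transpose(L, (0, 2, 1)), rng.standard_normal((N, 2, 1))
        )[:, :, 0]
        b1 = np.where(z == 1, bdraw[:, 0], 0.0)
        b2 = np.where(z == 1, bdraw[:, 1], 0.0)

        def ll_b0(p):
            mu = p[idx] + b1[idx] * t + b2[idx] * t**2
            return packed.per_subject_sumsq(y - mu, sigma) + normal_lp(p, mu_b0, sd_b0)

        b0 = mh_vector(b0, a_b0.scale, ll_b0, rng, a_b0 if adapting else None)

        beta = laplace_logistic_mh(beta, z, X, priors.coef_scale, rng)

        resp = z == 1
        mu_b0 = conj_normal_mean(b0, sd_b0, priors.b0_mean_loc, priors.b0_mean_scale, rng)
        mu_b1 = conj_normal_mean(b1[resp], sd_b1, priors.slope_mean_loc,
                                 priors.slope_mean_scale, rng)
        mu_b2 = conj_normal_mean(b2[resp], sd_b2, priors.curv_mean_loc,
                                 priors.curv_mean_scale, rng)
        for name, vals, mu_, scale_ in (
            ("b0", b0, mu_b0, priors.b0_sd_scale),
            ("b1", b1[resp], mu_b1, priors.slope_sd_scale),
            ("b2", b2[resp], mu_b2, priors.curv_sd_scale),
        ):
            cur = {"b0": sd_b0, "b1": sd_b1, "b2": sd_b2}[name]
            new = mh_scalar(
                cur, a_sds[name].scale,
                lambda s, vals=vals, mu_=mu_, scale_=scale_: float(
                    np.sum(normal_lp(vals, mu_, s)) + halfnormal_lp(s, scale_)
                ),
                rng, a_sds[name] if adapting else None, log_scale=True,
            )
            if name == "b0":
                sd_b0 = new
            elif name == "b1":
                sd_b1 = new
            else:
                sd_b2 = new

        # interweaved non-centered scale moves: rescale responder deviations
        # together with the group SD to cross the funnel at small SDs
        resp_idx = resp[idx]
        for which in (1, 2):
            vec = b1 if which == 1 else b2
            mu_c = mu_b1 if which == 1 else mu_b2
            sd_c = sd_b1 if which == 1 else sd_b2
            scale_c = priors.slope_sd_scale if which == 1 else priors.curv_sd_scale
            ad = a_int[which]
            e = np.where(resp, (vec - mu_c) / sd_c, 0.0)
            prop = sd_c * math.exp(ad.scale * rng.standard_normal())
            shift = (prop - sd_c) * e[idx] * (t if which == 1 else t**2)
            resid_cur = y - (b0[idx] + b1[idx] * t + b2[idx] * t**2)
            resid_prop = resid_cur - np.where(resp_idx, shift, 0.0)
            delta = (
                (np.dot(resid_cur, resid_cur) - np.dot(resid_prop, resid_prop)) / (2 * sigma**2)
                + float(halfnormal_lp(prop, scale_c)) - float(halfnormal_lp(sd_c, scale_c))
                + math.log(prop) - math.log(sd_c)
            )
            if adapting:
                ad.update(math.exp(min(delta, 0.0)) if math.isfinite(delta) else 0.0)
            if math.log(rng.random()) < delta:
                new_vec = np.where(resp, mu_c + prop * e, 0.0)
                if which == 1:
                    b1, sd_b1 = new_vec, prop
                else:
                    b2, sd_b2 = new_vec, prop

        resid = y - (b0[idx] + b1[idx] * t + b2[idx] * t**2)
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
            out["b0"][j], out["b1"][j], out["b2"][j], out["z"][j] = b0, b1, b2, z
            out["beta"][j] = beta
            out["mu_b0"][j], out["sd_b0"][j] = mu_b0, sd_b0
            out["mu_b1"][j], out["sd_b1"][j] = mu_b1, sd_b1
            out["mu_b2"][j], out["sd_b2"][j] = mu_b2, sd_b2
            out["sigma"][j] = sigma
    return out


def fit_latent_class(
    dataset: StudyDataset,
    covariates: CovariateTable | None = None,
    family: str = "exponential",
    priors: PriorConfig | None = None,
    sampler: SamplerConfig | None = None,
) -> ClassPosterior:
    """Fit the restricted 2-class model with covariates on class membership.

    ``covariates``, if given, must be standardized and imputed.  The
    returned :class:`ClassPosterior` carries per-subject responder
    probabilities (posterior means of the class indicators) and the full
    draws, including the membership coefficients ``beta`` (intercept first).
    """
    if family not in ("exponential", "quadratic"):
        raise ValueError("latent-class family must be 'exponential' or 'quadratic'")
    if dataset.n_subjects == 0:
        raise ValueError("empty dataset")
    priors = priors or PriorConfig()
    sampler = sampler or SamplerConfig()
    packed = PackedData(dataset)
    X, names = _covariate_matrix(dataset, covariates)

    chain_fn = _mixture_exponential_chain if family == "exponential" else _mixture_quadratic_chain
    chains = [
        chain_fn(packed, X, priors, sampler.warmup, sampler.draws,
                 chain_rng(sampler.seed, c), thin=sampler.thin)
        for c in range(sampler.chains)
    ]
    stacked = {k: np.stack([ch[k] for ch in chains]) for k in chains[0]}
    for k, v in stacked.items():
        if not np.all(np.isfinite(v)):
            raise FitError(f"non-finite draws for {k}")

    # identifiability check: the responder class must decay faster than the
    # (flat) nonresponder class in essentially all draws
    decay_proxy = stacked["mu_decay"] if family == "exponential" else -stacked["mu_b1"]
    violation = float(np.mean(decay_proxy <= 0.0))
    if violation > 0.01:
        warnings.warn(
            f"class-separation constraint violated in {violation:.1%} of draws; "
            "responder/nonresponder labels may be unstable",
            stacklevel=2,
        )

    draws = PosteriorDraws(
        draws=stacked,
        subject_ids=list(packed.subject_ids),
        coef_names=["intercept"] + names,
        meta={
            "family": f"mixture_{family}",
            "seed": sampler.seed,
            "warmup": sampler.warmup,
            "chains": sampler.chains,
            "priors": priors,
            "label_switch_fraction": violation,
        },
    )
    p_resp = pd.Series(
        draws.flat("z").mean(axis=0), index=packed.subject_ids, name="p_resp"
    )
    return ClassPosterior(p_resp=p_resp, draws=draws, covariate_names=names)


def classify(p_resp: pd.Series, threshold: float = 0.5):
    """Threshold responder probabilities into labels.

    Returns (labels, responder fraction); a subject is a responder iff
    ``p_resp >= threshold``.  The default threshold 0.5 is the natural
    posterior decision rule; 0.05 reproduces the published split criterion.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be strictly inside (0, 1)")
    p = pd.Series(p_resp)
    labels = p.map(lambda v: "responder" if v >= threshold else "nonresponder")
    labels.name = "class"
    fraction = float((p >= threshold).mean()) if len(p) else float("nan")
    return labels, fraction


def response_probability_curve(
    posterior: ClassPosterior,
    covariate: str,
    grid: Sequence[float],
    baseline: Mapping[str, float],
    mass: float = 0.95,
) -> pd.DataFrame:
    """Responder probability as a function of one covariate.

    All other covariates are held at the ``baseline`` row (standardized
    units).  Returns a tidy frame with posterior mean and HDI of the
    membership probability at each grid value.
    """
    if covariate not in posterior.covariate_names:
        raise KeyError(f"covariate {covariate!r} not in the fitted model")
    x0 = np.array([float(baseline[n]) for n in posterior.covariate_names])
    if np.any(np.isnan(x0)):
        raise ValidationError("baseline row has missing values")
    j = posterior.covariate_names.index(covariate)
    beta = posterior.draws.flat("beta")  # (S, K+1)
    rows = []
    for v in np.asarray(grid, dtype=float):
        x = x0.copy()
        x[j] = v
        probs = expit(beta[:, 0] + beta[:, 1:] @ x)
        lo, hi = _hdi(probs, mass)
        rows.append({"covariate": covariate, "value": float(v),
                     "mean": float(probs.mean()), "hdi_low": lo, "hdi_high": hi})
    return pd.DataFrame(rows)
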