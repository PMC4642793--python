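"""Adaptive Metropolis-within-Gibbs engine for the hierarchical growth models.

All models share the same skeleton, in the style of a hand-rolled Gibbs
sampler: vectorized random-walk Metropolis updates for the per-subject
trajectory parameters (conditionally independent given the group level),
conjugate draws for untruncated group means and regression coefficients,
and scalar log-scale random-walk updates for standard deviations and
truncated group means.  Proposal scales adapt toward standard acceptance
targets during warmup only, so the post-warmup chain is a valid Markov
chain.  Determinism: every chain derives its generator from
SeedSequence([seed, chain]), so identical seeds give identical draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_ndtr

LOG2PI = math.log(2.0 * math.pi)

__all__ = [
    "PriorConfig",
    "SamplerConfig",
    "PosteriorDraws",
    "FitError",
]


class FitError(RuntimeError):
    """Sampler failure (non-finite state, degenerate posterior)."""


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative priors on the raw score / weeks scale.

    Group-mean priors keep baseline trajectories in the plausible BDI-II
    range; coefficient priors are standard normal on standardized
    covariates, which the Savage-Dickey Bayes factors rely on.
    """

    b0_mean_loc: float = 20.0
    b0_mean_scale: float = 10.0
    decay_mean_loc: float = 0.1       # truncated >= 0
    decay_mean_scale: float = 0.2
    slope_mean_loc: float = 0.0
    slope_mean_scale: float = 2.0
    curv_mean_loc: float = 0.0
    curv_mean_scale: float = 0.5
    b0_sd_scale: float = 5.0          # half-normal scales
    slope_sd_scale: float = 5.0
    curv_sd_scale: float = 5.0
    decay_sd_scale: float = 0.5
    sigma_scale: float = 5.0
    coef_scale: float = 1.0           # class-membership / slope-regression coefficients

    def coef_prior_density_at_zero(self) -> float:
        return 1.0 / math.sqrt(2.0 * math.pi) / self.coef_scale


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 2000
    seed: int = 0
    thin: int = 1   # keep every thin-th post-warmup iteration

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required")
        if self.warmup < 1 or self.draws < 1:
            raise ValueError("warmup and draws must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorDraws:
    """Named posterior draws over (chain, draw[, subject/coefficient]).

    Scalar (group-level) parameters have shape (chains, draws); subject- or
    coefficient-indexed parameters carry a trailing axis.
    """

    draws: dict[str, np.ndarray]
    subject_ids: list[str] = field(default_factory=list)
    coef_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {v.shape[:2] for v in self.draws.values()}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent chain/draw shapes: {shapes}")
        if self.draws and next(iter(shapes))[0] < 2:
            raise ValueError("at least 2 chains required")

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def names(self) -> list[str]:
        return list(self.draws)

    def group_level_names(self) -> list[str]:
        return [k for k, v in self.draws.items() if v.ndim == 2]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name]

    def flat(self, name: str) -> np.ndarray:
        """All chains pooled, shape (chains*draws, ...)."""
        v = self.draws[name]
        return v.reshape(-1, *v.shape[2:])

    def to_frame(self, names=None):
        """Tidy (chain, draw, parameter, value) table for external inspection."""
        import pandas as pd

        names = list(names) if names is not None else self.group_level_names()
        rows = []
        for name in names:
            v = self.draws[name]
            if v.ndim != 2:
                raise ValueError(f"{name} is not a scalar parameter; export per-index slices")
            for c in range(v.shape[0]):
                rows.append(pd.DataFrame({
                    "chain": c,
                    "draw": np.arange(v.shape[1]),
                    "parameter": name,
                    "value": v[c],
                }))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Density helpers (unnormalized where constants cancel, normalized where not)


def normal_lp(x, loc, scale):
    return -0.5 * ((x - loc) / scale) ** 2 - np.log(scale) - 0.5 * LOG2PI


def halfnormal_lp(x, scale):
    x = np.asarray(x, dtype=float)
    out = np.where(
        x > 0,
        0.5 * math.log(2.0 / math.pi) - math.log(scale) - 0.5 * (x / scale) ** 2,
        -np.inf,
    )
    return out


def truncnorm_pos_lp(x, loc, scale):
    """log density of normal(loc, scale) truncated to [0, inf)."""
    x = np.asarray(x, dtype=float)
    base = normal_lp(x, loc, scale) - log_ndtr(loc / scale)
    return np.where(x >= 0, base, -np.inf)


# ---------------------------------------------------------------------------
# Metropolis building blocks


class _Adapt:
    """Robbins-Monro adaptation of a log proposal scale during warmup."""

    def __init__(self, init_scale, target: float):
        self.log_s = np.log(np.asarray(init_scale, dtype=float))
        self.target = target
        self.k = 0

    @property
    def scale(self):
        return np.exp(self.log_s)

    def update(self, accept_prob):
        self.k += 1
        gamma = min(0.25, self.k ** -0.6)
        self.log_s = self.log_s + gamma * (accept_prob - self.target)


def mh_vector(x, scale, logpost, rng, adapt: _Adapt | None):
    """Independent per-component random-walk MH (the components' conditionals
    must be independent, as subject-level parameters are given the group level)."""
    lp_cur = logpost(x)
    prop = x + scale * rng.standard_normal(x.shape)
    lp_prop = logpost(prop)
    with np.errstate(invalid="ignore"):
        delta = lp_prop - lp_cur
    delta = np.where(np.isnan(delta), -np.inf, delta)
    accept = np.log(rng.random(x.shape)) < delta
    x_new = np.where(accept, prop, x)
    if adapt is not None:
        adapt.update(np.exp(np.minimum(delta, 0.0)))
    return x_new


def mh_scalar(x, scale, logpost, rng, adapt: _Adapt | None, log_scale=False):
    """Scalar random-walk MH, optionally on the log of a positive parameter
    (with the Jacobian term)."""
    if log_scale:
        cur = math.log(x)
        prop = cur + scale * rng.standard_normal()
        lp_cur = logpost(math.exp(cur)) + cur
        lp_prop = logpost(math.exp(prop)) + prop
        x_prop = math.exp(prop)
    else:
        prop = x + scale * rng.standard_normal()
        lp_cur = logpost(x)
        lp_prop = logpost(prop)
        x_prop = prop
    delta = lp_prop - lp_cur
    if math.isnan(delta):
        delta = -math.inf
    accepted = math.log(rng.random()) < delta
    if adapt is not None:
        adapt.update(math.exp(min(delta, 0.0)))
    return x_prop if accepted else x


def conj_normal_mean(values, pop_sd, prior_loc, prior_scale, rng):
    """Conjugate draw of a normal population mean with a normal prior."""
    n = len(values)
    prec = n / pop_sd**2 + 1.0 / prior_scale**2
    mean = (values.sum() / pop_sd**2 + prior_loc / prior_scale**2) / prec
    return mean + rng.standard_normal() / math.sqrt(prec)


def conj_linear_coefs(y, X, noise_sd, prior_scales, rng):
    """Conjugate draw of ridge-regression coefficients: y ~ N(X c, noise_sd^2),
    c_j ~ N(0, prior_scales_j^2).  Returns one draw of c."""
    XtX = X.T @ X / noise_sd**2
    prec = XtX + np.diag(1.0 / np.asarray(prior_scales) ** 2)
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, X.T @ y / noise_sd**2)
    z = rng.standard_normal(len(mean))
    return mean + np.linalg.solve(L.T, z)


def laplace_logistic_mh(beta, z, X, prior_sd, rng, newton_iter=25):
    """Independence MH for logistic-regression coefficients given 0/1 outcomes,
    proposing from the Laplace (mode + Hessian) approximation of the conditional."""
    prior_prec = 1.0 / prior_sd**2

    def logpost(b):
        eta = X @ b
        # log Bernoulli likelihood, numerically stable
        ll = np.sum(np.where(z == 1, -np.logaddexp(0.0, -eta), -np.logaddexp(0.0, eta)))
        return ll - 0.5 * prior_prec * np.dot(b, b)

    # Newton from the current state to the conditional mode
    m = beta.copy()
    for _ in range(newton_iter):
        p = expit(X @ m)
        grad = X.T @ (z - p) - prior_prec * m
        W = p * (1.0 - p)
        H = X.T @ (X * W[:, None]) + prior_prec * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        m = m + step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = expit(X @ m)
    W = np.maximum(p * (1.0 - p), 1e-10)
    H = X.T @ (X * W[:, None]) + prior_prec * np.eye(X.shape[1])
    L = np.linalg.cholesky(H)

    def q_lp(b):
        d = L.T @ (b - m)
        return -0.5 * np.dot(d, d)

    prop = m + np.linalg.solve(L.T, rng.standard_normal(len(m)))
    delta = (logpost(prop) - q_lp(prop)) - (logpost(beta) - q_lp(beta))
    if math.log(rng.random()) < delta:
        return prop
    return beta


# ---------------------------------------------------------------------------
# Data packing shared by all fitters


class PackedData:
    """Flat observation arrays with a subject index, for vectorized likelihoods."""

    def __init__(self, dataset):
        series = dataset.series
        self.subject_ids = [s.subject_id for s in series]
        self.n_subjects = len(series)
        self.y = np.concatenate([s.scores for s in series]) if series else np.empty(0)
        self.t = np.concatenate([s.times for s in series]) if series else np.empty(0)
        self.idx = (
            np.concatenate([np.full(len(s), i) for i, s in enumerate(series)])
            if series
            else np.empty(0, dtype=int)
        )
        self.counts = np.bincount(self.idx, minlength=self.n_subjects).astype(float)
        self.n_obs = len(self.y)
        # crude per-subject summaries used for initialization
        self.first = np.array([s.scores[0] for s in series]) if series else np.empty(0)
        self.last = np.array([s.scores[-1] for s in series]) if series else np.empty(0)
        self.span = np.array([max(s.times[-1], 1.0) for s in series]) if series else np.empty(0)

    def per_subject_sumsq(self, resid, sigma):
        """Per-subject Gaussian log likelihood given flat residuals."""
        per = -0.5 * (resid / sigma) ** 2
        return np.bincount(self.idx, weights=per, minlength=self.n_subjects) - self.counts * (
            math.log(sigma) + 0.5 * LOG2PI
        )


def chain_rng(seed: int, chain: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(chain,)))


def check_finite(state: dict) -> None:
    for k, v in state.items():
        if not np.all(np.isfinite(v)):
            raise FitError(f"sampler produced non-finite value for {k}")
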