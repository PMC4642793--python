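"""Convergence diagnostics and posterior predictive checks.

R-hat is the split-chain potential scale reduction factor: each chain is
halved, and the between- and within-half variances are combined as

    Rhat = sqrt(((n - 1)/n * W + B/n) / W)

so values near 1 indicate the chains agree.  Posterior predictive checks
replicate the dataset from the fitted observation model at sampled
parameter draws and compare observed weekly mean/SD summaries with the
replicated envelope (visit times are irregular, so summaries are binned to
integer weeks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._mcmc import PosteriorDraws
from .trial_data import StudyDataset

__all__ = [
    "ConvergenceReport",
    "PpcReport",
    "gelman_rubin",
    "convergence_report",
    "posterior_predictive",
]

RHAT_THRESHOLD = 1.05


def gelman_rubin(chains) -> float:
    """Split-chain potential scale reduction for one scalar parameter.

    ``chains`` has shape (n_chains, n_draws) with at least 2 chains and 10
    draws each.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("chains must be a 2-D (chain, draw) array")
    m, n = x.shape
    if m < 2:
        raise ValueError("at least 2 chains required")
    if n < 10:
        raise ValueError("at least 10 draws per chain required")
    half = n // 2
    split = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    n_half = split.shape[1]
    within = np.mean(np.var(split, axis=1, ddof=1))
    between = n_half * np.var(np.mean(split, axis=1), ddof=1)
    if within == 0.0:
        return 1.0  # all half-chains constant and equal
    return float(np.sqrt((between / within + n_half - 1) / n_half))


@dataclass
class ConvergenceReport:
    """Per-parameter R-hat with a pass flag at a stated threshold."""

    rhat: pd.Series
    threshold: float = RHAT_THRESHOLD

    @property
    def passed(self) -> bool:
        return bool((self.rhat < self.threshold).all())

    @property
    def worst(self) -> float:
        return float(self.rhat.max())

    def to_frame(self) -> pd.DataFrame:
        df = self.rhat.rename("rhat").rename_axis("parameter").reset_index()
        df["pass"] = df["rhat"] < self.threshold
        return df


def convergence_report(
    draws: PosteriorDraws, threshold: float = RHAT_THRESHOLD
) -> ConvergenceReport:
    """R-hat for every group-level (scalar) parameter of a fit."""
    vals = {}
    for name in draws.group_level_names():
        vals[name] = gelman_rubin(draws[name])
    return ConvergenceReport(rhat=pd.Series(vals), threshold=threshold)


@dataclass
class PpcReport:
    """Observed vs replicated weekly summaries.

    ``table`` has one row per (week bin, statistic) with the observed value,
    the replicated 2.5/50/97.5% envelope and a tail probability
    P(replicated >= observed).
    """

    table: pd.DataFrame
    n_rep: int

    def coverage(self, stat: str = "mean") -> float:
        """Fraction of week bins whose observed summary lies inside the
        95% replicated envelope."""
        sub = self.table[self.table["stat"] == stat]
        inside = (sub["observed"] >= sub["q025"]) & (sub["observed"] <= sub["q975"])
        return float(inside.mean())


def _replicated_means(draws: PosteriorDraws, idx, t):
    """Flat (sample, obs) matrix of model means for every posterior sample."""
    family = draws.meta.get("family", "")
    d = {k: draws.flat(k) for k in draws.names()}
    if family == "exponential":
        return d["b0"][:, idx] * np.exp(-d["decay"][:, idx] * t)
    if family == "mixture_exponential":
        lam_eff = d["decay"][:, idx] * d["z"][:, idx]
        return d["b0"][:, idx] * np.exp(-lam_eff * t)
    if family == "linear":
        return d["b0"][:, idx] + d["b1"][:, idx] * t
    if family == "quadratic":
        return d["b0"][:, idx] + d["b1"][:, idx] * t + d["b2"][:, idx] * t**2
    if family == "mixture_quadratic":
        zi = d["z"][:, idx]
        return d["b0"][:, idx] + zi * (d["b1"][:, idx] * t + d["b2"][:, idx] * t**2)
    raise ValueError(f"posterior predictive not implemented for family {family!r}")


def posterior_predictive(
    dataset: StudyDataset,
    draws: PosteriorDraws,
    n_rep: int = 200,
    rng: np.random.Generator | int | None = None,
) -> PpcReport:
    """Posterior predictive check of weekly score means and SDs.

    ``n_rep`` replicated datasets are simulated on the observed time grids
    from the fitted observation model at randomly chosen posterior draws.
    """
    if n_rep == 0:
        raise ValueError("n_rep must be positive")
    if n_rep < 50:
        import warnings

        warnings.warn(f"n_rep={n_rep} is small; envelope will be noisy", stacklevel=2)
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)

    from ._mcmc import PackedData

    packed = PackedData(dataset)
    idx, t, y = packed.idx, packed.t, packed.y
    bins = np.floor(t).astype(int)

    n_samples = draws.n_chains * draws.n_draws
    pick = rng.choice(n_samples, size=n_rep, replace=n_rep > n_samples)
    mu = _replicated_means(draws, idx, t)[pick]
    sigma = draws.flat("sigma")[pick][:, None]
    reps = mu + rng.normal(size=mu.shape) * sigma
    reps = np.round(np.clip(reps, 0, 63))

    rows = []
    for b in np.unique(bins):
        sel = bins == b
        obs_vals = y[sel]
        rep_vals = reps[:, sel]
        for stat, obs_s, rep_s in (
            ("mean", float(obs_vals.mean()), rep_vals.mean(axis=1)),
            ("sd", float(obs_vals.std(ddof=0)), rep_vals.std(axis=1, ddof=0)),
        ):
            q025, q500, q975 = np.percentile(rep_s, [2.5, 50.0, 97.5])
            rows.append({
                "week_bin": int(b), "stat": stat, "n_obs": int(sel.sum()),
                "observed": obs_s, "q025": float(q025), "q500": float(q500),
                "q975": float(q975), "tail_prob": float(np.mean(rep_s >= obs_s)),
            })
    return PpcReport(table=pd.DataFrame(rows), n_rep=n_rep)
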