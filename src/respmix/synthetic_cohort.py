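"""Seeded generator of trial-like cohorts with known ground truth.

Emulates the structure of a guided internet-CBT depression trial: ~82
subjects, baseline BDI-II restricted to 10-40 (mean 21.3, SD 6.6), up to
11 measurement occasions over a treatment span of mean 9.6 / SD 4.8 weeks
(range 1-22), a latent responder/nonresponder split near 74%/26%, and ~20
baseline covariates with realistic marginals and MCAR missingness.

Responders decay exponentially toward low scores; nonresponders stay flat.
Covariates can shift class membership (logit scale) and, in the quadratic
world, the individual linear slope — the ground truths the recovery tests
measure against.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
import numpy as np
from scipy import stats
from scipy.special import expit

from .trial_data import (
    CovariateTable,
    MeasurementSeries,
    StudyDataset,
    ValidationError,
    impute_covariates,
    standardize_covariates,
)

__all__ = [
    "CovariateSpec",
    "GeneratorConfig",
    "GroundTruth",
    "default_covariate_specs",
    "sample_schedule",
    "sample_covariates",
    "assign_classes",
    "simulate_trajectories",
    "generate",
]


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution and missingness rate for one baseline covariate."""

    name: str
    kind: str  # binary | ordinal | continuous
    p: float | None = None                    # binary: P(value = 1)
    levels: tuple[int, ...] | None = None     # ordinal levels
    probs: tuple[float, ...] | None = None    # ordinal level probabilities
    mean: float | None = None                 # continuous
    sd: float | None = None
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"{self.name}: missing_rate outside [0, 1]")
        if self.kind == "binary":
            if self.p is None or not 0.0 <= self.p <= 1.0:
                raise ValueError(f"{self.name}: binary spec needs p in [0, 1]")
        elif self.kind == "ordinal":
            if not self.levels or not self.probs or len(self.levels) != len(self.probs):
                raise ValueError(f"{self.name}: ordinal spec needs matching levels/probs")
            if any(q < 0 for q in self.probs) or abs(sum(self.probs) - 1.0) > 1e-8:
                raise ValueError(f"{self.name}: ordinal probs must be a distribution")
        elif self.kind == "continuous":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise ValueError(f"{self.name}: continuous spec needs mean and sd > 0")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")


def default_covariate_specs() -> list[CovariateSpec]:
    """The 20 baseline predictors of the emulated trial, with its marginals.

    Binary proportions, continuous means/SDs, the episode-count distribution
    (0 = no lifetime episode ... 3 = five or more) and per-covariate
    missingness rates follow the published participant-characteristics table.
    """
    ep = np.array([6, 33, 31, 23], dtype=float)
    ep /= ep.sum()
    return [
        CovariateSpec("gender_female", "binary", p=0.73),
        CovariateSpec("age", "continuous", mean=36.0, sd=11.7),
        CovariateSpec("marital", "binary", p=0.54),
        CovariateSpec("employment", "binary", p=0.68),
        CovariateSpec("bai", "continuous", mean=13.0, sd=10.2),
        CovariateSpec("hads_d", "continuous", mean=8.3, sd=2.9, missing_rate=0.04),
        CovariateSpec("hads_a", "continuous", mean=9.7, sd=4.1, missing_rate=0.04),
        CovariateSpec("swls", "continuous", mean=16.7, sd=5.1, missing_rate=0.10),
        CovariateSpec("eq5d", "continuous", mean=0.7, sd=0.2, missing_rate=0.11),
        CovariateSpec("audit", "continuous", mean=5.0, sd=4.1, missing_rate=0.01),
        CovariateSpec("depression_diagnosis", "binary", p=0.54),
        CovariateSpec(
            "n_depressive_episodes", "ordinal",
            levels=(0, 1, 2, 3), probs=tuple(ep), missing_rate=0.07,
        ),
        CovariateSpec("anxiety_diagnosis", "binary", p=0.33),
        CovariateSpec("earlier_treatment", "binary", p=0.60, missing_rate=0.02),
        CovariateSpec("warpy_thoughts", "continuous", mean=82.8, sd=25.1, missing_rate=0.02),
        CovariateSpec("gse", "continuous", mean=26.6, sd=4.9, missing_rate=0.02),
        CovariateSpec("expectancy", "continuous", mean=2.6, sd=0.7),
        CovariateSpec("attitude", "continuous", mean=4.1, sd=0.8),
        CovariateSpec("motivation", "continuous", mean=94.0, sd=12.2),
        CovariateSpec("modules", "continuous", mean=3.8, sd=1.7),
    ]


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the emulated trial's conditions."""

    n_subjects: int = 82
    seed: int = 0
    #: logit-scale intercept of the responder class; logit(0.74) gives the 74/26 split
    responder_intercept: float = 1.0459
    true_beta: dict[str, float] = field(default_factory=dict)
    true_alpha: dict[str, float] = field(default_factory=dict)
    responder_decay_mean: float = 0.15    # week^-1
    responder_decay_sd: float = 0.03
    nonresponder_decay_mean: float = 0.0
    nonresponder_decay_sd: float = 0.01
    baseline_mean: float = 21.3           # BDI-II units, truncated to [10, 40]
    baseline_sd: float = 6.6
    residual_sd: float = 3.0
    duration_mean: float = 9.6            # weeks
    duration_sd: float = 4.8
    duration_range: tuple[float, float] = (1.0, 22.0)
    max_occasions: int = 11
    dropout_hazard: float = 0.10          # per-session stopping probability
    covariate_specs: list[CovariateSpec] = field(default_factory=default_covariate_specs)
    family: str = "exponential"           # generative world: exponential | quadratic
    # quadratic-world trajectory parameters (BDI-II units per week)
    responder_slope_mean: float = -1.2
    responder_slope_sd: float = 0.3
    nonresponder_slope_mean: float = 0.0
    nonresponder_slope_sd: float = 0.1
    curvature_mean: float = 0.04
    curvature_sd: float = 0.02

    def __post_init__(self) -> None:
        for name in ("responder_decay_sd", "nonresponder_decay_sd", "baseline_sd",
                     "residual_sd", "duration_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.duration_range
        if not (0 < lo <= hi <= 52):
            raise ValueError("duration_range must lie within (0, 52]")
        if not 0.0 <= self.dropout_hazard <= 1.0:
            raise ValueError("dropout_hazard must be in [0, 1]")
        if self.max_occasions < 2:
            raise ValueError("max_occasions must be >= 2")
        if self.family not in ("exponential", "quadratic"):
            raise ValueError(f"unknown generative family {self.family!r}")

    def fingerprint(self) -> str:
        payload = asdict(self)
        payload["covariate_specs"] = [asdict(s) for s in self.covariate_specs]
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Per-subject generative truth for recovery tests."""

    subject_ids: list[str]
    class_labels: list[str]              # "responder" | "nonresponder"
    subject_params: dict[str, np.ndarray]  # b0, decay (exp) or b1/b2 (quad)
    responder_probs: np.ndarray          # generative P(responder | covariates)
    config: GeneratorConfig

    @property
    def responder_fraction(self) -> float:
        if not self.class_labels:
            return float("nan")
        return sum(l == "responder" for l in self.class_labels) / len(self.class_labels)


def _truncnorm(mean, sd, lo, hi, size, rng):
    if lo == hi:
        return np.full(size, float(lo))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_schedule(config: GeneratorConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Per-subject measurement grids: t=0 plus k-1 jittered session times.

    The number of post-baseline occasions follows a geometric stopping rule
    with the configured per-session dropout hazard, capped at
    ``max_occasions``; the total span is a normal draw truncated to the
    configured duration range, split into positive jittered gaps.
    """
    n = config.n_subjects
    lo, hi = config.duration_range
    spans = _truncnorm(config.duration_mean, config.duration_sd, lo, hi, n, rng)
    if config.dropout_hazard <= 0.0:
        extra = np.full(n, config.max_occasions - 2, dtype=int)
    else:
        # survivals before first dropout, counted after the first session
        extra = np.minimum(
            rng.geometric(config.dropout_hazard, size=n) - 1, config.max_occasions - 2
        )
    schedules = []
    for i in range(n):
        k = 2 + int(extra[i])
        gaps = rng.gamma(shape=10.0, scale=1.0, size=k - 1)
        times = np.concatenate([[0.0], spans[i] * np.cumsum(gaps) / gaps.sum()])
        schedules.append(times)
    return schedules


def sample_covariates(config: GeneratorConfig, rng: np.random.Generator) -> CovariateTable:
    """Draw baseline covariates from their marginal specs with MCAR missingness."""
    n = config.n_subjects
    ids = [f"s{i + 1:03d}" for i in range(n)]
    names, kinds, cols = [], {}, []
    for spec in config.covariate_specs:
        if spec.kind == "binary":
            col = (rng.random(n) < spec.p).astype(float)
        elif spec.kind == "ordinal":
            col = rng.choice(np.asarray(spec.levels, dtype=float), size=n, p=spec.probs)
        else:
            col = rng.normal(spec.mean, spec.sd, size=n)
        if spec.missing_rate > 0:
            col = col.copy()
            col[rng.random(n) < spec.missing_rate] = np.nan
        names.append(spec.name)
        kinds[spec.name] = spec.kind
        cols.append(col)
    values = np.column_stack(cols) if cols else np.empty((n, 0))
    return CovariateTable(subject_ids=ids, names=names, kinds=kinds, values=values)


def assign_classes(
    covariates: CovariateTable, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli class labels from the logit-linear membership model.

    ``covariates`` must be standardized and imputed (missing values are an
    error here).  Returns (boolean responder labels, generative probabilities).
    """
    eta = np.full(covariates.n_subjects, config.responder_intercept, dtype=float)
    for name, beta in config.true_beta.items():
        if name not in covariates.names:
            raise KeyError(f"true_beta covariate {name!r} not in table")
        col = covariates.column(name)
        if np.any(np.isnan(col)):
            raise ValidationError(f"covariate {name}: missing values — impute first")
        eta += beta * col
    probs = expit(eta)
    labels = rng.random(covariates.n_subjects) < probs
    return labels, probs


def simulate_trajectories(
    labels: np.ndarray,
    schedules: list[np.ndarray],
    covariates: CovariateTable,
    config: GeneratorConfig,
    rng: np.random.Generator,
    standardized_covariates: CovariateTable | None = None,
) -> tuple[StudyDataset, GroundTruth]:
    """Simulate BDI-II series given class labels and visit schedules.

    Exponential world: y_ij = round(clamp(b0_i * exp(-decay_i * t_ij) + eps)).
    Quadratic world: y_ij = round(clamp(b0_i + b1_i t + b2_i t^2 + eps)) where
    b1_i is shifted by -sum_k alpha_k x_ik (positive alpha = faster decline).
    Baselines are truncated to the trial's 10-40 inclusion window and decay
    rates at zero; scores are clamped to the BDI-II range and rounded.
    """
    n = config.n_subjects
    labels = np.asarray(labels, dtype=bool)
    if len(labels) != n or len(schedules) != n:
        raise ValueError("labels/schedules misaligned with n_subjects")
    ids = covariates.subject_ids
    b0 = _truncnorm(config.baseline_mean, config.baseline_sd, 10.0, 40.0, n, rng)

    params: dict[str, np.ndarray] = {"b0": b0}
    if config.family == "exponential":
        mean_ = np.where(labels, config.responder_decay_mean, config.nonresponder_decay_mean)
        sd_ = np.where(labels, config.responder_decay_sd, config.nonresponder_decay_sd)
        decay = stats.truncnorm.rvs(
            -mean_ / sd_, np.inf, loc=mean_, scale=sd_, size=n, random_state=rng
        )
        params["decay"] = decay
    else:
        mean_ = np.where(labels, config.responder_slope_mean, config.nonresponder_slope_mean)
        sd_ = np.where(labels, config.responder_slope_sd, config.nonresponder_slope_sd)
        b1 = rng.normal(mean_, sd_)
        if config.true_alpha:
            std = standardized_covariates if standardized_covariates is not None else covariates
            for name, alpha in config.true_alpha.items():
                if name not in std.names:
                    raise KeyError(f"true_alpha covariate {name!r} not in table")
                col = std.column(name)
                if np.any(np.isnan(col)):
                    raise ValidationError(f"covariate {name}: missing values — impute first")
                b1 = b1 - alpha * col  # positive alpha = faster symptom decline
        # nonresponders are flat: curvature belongs to the responding trajectory
        b2 = np.where(labels, rng.normal(config.curvature_mean, config.curvature_sd, size=n), 0.0)
        params["b1"], params["b2"] = b1, b2

    series = []
    for i in range(n):
        t = schedules[i]
        if config.family == "exponential":
            mu = b0[i] * np.exp(-params["decay"][i] * t)
        else:
            mu = b0[i] + params["b1"][i] * t + params["b2"][i] * t**2
        y = np.round(np.clip(mu + rng.normal(0.0, config.residual_sd, size=len(t)), 0, 63))
        series.append(MeasurementSeries(ids[i], t, y))

    dataset = StudyDataset(series=series, covariates=covariates)
    truth = GroundTruth(
        subject_ids=list(ids),
        class_labels=["responder" if l else "nonresponder" for l in labels],
        subject_params=params,
        responder_probs=np.empty(0),
        config=config,
    )
    return dataset, truth


def generate(config: GeneratorConfig) -> tuple[StudyDataset, GroundTruth]:
    """Full cohort draw: schedules, covariates, classes, trajectories.

    Fully reproducible given ``config.seed``; the dataset's metadata records
    the seed and a config fingerprint.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if config.n_subjects == 0:
        empty_cov = CovariateTable([], [s.name for s in config.covariate_specs],
                                   {s.name: s.kind for s in config.covariate_specs},
                                   np.empty((0, len(config.covariate_specs))))
        dataset = StudyDataset(series=[], covariates=empty_cov,
                               metadata={"seed": config.seed,
                                         "config_fingerprint": config.fingerprint()})
        truth = GroundTruth([], [], {}, np.empty(0), config)
        return dataset, truth

    schedules = sample_schedule(config, rng)
    covariates = sample_covariates(config, rng)
    if covariates.names:
        std, _ = standardize_covariates(covariates)
        std = impute_covariates(std, "mean")
    else:
        std = covariates
    labels, probs = assign_classes(std, config, rng)
    dataset, truth = simulate_trajectories(
        labels, schedules, covariates, config, rng, standardized_covariates=std
    )
    truth.responder_probs = probs
    dataset.metadata.update(seed=config.seed, config_fingerprint=config.fingerprint())
    dataset.validate()
    return dataset, truth
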