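"""Domain types and IO for longitudinal depression-score studies.

A study consists of repeated BDI-II measurements per subject (irregular
visit times, in weeks from the pre-treatment baseline) plus one row of
baseline covariates per subject.  Covariates are typed (binary, ordinal,
continuous) and may contain missing values up to a hard cap.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "FormatError",
    "MeasurementSeries",
    "CovariateTable",
    "ScalingRecord",
    "StudyDataset",
    "read_long_csv",
    "write_long_csv",
    "read_covariates_csv",
    "write_covariates_csv",
    "standardize_covariates",
    "impute_covariates",
]

SCORE_MIN = 0
SCORE_MAX = 63  # BDI-II total range

COVARIATE_KINDS = ("binary", "ordinal", "continuous")

#: missingness fraction per covariate above which loading is a hard error;
#: above MISSING_WARN a warning is emitted (the trial's own maximum was 11%).
MISSING_MAX = 0.2
MISSING_WARN = 0.11


class ValidationError(ValueError):
    """Data violates a study invariant (range, ordering, consistency)."""


class FormatError(ValueError):
    """File or table does not have the expected structure."""


@dataclass(frozen=True)
class MeasurementSeries:
    """One subject's time-stamped BDI-II scores.

    ``times`` are weeks from baseline, strictly increasing, starting at 0.
    ``scores`` are integer BDI-II totals in [0, 63].  Subjects with fewer
    than 2 observations are not admissible (single-occasion participants
    carry no trajectory information and are excluded at load time).
    """

    subject_id: str
    times: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "scores", scores)
        sid = self.subject_id
        if times.ndim != 1 or scores.ndim != 1 or len(times) != len(scores):
            raise ValidationError(f"subject {sid}: times/scores must be 1-D and equal length")
        if len(times) < 2:
            raise ValidationError(f"subject {sid}: at least 2 measurement occasions required")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(scores)):
            raise ValidationError(f"subject {sid}: non-finite time or score")
        if abs(times[0]) > 1e-9:
            raise ValidationError(f"subject {sid}: first time must be 0 (baseline), got {times[0]}")
        if np.any(np.diff(times) <= 0):
            raise ValidationError(f"subject {sid}: times not strictly increasing")
        if np.any((scores < SCORE_MIN) | (scores > SCORE_MAX)):
            bad = scores[(scores < SCORE_MIN) | (scores > SCORE_MAX)][0]
            raise ValidationError(f"subject {sid}: score out of range [0, 63]: {bad}")
        if np.any(scores != np.round(scores)):
            raise ValidationError(f"subject {sid}: scores must be integers")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ScalingRecord:
    """Per-covariate centering/scaling applied by :func:`standardize_covariates`.

    ``scale`` is 1.0 for binary covariates (centered only, so their
    coefficients read as full 0-vs-1 contrasts).
    """

    center: dict[str, float]
    scale: dict[str, float]

    def transform(self, name: str, raw):
        return (np.asarray(raw, dtype=float) - self.center[name]) / self.scale[name]

    def invert(self, name: str, standardized):
        return np.asarray(standardized, dtype=float) * self.scale[name] + self.center[name]


@dataclass
class CovariateTable:
    """Subjects x covariates matrix with type metadata and NaN as missing marker."""

    subject_ids: list[str]
    names: list[str]
    kinds: dict[str, str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.names = list(self.names)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.names)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.names)} covariates"
            )
        unknown = set(self.names) - set(self.kinds)
        if unknown:
            raise FormatError(f"no kind declared for covariates: {sorted(unknown)}")
        for name in self.names:
            if self.kinds[name] not in COVARIATE_KINDS:
                raise FormatError(f"covariate {name}: unknown kind {self.kinds[name]!r}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def missing_fraction(self) -> dict[str, float]:
        if self.n_subjects == 0:
            return {name: 0.0 for name in self.names}
        return {
            name: float(np.mean(np.isnan(self.values[:, j])))
            for j, name in enumerate(self.names)
        }

    def validate(self) -> None:
        """Check coding and missingness invariants; raise ValidationError on breach."""
        for j, name in enumerate(self.names):
            col = self.values[:, j]
            obs = col[~np.isnan(col)]
            kind = self.kinds[name]
            if kind == "binary" and obs.size and not np.all(np.isin(obs, (0.0, 1.0))):
                bad = obs[~np.isin(obs, (0.0, 1.0))][0]
                raise ValidationError(f"binary covariate {name}: value {bad} not in {{0, 1}}")
            if kind == "ordinal" and obs.size and np.any(obs != np.round(obs)):
                raise ValidationError(f"ordinal covariate {name}: non-integer value")
        for name, frac in self.missing_fraction().items():
            if frac > MISSING_MAX:
                raise ValidationError(
                    f"covariate {name}: missingness {frac:.0%} exceeds the {MISSING_MAX:.0%} cap"
                )
            if frac > MISSING_WARN:
                warnings.warn(
                    f"covariate {name}: missingness {frac:.0%} exceeds {MISSING_WARN:.0%}",
                    stacklevel=2,
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.names)

    def copy(self) -> "CovariateTable":
        return CovariateTable(
            list(self.subject_ids), list(self.names), dict(self.kinds), self.values.copy()
        )


@dataclass
class StudyDataset:
    """A full study: trajectory series plus (optionally) a covariate table."""

    series: list[MeasurementSeries]
    covariates: CovariateTable | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.series]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject ids among measurement series")
        if self.covariates is not None:
            series_ids = set(ids)
            cov_ids = set(self.covariates.subject_ids)
            if series_ids != cov_ids:
                missing = sorted(series_ids ^ cov_ids)[:5]
                raise ValidationError(
                    f"subject ids of series and covariates differ (e.g. {missing})"
                )

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.series]

    @property
    def n_subjects(self) -> int:
        return len(self.series)

    @property
    def n_observations(self) -> int:
        return int(sum(len(s) for s in self.series))

    def validate(self) -> None:
        # series invariants are enforced at construction; re-check covariates
        if self.covariates is not None:
            self.covariates.validate()

    def to_long_frame(self, id_col="subject", time_col="time_weeks", score_col="bdi2"):
        rows = []
        for s in self.series:
            for t, y in zip(s.times, s.scores):
                rows.append((s.subject_id, float(t), int(y)))
        return pd.DataFrame(rows, columns=[id_col, time_col, score_col])


# ---------------------------------------------------------------------------
# CSV IO (comma-separated, UTF-8, header required, missing = empty or "NA")


def read_long_csv(
    path,
    id_col: str = "subject",
    time_col: str = "time_weeks",
    score_col: str = "bdi2",
) -> StudyDataset:
    """Read long-format scores (one row per subject x occasion) into a dataset.

    Rows are grouped by subject id and sorted by time before validation, so
    the file's row order does not matter; duplicate times do (they violate
    the strictly-increasing invariant).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True,
                     float_precision="round_trip")
    for col in (id_col, time_col, score_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df[[time_col, score_col]].isna().any().any():
        raise ValidationError(f"{path}: missing time or score value")
    try:
        times = df[time_col].astype(float)
        scores = df[score_col].astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric time or score: {exc}") from exc
    series = []
    for sid, grp in df.assign(**{time_col: times, score_col: scores}).groupby(
        id_col, sort=True
    ):
        grp = grp.sort_values(time_col)
        series.append(
            MeasurementSeries(str(sid), grp[time_col].to_numpy(), grp[score_col].to_numpy())
        )
    return StudyDataset(series=series, metadata={"source": str(path)})


def write_long_csv(dataset: StudyDataset, path, id_col="subject",
                   time_col="time_weeks", score_col="bdi2") -> None:
    df = dataset.to_long_frame(id_col, time_col, score_col)
    # full float precision on times so read->write->read round-trips exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_covariates_csv(path, kinds: Mapping[str, str], id_col: str = "subject") -> CovariateTable:
    """Read one-row-per-subject covariates; ``kinds`` must cover all non-id columns."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True, dtype={id_col: str},
                     float_precision="round_trip")
    if id_col not in df.columns:
        raise FormatError(f"{path}: missing id column {id_col!r}")
    if df[id_col].duplicated().any():
        raise ValidationError(f"{path}: duplicate subject id")
    names = [c for c in df.columns if c != id_col]
    uncovered = set(names) - set(kinds)
    if uncovered:
        raise FormatError(f"{path}: no kind declared for columns {sorted(uncovered)}")
    table = CovariateTable(
        subject_ids=df[id_col].tolist(),
        names=names,
        kinds={n: kinds[n] for n in names},
        values=df[names].to_numpy(dtype=float),
    )
    table.validate()
    return table


def write_covariates_csv(table: CovariateTable, path, id_col: str = "subject") -> None:
    df = table.to_frame().rename_axis(id_col).reset_index()
    df.to_csv(path, index=False, float_format="%.17g", na_rep="NA")


# ---------------------------------------------------------------------------
# Standardization and imputation


def standardize_covariates(table: CovariateTable) -> tuple[CovariateTable, ScalingRecord]:
    """Standardize covariates over non-missing entries.

    Continuous and ordinal covariates become mean 0 / SD 1 (population SD);
    binary covariates are centered only.  Returns the transformed table and
    a :class:`ScalingRecord` sufficient to invert the transform.
    """
    out = table.copy()
    center: dict[str, float] = {}
    scale: dict[str, float] = {}
    for j, name in enumerate(out.names):
        col = out.values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValidationError(f"covariate {name}: no observed values")
        m = float(obs.mean())
        if out.kinds[name] == "binary":
            s = 1.0
            if np.ptp(obs) == 0:
                raise ValidationError(f"covariate {name}: zero variance")
        else:
            s = float(obs.std(ddof=0))
            if s == 0.0:
                raise ValidationError(f"covariate {name}: zero variance")
        out.values[:, j] = (col - m) / s
        center[name] = m
        scale[name] = s
    return out, ScalingRecord(center=center, scale=scale)


def impute_covariates(table: CovariateTable, strategy: str = "mean") -> CovariateTable:
    """Fill missing covariate entries.

    ``mean`` replaces each missing entry by the covariate's observed mean
    (which is 0 after standardization); ``none`` returns the table unchanged.
    """
    if strategy not in ("mean", "none"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    out = table.copy()
    if strategy == "none":
        return out
    for j, name in enumerate(out.names):
        col = out.values[:, j]
        mask = np.isnan(col)
        if mask.all():
            raise ValidationError(f"covariate {name}: all values missing, mean undefined")
        if mask.any():
            col[mask] = col[~mask].mean()
    return out


def dataset_fingerprint(dataset: StudyDataset) -> str:
    """Stable content hash used in run manifests."""
    h = hashlib.sha256()
    h.update(dataset.to_long_frame().to_csv(index=False).encode())
    if dataset.covariates is not None:
        h.update(dataset.covariates.to_frame().to_csv().encode())
    return h.hexdigest()[:16]
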