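"""Schema-aware loading, validation and preprocessing of tabular cohorts.

A cohort is a complete-case table of clinical and demographic features with a
single continuous regression target (for the motivating use case, glycated
haemoglobin HbA1c in mmol/mol). Features carry a declared *kind*
(continuous / binary / categorical) and a *role*:

- ``predictor``: enters the model's design matrix;
- ``target``: the continuous outcome being predicted (exactly one);
- ``excluded_from_prediction``: recorded but withheld from the design matrix
  (e.g. a diagnosis collinear with the target);
- ``stratification``: reporting-only features for stratified audits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

KINDS = ("continuous", "binary", "categorical")
ROLES = ("predictor", "target", "excluded_from_prediction", "stratification")


class SchemaError(ValueError):
    """The data do not conform to the declared feature schema."""


class EmptyCohortError(ValueError):
    """No complete-case records survived loading."""


class DegenerateFeatureError(ValueError):
    """A continuous feature has zero spread on the fitting split."""


@dataclass(frozen=True)
class FeatureField:
    name: str
    kind: str
    role: str = "predictor"
    levels: tuple[str, ...] | None = None
    units: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown feature role {self.role!r} for {self.name!r}")
        if self.kind == "categorical" and not self.levels:
            raise SchemaError(f"categorical feature {self.name!r} must list its levels")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of feature declarations; exactly one continuous target."""

    fields: tuple[FeatureField, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.fields]
        if len(names) != len(set(names)):
            raise SchemaError("feature names must be unique")
        targets = [f for f in self.fields if f.role == "target"]
        if len(targets) != 1:
            raise SchemaError(f"schema must declare exactly one target, found {len(targets)}")
        if targets[0].kind != "continuous":
            raise SchemaError("the target must be continuous")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.fields]

    @property
    def target(self) -> FeatureField:
        return next(f for f in self.fields if f.role == "target")

    @property
    def predictors(self) -> list[FeatureField]:
        return [f for f in self.fields if f.role == "predictor"]

    def __getitem__(self, name: str) -> FeatureField:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)

    @classmethod
    def from_dict(cls, spec: Mapping) -> "FeatureSchema":
        fields = []
        for item in spec["features"]:
            levels = item.get("levels")
            fields.append(
                FeatureField(
                    name=item["name"],
                    kind=item["kind"],
                    role=item.get("role", "predictor"),
                    levels=tuple(levels) if levels else None,
                    units=item.get("units"),
                )
            )
        return cls(tuple(fields))

    @classmethod
    def from_yaml(cls, path: str) -> "FeatureSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Cohort:
    """Complete-case records conforming to a :class:`FeatureSchema`."""

    records: pd.DataFrame
    schema: FeatureSchema

    def __post_init__(self) -> None:
        missing = [n for n in self.schema.names if n not in self.records.columns]
        if missing:
            raise SchemaError(f"cohort table lacks schema column(s): {missing}")
        if self.records[self.schema.names].isna().any().any():
            raise SchemaError("cohort contains missing values; complete-case only")
        for f in self.schema.fields:
            if f.kind == "categorical":
                bad = set(self.records[f.name].astype(str)) - set(f.levels)
                if bad:
                    raise SchemaError(f"{f.name!r} has undeclared level(s) {sorted(bad)}")

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def target_values(self) -> np.ndarray:
        return self.records[self.schema.target.name].to_numpy(dtype=float)


def load_cohort(
    path: str,
    schema: FeatureSchema,
    target_bounds: tuple[float, float] | None = None,
) -> Cohort:
    """Read a CSV cohort, applying the complete-case rule.

    Rows with any missing value in a schema column are dropped (row order of
    survivors preserved); the number dropped is logged. ``target_bounds``
    optionally removes records whose target lies outside ``(low, high)`` —
    a crude absolute-bounds outlier filter, off by default.
    """
    df = pd.read_csv(path)
    missing = [n for n in schema.names if n not in df.columns]
    if missing:
        raise SchemaError(f"input file lacks schema column(s): {missing}")
    df = df[schema.names]
    n_raw = len(df)
    df = df.dropna(axis=0, how="any")
    n_dropped = n_raw - len(df)
    if n_dropped:
        logger.info("dropped %d of %d rows with missing values", n_dropped, n_raw)
    if target_bounds is not None:
        low, high = target_bounds
        tname = schema.target.name
        keep = (df[tname] >= low) & (df[tname] <= high)
        n_out = int((~keep).sum())
        if n_out:
            logger.info("dropped %d rows with target outside [%g, %g]", n_out, low, high)
        df = df[keep]
    if len(df) == 0:
        raise EmptyCohortError(f"no complete records in {path}")
    return Cohort(records=df.reset_index(drop=True), schema=schema)


@dataclass
class PreparedCohort:
    """Design matrix and normalisation state for one cohort.

    Continuous predictors are z-scored with statistics fitted on
    ``fit_indices`` only (population-form spread, divide by n); binary
    predictors enter as {0,1}; categorical predictors are one-hot expanded
    keeping every level. The raw target is stored alongside a z-scored copy
    and is exactly recoverable from the stored statistics.
    """

    X: np.ndarray
    columns: list[str]
    stats: dict[str, tuple[float, float]]  # continuous feature -> (mean, spread)
    expansion: dict[str, dict[str, str]]  # categorical -> {level: column name}
    y_raw: np.ndarray
    y_norm: np.ndarray
    target_stats: tuple[float, float]
    fit_indices: np.ndarray
    schema: FeatureSchema = field(repr=False)

    @property
    def input_dim(self) -> int:
        return self.X.shape[1]

    def denormalise_target(self, y_norm: np.ndarray) -> np.ndarray:
        mean, spread = self.target_stats
        return np.asarray(y_norm, dtype=float) * spread + mean

    def normalise_target(self, y_raw: np.ndarray) -> np.ndarray:
        mean, spread = self.target_stats
        return (np.asarray(y_raw, dtype=float) - mean) / spread


def _fit_stats(values: np.ndarray, name: str) -> tuple[float, float]:
    mean = float(np.mean(values))
    spread = float(np.std(values))  # population form
    if spread == 0.0:
        raise DegenerateFeatureError(f"feature {name!r} has zero spread on the fitting split")
    return mean, spread


def preprocess(cohort: Cohort, fit_statistics_on: Sequence[int] | np.ndarray) -> PreparedCohort:
    """Build the design matrix for *all* records using statistics from one split.

    ``fit_statistics_on`` is the index set of the fitting (training) split;
    normalisation statistics come from it alone and are reused unchanged for
    any other split, so no information leaks from validation records.
    """
    fit_idx = np.asarray(fit_statistics_on, dtype=int)
    if fit_idx.size == 0:
        raise ValueError("fit_statistics_on must be nonempty")
    df = cohort.records
    cols: list[np.ndarray] = []
    names: list[str] = []
    stats: dict[str, tuple[float, float]] = {}
    expansion: dict[str, dict[str, str]] = {}

    for f in cohort.schema.predictors:
        if f.kind == "continuous":
            v = df[f.name].to_numpy(dtype=float)
            mean, spread = _fit_stats(v[fit_idx], f.name)
            stats[f.name] = (mean, spread)
            cols.append((v - mean) / spread)
            names.append(f.name)
        elif f.kind == "binary":
            v = df[f.name].to_numpy(dtype=float)
            if not np.isin(v, (0.0, 1.0)).all():
                raise SchemaError(f"binary feature {f.name!r} has values outside {{0,1}}")
            cols.append(v)
            names.append(f.name)
        else:  # categorical, keep all levels
            level_map: dict[str, str] = {}
            raw = df[f.name].astype(str).to_numpy()
            for level in f.levels:  # declared order, not data order
                col = f"{f.name}={level}"
                cols.append((raw == level).astype(float))
                names.append(col)
                level_map[level] = col
            expansion[f.name] = level_map

    tname = cohort.schema.target.name
    y_raw = df[tname].to_numpy(dtype=float)
    t_mean, t_spread = _fit_stats(y_raw[fit_idx], tname)
    y_norm = (y_raw - t_mean) / t_spread

    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return PreparedCohort(
        X=X,
        columns=names,
        stats=stats,
        expansion=expansion,
        y_raw=y_raw,
        y_norm=y_norm,
        target_stats=(t_mean, t_spread),
        fit_indices=fit_idx,
        schema=cohort.schema,
    )


def mean_split(
    cohort: Cohort, feature: str, fit_statistics_on: Sequence[int] | np.ndarray
) -> np.ndarray:
    """Binarise a continuous feature into 'high'/'low' by mean split.

    The threshold is the mean of the feature over the fitting split; values
    strictly above it are labelled 'high'.
    """
    f = cohort.schema[feature]
    if f.kind != "continuous":
        raise SchemaError(f"mean_split requires a continuous feature, got {f.kind!r}")
    v = cohort.records[feature].to_numpy(dtype=float)
    threshold = float(np.mean(v[np.asarray(fit_statistics_on, dtype=int)]))
    return np.where(v > threshold, "high", "low")
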