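"""Synthetic biobank-like cohorts with planted subgroups of known severity.

The generator emulates a mid-life population-cohort variable set (sex, age,
smoking, grouped ethnicity, an area-deprivation index, haemoglobin, BMI,
weight, body-fat %, morbidity flags) with a continuous HbA1c-like regression
target. Subgroups can be *planted* — selected by a feature rule or a random
fraction — with a shifted conditional target mean and/or an inflated residual
spread, so downstream auditing stages can be tested against ground truth:
the generator records exactly who was planted and how severely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, FeatureField, FeatureSchema


class SpecError(ValueError):
    """The cohort specification is internally inconsistent or infeasible."""


# ---------------------------------------------------------------------------
# feature generator specs


@dataclass(frozen=True)
class ContinuousFeature:
    name: str
    mean: float
    sd: float
    role: str = "predictor"
    units: str | None = None


@dataclass(frozen=True)
class BinaryFeature:
    name: str
    prevalence: float
    role: str = "predictor"


@dataclass(frozen=True)
class CategoricalFeature:
    name: str
    probs: Mapping[str, float]
    role: str = "predictor"


@dataclass(frozen=True)
class LinearFeature:
    """Continuous feature generated as a linear function of earlier features."""

    name: str
    intercept: float
    coeffs: Mapping[str, float]
    sd: float
    role: str = "predictor"
    units: str | None = None


@dataclass(frozen=True)
class LogisticFeature:
    """Binary feature with logistic dependence on earlier features."""

    name: str
    intercept: float
    coeffs: Mapping[str, float]
    role: str = "predictor"


FeatureGen = ContinuousFeature | BinaryFeature | CategoricalFeature | LinearFeature | LogisticFeature


@dataclass(frozen=True)
class TargetModel:
    intercept: float
    coeffs: Mapping[str, float]
    residual_sd: float

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise SpecError("base residual spread must be positive")


@dataclass(frozen=True)
class PlantedSubgroup:
    """A subpopulation with a known target-mean shift and residual inflation.

    Membership is either a conjunction of feature conditions
    (``rule=(("smoking", "==", 1), ("townsend", ">", 0.0))``) or an explicit
    random fraction of records.
    """

    name: str
    mean_shift: float = 0.0
    sd_multiplier: float = 1.0
    rule: tuple[tuple[str, str, float], ...] | None = None
    fraction: float | None = None

    def __post_init__(self) -> None:
        if (self.rule is None) == (self.fraction is None):
            raise SpecError(f"subgroup {self.name!r}: give exactly one of rule or fraction")
        if self.fraction is not None and not 0 < self.fraction < 1:
            raise SpecError(f"subgroup {self.name!r}: fraction must be in (0,1)")
        if self.sd_multiplier < 1:
            raise SpecError(f"subgroup {self.name!r}: sd multiplier must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    n_records: int
    features: tuple[FeatureGen, ...]
    target: TargetModel
    subgroups: tuple[PlantedSubgroup, ...] = ()
    target_name: str = "hba1c"
    target_units: str = "mmol/mol"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise SpecError("n_records must be positive")
        frac = sum(g.fraction for g in self.subgroups if g.fraction is not None)
        if frac >= 1:
            raise SpecError("random-fraction subgroup fractions must sum to < 1")
        for f in self.features:
            if isinstance(f, CategoricalFeature):
                total = sum(f.probs.values())
                if abs(total - 1.0) > 1e-9:
                    raise SpecError(f"level probabilities of {f.name!r} sum to {total}, not 1")


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside a generated cohort."""

    membership: pd.DataFrame  # n x n_subgroups boolean
    fractions: dict[str, float]
    conditional_stats: pd.DataFrame  # per subgroup: realised target mean / spread
    linear_predictor: np.ndarray  # target mean per record before noise
    sd_per_record: np.ndarray

    def to_manifest(self) -> dict:
        return {
            "fractions": self.fractions,
            "conditional_stats": self.conditional_stats.to_dict(orient="index"),
        }


# ---------------------------------------------------------------------------
# generation

_OPS = {
    "==": np.equal,
    "!=": np.not_equal,
    ">": np.greater,
    ">=": np.greater_equal,
    "<": np.less,
    "<=": np.less_equal,
}


def _schema_from_spec(spec: CohortSpec) -> FeatureSchema:
    fields = []
    for f in spec.features:
        if isinstance(f, (ContinuousFeature, LinearFeature)):
            fields.append(FeatureField(f.name, "continuous", f.role, units=f.units))
        elif isinstance(f, (BinaryFeature, LogisticFeature)):
            fields.append(FeatureField(f.name, "binary", f.role))
        else:
            fields.append(FeatureField(f.name, "categorical", f.role, levels=tuple(f.probs)))
    fields.append(
        FeatureField(spec.target_name, "continuous", "target", units=spec.target_units)
    )
    return FeatureSchema(tuple(fields))


def generate_cohort(spec: CohortSpec) -> tuple[Cohort, PlantedTruth]:
    """Draw a complete-case cohort and its planted-subgroup ground truth.

    The target for record *i* is
    ``intercept + coeffs . features_i + sum(mean shifts of i's subgroups)
    + eps_i`` with ``eps_i ~ Normal(0, base_sd * max multiplier over i's
    subgroups)``. Identical specs (including seed) give identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records
    data: dict[str, np.ndarray] = {}
    for f in spec.features:
        if isinstance(f, ContinuousFeature):
            data[f.name] = rng.normal(f.mean, f.sd, size=n)
        elif isinstance(f, BinaryFeature):
            data[f.name] = (rng.random(n) < f.prevalence).astype(int)
        elif isinstance(f, CategoricalFeature):
            levels = list(f.probs)
            data[f.name] = rng.choice(levels, size=n, p=[f.probs[l] for l in levels])
        elif isinstance(f, LinearFeature):
            mu = f.intercept + sum(c * data[k] for k, c in f.coeffs.items())
            data[f.name] = mu + rng.normal(0.0, f.sd, size=n)
        elif isinstance(f, LogisticFeature):
            logit = f.intercept + sum(c * data[k] for k, c in f.coeffs.items())
            p = 1.0 / (1.0 + np.exp(-logit))
            data[f.name] = (rng.random(n) < p).astype(int)
        else:  # pragma: no cover
            raise SpecError(f"unknown feature generator {type(f).__name__}")

    membership: dict[str, np.ndarray] = {}
    for g in spec.subgroups:
        if g.rule is not None:
            mask = np.ones(n, dtype=bool)
            for feat, op, value in g.rule:
                if feat not in data:
                    raise SpecError(f"subgroup {g.name!r} references unknown feature {feat!r}")
                mask &= _OPS[op](data[feat].astype(float), value)
        else:
            mask = rng.random(n) < g.fraction
        if not mask.any():
            raise SpecError(f"subgroup {g.name!r} selects no records at n={n}")
        membership[g.name] = mask

    mu = np.full(n, spec.target.intercept, dtype=float)
    for feat, coef in spec.target.coeffs.items():
        mu += coef * data[feat].astype(float)
    sd = np.full(n, spec.target.residual_sd, dtype=float)
    for g in spec.subgroups:
        mask = membership[g.name]
        mu[mask] += g.mean_shift
        # overlapping subgroups: shifts add, the worst inflation wins
        sd[mask] = np.maximum(sd[mask], spec.target.residual_sd * g.sd_multiplier)
    y = mu + rng.normal(0.0, 1.0, size=n) * sd
    data[spec.target_name] = y

    schema = _schema_from_spec(spec)
    cohort = Cohort(records=pd.DataFrame(data, columns=schema.names), schema=schema)

    mem_df = pd.DataFrame(membership, index=range(n)) if membership else pd.DataFrame(index=range(n))
    stats_rows = {}
    for name, mask in membership.items():
        stats_rows[name] = {
            "fraction": float(mask.mean()),
            "target_mean": float(y[mask].mean()),
            "target_sd": float(y[mask].std()),
        }
    truth = PlantedTruth(
        membership=mem_df,
        fractions={k: float(v.mean()) for k, v in membership.items()},
        conditional_stats=pd.DataFrame(stats_rows).T
        if stats_rows
        else pd.DataFrame(columns=["fraction", "target_mean", "target_sd"]),
        linear_predictor=mu,
        sd_per_record=sd,
    )
    return cohort, truth


def split_cohort(
    cohort: Cohort, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint, exhaustive train/validation index split."""
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0,1), got {train_fraction}")
    n = cohort.n_records
    n_train = int(round(n * train_fraction))
    if n_train == 0 or n_train == n:
        raise ValueError(f"degenerate split: {n_train}/{n - n_train} at n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


# ---------------------------------------------------------------------------
# default biobank-like preset


def biobank_like_spec(n_records: int = 20_000, seed: int = 0) -> CohortSpec:
    """Default cohort: mid-life population survey with two planted subgroups.

    The diabetic stratum (logistic in BMI, age and deprivation; prevalence
    ~6-7%) carries a +12 mmol/mol HbA1c shift with 2.5x residual spread —
    the familiar wide glycaemic dispersion of diabetics. A second,
    intersectional subgroup (male smokers in more-deprived areas, ~5%)
    carries a +8 shift with 3x spread; it is defined only by the conjunction,
    so single-feature stratification dilutes it. The diabetes flag itself is
    excluded from prediction.
    """
    features: tuple[FeatureGen, ...] = (
        BinaryFeature("sex", prevalence=0.46),  # 1 = male
        ContinuousFeature("age", mean=56.5, sd=8.1, units="years"),
        BinaryFeature("smoking", prevalence=0.35),
        CategoricalFeature(
            "ethnicity",
            probs={
                "white": 0.875,
                "asian": 0.05,
                "black": 0.04,
                "mixed": 0.015,
                "chinese": 0.005,
                "other": 0.015,
            },
        ),
        ContinuousFeature("townsend", mean=-1.3, sd=3.0),
        ContinuousFeature("haemoglobin", mean=14.2, sd=1.2, units="g/dL"),
        ContinuousFeature("bmi", mean=27.4, sd=4.8, units="kg/m^2"),
        LinearFeature("weight", intercept=1.3, coeffs={"bmi": 2.8}, sd=8.0, units="kg"),
        LinearFeature(
            "body_fat_pct", intercept=14.0, coeffs={"bmi": 0.8, "sex": -10.0}, sd=4.0, units="%"
        ),
        LogisticFeature(
            "high_blood_pressure", intercept=-9.6, coeffs={"age": 0.09, "bmi": 0.12}
        ),
        BinaryFeature("heart_attack_angina_stroke", prevalence=0.06),
        BinaryFeature("clot_emphysema", prevalence=0.08),
        BinaryFeature("asthma", prevalence=0.12),
        BinaryFeature("hayfever_eczema", prevalence=0.22),
        BinaryFeature("other_serious_condition", prevalence=0.09),
        LogisticFeature(
            "diabetes",
            intercept=-15.0,
            coeffs={"bmi": 0.25, "age": 0.10, "townsend": 0.10},
            role="excluded_from_prediction",
        ),
    )
    target = TargetModel(
        intercept=24.0,
        coeffs={
            "age": 0.06,
            "bmi": 0.15,
            "smoking": 0.6,
            "townsend": 0.15,
            "sex": 0.3,
            "haemoglobin": 0.2,
            "high_blood_pressure": 0.5,
        },
        residual_sd=3.0,
    )
    subgroups = (
        PlantedSubgroup(
            "diabetic", rule=(("diabetes", "==", 1),), mean_shift=12.0, sd_multiplier=2.5
        ),
        PlantedSubgroup(
            "deprived_male_smokers",
            rule=(("smoking", "==", 1), ("sex", "==", 1), ("townsend", ">", 0.0)),
            mean_shift=8.0,
            sd_multiplier=3.0,
        ),
    )
    return CohortSpec(
        n_records=n_records, features=features, target=target, subgroups=subgroups, seed=seed
    )


def separable_recovery_spec(n_records: int = 6_000, seed: int = 0) -> CohortSpec:
    """Recovery-study cohort: one planted subgroup that is a real cluster.

    A 15% marker-defined subgroup has several feature means shifted by
    1.5-2 spreads (a BMI-like variable most strongly), so it separates in
    any faithful low-dimensional representation, and a 3x residual spread so
    it is genuinely under-served. Used to test end-to-end ground-truth
    recovery: on realistic cohorts like :func:`biobank_like_spec`, planted
    conjunction subgroups blend into latent groups instead of dominating
    them, which is the phenomenon the framework exists to detect — but it
    makes majority-based recovery metrics degenerate there.
    """
    features: tuple[FeatureGen, ...] = (
        BinaryFeature("marker", prevalence=0.15),
        BinaryFeature("sex", prevalence=0.5),
        ContinuousFeature("age", mean=55.0, sd=8.0, units="years"),
        LinearFeature("bmi_like", intercept=26.0, coeffs={"marker": 8.0}, sd=4.0),
        LinearFeature("exposure", intercept=0.0, coeffs={"marker": 2.0}, sd=1.0),
        LinearFeature("biomarker", intercept=10.0, coeffs={"marker": -3.0}, sd=1.5),
        ContinuousFeature("noise_1", mean=0.0, sd=1.0),
        ContinuousFeature("noise_2", mean=0.0, sd=1.0),
    )
    target = TargetModel(
        intercept=30.0,
        coeffs={"age": 0.08, "bmi_like": 0.2, "exposure": 0.5, "sex": 0.4},
        residual_sd=3.0,
    )
    subgroups = (
        PlantedSubgroup(
            "marked", rule=(("marker", "==", 1),), mean_shift=6.0, sd_multiplier=3.0
        ),
    )
    return CohortSpec(
        n_records=n_records, features=features, target=target, subgroups=subgroups, seed=seed
    )
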