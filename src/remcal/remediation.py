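"""Remediation by rebalanced retraining.

Groups whose NRMSE exceeds the median group NRMSE are designated
*under-served*; their pooled records form the under-served stratum and the
remainder the *base* stratum. Remediation oversamples every under-served
record by a common multiplier m — so each constituent group keeps its share
of the pool — and retrains the model from fresh seeded initialisation on the
rebalanced data. Pooling (rather than per-group multipliers) avoids pushing
small, already-marginalised groups further out. The before/after comparison
keeps the original latent segmentation and group assignment fixed so the
deltas compare like with like.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationConfig,
    GroupCalibrationTable,
    equity_summary,
    group_calibration,
    nrmse,
)

logger = logging.getLogger(__name__)


class Predictor(Protocol):
    def fit(self, X: np.ndarray, y: np.ndarray) -> "Predictor": ...

    def predict(self, X: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class RemediationConfig:
    multiplier: float = 4.0
    n_trials: int = 10
    seed: int = 0
    seeds: tuple[int, ...] | None = None  # overrides seed-derived trial seeds

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("oversampling multiplier must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    def trial_seeds(self) -> list[int]:
        if self.seeds is not None:
            return list(self.seeds)[: self.n_trials]
        return [(self.seed + 1009 * t) % (2**31 - 1) for t in range(self.n_trials)]


def designate_underserved(table: GroupCalibrationTable) -> set[int]:
    """Group ids with NRMSE strictly above the median of included groups."""
    g = table.included
    if len(g) < 2:
        raise ValueError("designation needs at least 2 included groups")
    median = float(g["nrmse"].median())
    return set(g.index[g["nrmse"] > median])


def rebalance(
    underserved: np.ndarray, multiplier: float, seed: int = 0
) -> np.ndarray:
    """Record indices of the rebalanced training set.

    Every flagged record appears floor(m) times plus one more with
    probability m - floor(m) (seeded); unflagged records appear exactly
    once. A common multiplier preserves, in expectation, each constituent
    subpopulation's share of the under-served pool.
    """
    flags = np.asarray(underserved, dtype=bool).ravel()
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    n = flags.size
    if multiplier > 1 and not flags.any():
        warnings.warn("no records flagged under-served; returning identity", stacklevel=2)
        return np.arange(n)
    base = int(np.floor(multiplier))
    frac = multiplier - base
    copies = np.ones(n, dtype=int)
    copies[flags] = base
    if frac > 0:
        rng = np.random.default_rng(seed)
        copies[flags] += rng.random(int(flags.sum())) < frac
    return np.repeat(np.arange(n), copies)


# ---------------------------------------------------------------------------
# repeated-trial experiment


@dataclass
class RemediationResult:
    """Before/after fidelity for the all / base / under-served strata.

    ``per_trial`` has one row per (trial, split, stratum) with NRMSE before
    and after and delta = before - after (positive = improvement);
    ``gini_per_trial`` likewise for the Gini coefficient over group NRMSE.
    """

    per_trial: pd.DataFrame
    gini_per_trial: pd.DataFrame
    designated: list[set[int]] = field(default_factory=list)
    multiplier: float = 1.0

    @property
    def n_trials(self) -> int:
        return int(self.per_trial["trial"].nunique()) if len(self.per_trial) else 0

    def summary(self) -> pd.DataFrame:
        """Mean and SD of delta-NRMSE per stratum and split (SD NaN at 1 trial)."""
        agg = (
            self.per_trial.groupby(["stratum", "split"])["delta"]
            .agg(["mean", "std"])
            .rename(columns={"mean": "delta_mean", "std": "delta_sd"})
        )
        return agg.reset_index()

    def gini_summary(self) -> pd.DataFrame:
        agg = (
            self.gini_per_trial.groupby("split")[["gini_before", "gini_after", "delta"]]
            .agg(["mean", "std"])
        )
        agg.columns = ["_".join(c) for c in agg.columns]
        return agg.reset_index()


class RemediationRunner:
    """Shared data + model factory for remediation experiments and sweeps.

    ``make_predictor(seed)`` must return a fresh fit/predict object; fitting
    happens on the normalised target (``y_fit``), scoring on raw units via
    ``denormalise``. Baselines are cached per trial seed, so a multiplier
    sweep retrains only the remediated models.
    """

    def __init__(
        self,
        X_train: np.ndarray,
        y_train_fit: np.ndarray,
        y_train_raw: np.ndarray,
        X_val: np.ndarray,
        y_val_raw: np.ndarray,
        labels_train: np.ndarray,
        labels_val: np.ndarray,
        make_predictor: Callable[[int], Predictor],
        denormalise: Callable[[np.ndarray], np.ndarray],
        calib: CalibrationConfig | None = None,
    ) -> None:
        self.X_train = X_train
        self.y_train_fit = np.asarray(y_train_fit, dtype=float)
        self.y_train_raw = np.asarray(y_train_raw, dtype=float)
        self.X_val = X_val
        self.y_val_raw = np.asarray(y_val_raw, dtype=float)
        self.labels_train = np.asarray(labels_train)
        self.labels_val = np.asarray(labels_val)
        self.make_predictor = make_predictor
        self.denormalise = denormalise
        self.calib = calib or CalibrationConfig()
        self._baseline_cache: dict[int, dict] = {}

    def _score(self, model: Predictor) -> dict[str, np.ndarray]:
        return {
            "train": self.denormalise(np.asarray(model.predict(self.X_train))),
            "val": self.denormalise(np.asarray(model.predict(self.X_val))),
        }

    def baseline(self, seed: int) -> dict:
        if seed not in self._baseline_cache:
            model = self.make_predictor(seed)
            model.fit(self.X_train, self.y_train_fit)
            preds = self._score(model)
            tables = {
                split: group_calibration(
                    self._raw(split), preds[split], self._labels(split), self.calib
                )
                for split in ("train", "val")
            }
            self._baseline_cache[seed] = {
                "preds": preds,
                "tables": tables,
                "designated": designate_underserved(tables["train"]),
            }
        return self._baseline_cache[seed]

    def _raw(self, split: str) -> np.ndarray:
        return self.y_train_raw if split == "train" else self.y_val_raw

    def _labels(self, split: str) -> np.ndarray:
        return self.labels_train if split == "train" else self.labels_val

    def _strata_rows(
        self, trial: int, split: str, flags: np.ndarray, before: np.ndarray, after: np.ndarray
    ) -> list[dict]:
        y = self._raw(split)
        rows = []
        for stratum, mask in (
            ("all", np.ones_like(flags)),
            ("base", ~flags),
            ("under-served", flags),
        ):
            if not mask.any():
                continue
            b = nrmse(y[mask], before[mask])
            a = nrmse(y[mask], after[mask])
            rows.append(
                {
                    "trial": trial,
                    "split": split,
                    "stratum": stratum,
                    "count": int(mask.sum()),
                    "nrmse_before": b,
                    "nrmse_after": a,
                    "delta": b - a,
                }
            )
        return rows

    def run(self, config: RemediationConfig) -> RemediationResult:
        """Repeated rebalance-and-retrain trials against cached baselines.

        Each trial: train (or reuse) the baseline from its trial seed,
        designate under-served groups on the training-split calibration,
        oversample them by the multiplier, retrain from the same fresh
        initialisation seed, and recompute fidelity on the unchanged group
        assignment. At m = 1 the rebalanced data equal the original, so the
        retrained model reproduces the baseline exactly.
        """
        rows, gini_rows, designated_log = [], [], []
        for trial, seed in enumerate(config.trial_seeds()):
            base = self.baseline(seed)
            designated = base["designated"]
            designated_log.append(designated)
            flags_train = np.isin(self.labels_train, list(designated))
            flags_val = np.isin(self.labels_val, list(designated))
            if not designated:
                warnings.warn("empty designation; remediation is a no-op", stacklevel=2)
                after_preds = base["preds"]
            else:
                idx = rebalance(flags_train, config.multiplier, seed=seed + 7919)
                model = self.make_predictor(seed)
                model.fit(self.X_train[idx], self.y_train_fit[idx])
                after_preds = self._score(model)
            for split, flags in (("train", flags_train), ("val", flags_val)):
                rows.extend(
                    self._strata_rows(
                        trial, split, flags, base["preds"][split], after_preds[split]
                    )
                )
                g_before = equity_summary(base["tables"][split]).gini_coefficient
                g_after = equity_summary(
                    group_calibration(
                        self._raw(split), after_preds[split], self._labels(split), self.calib
                    )
                ).gini_coefficient
                gini_rows.append(
                    {
                        "trial": trial,
                        "split": split,
                        "gini_before": g_before,
                        "gini_after": g_after,
                        "delta": g_before - g_after,
                    }
                )
        return RemediationResult(
            per_trial=pd.DataFrame(rows),
            gini_per_trial=pd.DataFrame(gini_rows),
            designated=designated_log,
            multiplier=config.multiplier,
        )

    def sweep(
        self, multipliers: Sequence[float], config: RemediationConfig
    ) -> pd.DataFrame:
        """One summary row per multiplier, sharing baselines across rows."""
        if len(multipliers) == 0:
            raise ValueError("empty multiplier list")
        if any(m < 1 for m in multipliers):
            raise ValueError("all multipliers must be >= 1")
        rows = []
        for m in multipliers:
            res = self.run(replace(config, multiplier=m))
            for split in ("train", "val"):
                row = {"multiplier": m, "split": split}
                sub = res.per_trial[res.per_trial["split"] == split]
                for stratum in ("all", "base", "under-served"):
                    vals = sub[sub["stratum"] == stratum]["nrmse_after"]
                    row[f"nrmse_{stratum}"] = float(vals.mean()) if len(vals) else np.nan
                gsub = res.gini_per_trial[res.gini_per_trial["split"] == split]
                row["gini"] = float(gsub["gini_after"].mean())
                rows.append(row)
        return pd.DataFrame(rows)


def remediation_experiment(
    runner: RemediationRunner, config: RemediationConfig
) -> RemediationResult:
    """Functional wrapper over :meth:`RemediationRunner.run`."""
    return runner.run(config)


def multiplier_sweep(
    runner: RemediationRunner, multipliers: Sequence[float], config: RemediationConfig
) -> pd.DataFrame:
    """Functional wrapper over :meth:`RemediationRunner.sweep`."""
    return runner.sweep(multipliers, config)
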