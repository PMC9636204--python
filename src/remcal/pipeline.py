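"""End-to-end orchestration of the calibration-and-remediation loop.

One iteration runs: load/generate cohort -> split -> preprocess -> train
predictor -> train autoencoder -> encode -> segment the latent space ->
group and stratified calibration -> permutation characterisation of the
worst groups -> equity summary. If the equity criterion (by default,
Gini over group fidelities at or below a threshold) is not met, the
under-served stratum is oversampled and the model retrained, and the loop
repeats up to ``max_iterations``. All randomness derives from the config
seeds, so a report is reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationConfig,
    EquitySummary,
    characterize_worst_groups,
    equity_summary,
    group_calibration,
    stratified_calibration,
)
from .cohort import Cohort, FeatureSchema, load_cohort, mean_split, preprocess
from .predictor import RegressorConfig, build_regressor
from .remediation import (
    RemediationConfig,
    RemediationResult,
    RemediationRunner,
    rebalance,
)
from .representation import AutoencoderConfig, encode, train_autoencoder
from .segmentation import assign_groups, fit_segmentation, silhouette_diagnostic
from .synthetic import CohortSpec, generate_cohort, split_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrameworkConfig:
    # cohort source: exactly one of synthetic_spec or (cohort_csv + schema)
    synthetic_spec: CohortSpec | None = None
    cohort_csv: str | None = None
    schema: FeatureSchema | None = None
    target_bounds: tuple[float, float] | None = None
    # split
    train_fraction: float = 0.75
    seed: int = 0
    predictor_seed: int | None = None  # defaults to a stream derived from seed
    # predictor
    hidden_sizes: tuple[int, ...] = (16, 16, 8)
    n_epochs: int = 5
    learning_rate: float = 1e-3
    batch_size: int = 10
    # representation
    ae_hidden: tuple[int, ...] = (8, 4)
    latent_dim: int = 2
    ae_epochs: int = 5
    ae_include_withheld: bool = False
    # segmentation
    K: int = 50
    # calibration / characterisation
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    stratify_features: tuple[str, ...] = ()
    weighted_gini: bool = False
    # equity loop
    remediation: RemediationConfig = field(default_factory=RemediationConfig)
    gini_threshold: float = 0.05
    max_iterations: int = 2

    def __post_init__(self) -> None:
        has_synth = self.synthetic_spec is not None
        has_file = self.cohort_csv is not None
        if has_synth == has_file:
            raise ValueError("give exactly one of synthetic_spec or cohort_csv")
        if has_file and self.schema is None:
            raise ValueError("cohort_csv requires a schema")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class IterationReport:
    index: int
    group_table_train: object
    group_table_val: object
    equity_train: EquitySummary
    equity_val: EquitySummary
    stratified: dict[str, pd.DataFrame]
    characterisation: pd.DataFrame
    silhouette: float
    remediation: RemediationResult | None = None


@dataclass
class FrameworkReport:
    iterations: list[IterationReport]
    provenance: dict
    cohort_summary: dict[str, pd.DataFrame]

    def payload(self) -> dict:
        """JSON-serialisable view of the report (excluding timestamps)."""
        out = {"provenance": self.provenance, "iterations": []}
        for it in self.iterations:
            entry = {
                "index": it.index,
                "equity_train": it.equity_train.to_dict(),
                "equity_val": it.equity_val.to_dict(),
                "silhouette": it.silhouette,
                "group_table_train": it.group_table_train.table.to_dict(orient="index"),
                "group_table_val": it.group_table_val.table.to_dict(orient="index"),
                "stratified": {k: v.to_dict(orient="index") for k, v in it.stratified.items()},
                "characterisation": it.characterisation.to_dict(orient="records"),
            }
            if it.remediation is not None:
                entry["remediation_summary"] = it.remediation.summary().to_dict(orient="records")
                entry["gini_summary"] = it.remediation.gini_summary().to_dict(orient="records")
            out["iterations"].append(entry)
        return out

    def to_dir(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(self.payload(), fh, indent=1, default=float)
        for it in self.iterations:
            prefix = os.path.join(out_dir, f"iter{it.index}")
            it.group_table_train.table.to_csv(prefix + "_groups_train.csv")
            it.group_table_val.table.to_csv(prefix + "_groups_val.csv")
            it.characterisation.to_csv(prefix + "_characterisation.csv", index=False)
            for name, tbl in it.stratified.items():
                tbl.to_csv(f"{prefix}_stratified_{name}.csv")
            if it.remediation is not None:
                it.remediation.per_trial.to_csv(prefix + "_remediation_trials.csv", index=False)


def _stage_seed(seed: int, stage: int) -> int:
    return (seed * 10007 + stage) % (2**31 - 1)


def _resolve_cohort(config: FrameworkConfig) -> Cohort:
    if config.synthetic_spec is not None:
        cohort, _truth = generate_cohort(config.synthetic_spec)
        return cohort
    return load_cohort(config.cohort_csv, config.schema, config.target_bounds)


def _ae_matrix(prep, cohort: Cohort, config: FrameworkConfig) -> np.ndarray:
    """Autoencoder input: predictor features, optionally plus withheld ones."""
    if not config.ae_include_withheld:
        return prep.X
    extra = [prep.y_norm[:, None]]
    fit = prep.fit_indices
    for f in cohort.schema.fields:
        if f.role == "excluded_from_prediction":
            v = cohort.records[f.name].to_numpy(dtype=float)
            if f.kind == "continuous":
                mu, sd = float(v[fit].mean()), float(v[fit].std())
                v = (v - mu) / sd
            extra.append(v[:, None])
    return np.hstack([prep.X, *extra])


def run_framework(config: FrameworkConfig) -> FrameworkReport:
    """Execute the full audit-and-remediate loop; returns the report."""
    cohort = _resolve_cohort(config)
    train_idx, val_idx = split_cohort(cohort, config.train_fraction, _stage_seed(config.seed, 0))
    prep = preprocess(cohort, train_idx)

    pred_seed = (
        config.predictor_seed
        if config.predictor_seed is not None
        else _stage_seed(config.seed, 1)
    )
    reg_cfg = RegressorConfig(
        input_dim=prep.input_dim,
        hidden_sizes=config.hidden_sizes,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        n_epochs=config.n_epochs,
        seed=pred_seed,
    )

    def make_predictor(seed: int):
        return build_regressor(replace(reg_cfg, seed=seed))

    # representation + segmentation (fixed across the remediation loop)
    X_ae = _ae_matrix(prep, cohort, config)
    ae_cfg = AutoencoderConfig(
        input_dim=X_ae.shape[1],
        encoder_hidden=config.ae_hidden,
        latent_dim=config.latent_dim,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        n_epochs=config.ae_epochs,
        seed=_stage_seed(config.seed, 2),
    )
    ae = train_autoencoder(X_ae[train_idx], ae_cfg)
    embedding_all = encode(ae, X_ae)
    emb_train = encode(ae, X_ae[train_idx])
    seg = fit_segmentation(emb_train, K=config.K, seed=_stage_seed(config.seed, 3))
    labels_all = assign_groups(seg, embedding_all).labels
    sil = silhouette_diagnostic(emb_train, assign_groups(seg, emb_train))
    if sil < 0.1:
        logger.info("low mean silhouette (%.3f): latent groups are weakly separated", sil)

    runner = RemediationRunner(
        X_train=prep.X[train_idx],
        y_train_fit=prep.y_norm[train_idx],
        y_train_raw=prep.y_raw[train_idx],
        X_val=prep.X[val_idx],
        y_val_raw=prep.y_raw[val_idx],
        labels_train=labels_all[train_idx],
        labels_val=labels_all[val_idx],
        make_predictor=make_predictor,
        denormalise=prep.denormalise_target,
        calib=config.calibration,
    )

    strat_labels: dict[str, np.ndarray] = {}
    for name in config.stratify_features:
        f = cohort.schema[name]
        if f.kind == "continuous":
            strat_labels[name] = mean_split(cohort, name, train_idx)
        else:
            strat_labels[name] = cohort.records[name].to_numpy()

    iterations: list[IterationReport] = []
    current_preds: dict[str, np.ndarray] | None = None
    for iteration in range(config.max_iterations):
        if current_preds is None:
            current_preds = runner.baseline(pred_seed)["preds"]
        tables = {
            split: group_calibration(
                runner._raw(split), current_preds[split], runner._labels(split), config.calibration
            )
            for split in ("train", "val")
        }
        eq = {
            split: equity_summary(tables[split], weighted=config.weighted_gini)
            for split in ("train", "val")
        }
        strat_tables = {}
        for name, labels in strat_labels.items():
            yhat_all = np.empty(cohort.n_records)
            yhat_all[train_idx] = current_preds["train"]
            yhat_all[val_idx] = current_preds["val"]
            strat_tables[name] = stratified_calibration(
                prep.y_raw, yhat_all, labels, config.calibration.min_group_size
            )
        char = characterize_worst_groups(
            _subcohort(cohort, train_idx),
            tables["train"],
            labels_all[train_idx],
            config.calibration,
            seed=_stage_seed(config.seed, 4 + iteration),
        )
        report = IterationReport(
            index=iteration,
            group_table_train=tables["train"],
            group_table_val=tables["val"],
            equity_train=eq["train"],
            equity_val=eq["val"],
            stratified=strat_tables,
            characterisation=char,
            silhouette=sil,
        )
        met = eq["val"].gini_coefficient <= config.gini_threshold
        last = iteration == config.max_iterations - 1
        if met or last:
            iterations.append(report)
            if met:
                logger.info("equity criterion met at iteration %d", iteration)
            break
        res = runner.run(config.remediation)
        report.remediation = res
        iterations.append(report)
        # carry the first remediated trial forward as the next candidate model
        first_seed = config.remediation.trial_seeds()[0]
        flags = np.isin(runner.labels_train, list(res.designated[0]))
        if not res.designated[0]:
            break
        idx = rebalance(flags, config.remediation.multiplier, seed=first_seed + 7919)
        model = make_predictor(first_seed)
        model.fit(runner.X_train[idx], runner.y_train_fit[idx])
        current_preds = runner._score(model)

    provenance = {
        "seed": config.seed,
        "stage_seeds": {
            "split": _stage_seed(config.seed, 0),
            "predictor": pred_seed,
            "autoencoder": _stage_seed(config.seed, 2),
            "segmentation": _stage_seed(config.seed, 3),
            "characterisation": _stage_seed(config.seed, 4),
        },
        "config_hash": hashlib.sha256(repr(config).encode()).hexdigest()[:16],
        "n_records": cohort.n_records,
        "n_train": int(len(train_idx)),
        "n_val": int(len(val_idx)),
        "software_version": __package_version__(),
    }
    return FrameworkReport(
        iterations=iterations,
        provenance=provenance,
        cohort_summary=summarise_cohort(cohort),
    )


def _subcohort(cohort: Cohort, idx: np.ndarray) -> Cohort:
    return Cohort(records=cohort.records.iloc[idx].reset_index(drop=True), schema=cohort.schema)


def __package_version__() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("remcal")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def summarise_cohort(
    cohort: Cohort, stratify_by: str | None = None
) -> dict[str, pd.DataFrame]:
    """Descriptive tables: binary prevalences and target spread by flag.

    Returns ``{"prevalence": ..., "target_by_flag": ...}``; if
    ``stratify_by`` names a feature, prevalences are additionally broken out
    per level of that feature.
    """
    df = cohort.records
    tname = cohort.schema.target.name
    binaries = [f.name for f in cohort.schema.fields if f.kind == "binary"]
    rows = []
    strat_levels = (
        pd.unique(df[stratify_by]) if stratify_by is not None and stratify_by in df else []
    )
    for b in binaries:
        row = {"feature": b, "prevalence": float(df[b].mean())}
        for level in strat_levels:
            m = df[stratify_by] == level
            row[f"prevalence[{stratify_by}={level}]"] = float(df.loc[m, b].mean())
        rows.append(row)
    prevalence = pd.DataFrame(rows).set_index("feature") if rows else pd.DataFrame()

    flag_rows = []
    for b in binaries:
        for value in (0, 1):
            m = df[b] == value
            if not m.any():
                continue
            flag_rows.append(
                {
                    "flag": b,
                    "value": value,
                    "count": int(m.sum()),
                    "target_mean": float(df.loc[m, tname].mean()),
                    "target_sd": float(df.loc[m, tname].std(ddof=0)),
                }
            )
    target_by_flag = pd.DataFrame(flag_rows)
    return {"prevalence": prevalence, "target_by_flag": target_by_flag}
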