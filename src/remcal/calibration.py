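"""Fidelity and equity statistics: RMSE/NRMSE, group calibration tables,
the Gini inequality index over group fidelities, and permutation
characterisation of under-performing groups with FDR control.

NRMSE here is RMSE divided by the root-mean-square of the *observed raw
target within the evaluated subpopulation*. Dividing by the subpopulation's
own RMS makes fidelity comparable across groups with different target
dispersion — a group with intrinsically wide values (e.g. diabetics' HbA1c)
is not penalised for its higher absolute RMSE. The measure is 0 for a
perfect model and exactly 1 for the all-zero predictor; it is scale-free but
origin-dependent (adding a constant to target and predictions changes it).

All metrics are computed on the raw target scale: de-normalise predictions
before scoring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort
from .segmentation import GroupAssignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationConfig:
    B: int = 1000  # permutation rounds
    alpha: float = 0.05  # FDR level
    worst_percentile: float = 25.0
    top_n_groups: int = 5
    min_group_size: int = 30

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if not 0 < self.worst_percentile < 100:
            raise ValueError("worst_percentile must be in (0,100)")


# ---------------------------------------------------------------------------
# pointwise fidelity


def _paired(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty target vector")
    if y.size != yhat.size:
        raise ValueError(f"length mismatch: {y.size} vs {yhat.size}")
    return y, yhat


def rmse(y, yhat) -> float:
    """Root mean square error, in target units."""
    y, yhat = _paired(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def nrmse(y, yhat) -> float:
    """RMSE normalised by the root-mean-square of the observed target."""
    y, yhat = _paired(y, yhat)
    denom = float(np.sqrt(np.mean(y**2)))
    if denom == 0.0:
        raise ValueError("NRMSE undefined: observed target is identically zero")
    return rmse(y, yhat) / denom


# ---------------------------------------------------------------------------
# stratified and group-wise calibration


def stratified_calibration(
    y, yhat, strat_labels, min_group_size: int = 30
) -> pd.DataFrame:
    """Per-level count / RMSE / NRMSE for one stratification feature.

    Each level's NRMSE uses that level's own normaliser. Levels with fewer
    than ``min_group_size`` records are flagged rather than dropped.
    """
    y, yhat = _paired(y, yhat)
    labels = np.asarray(strat_labels)
    if labels.size != y.size:
        raise ValueError("stratification labels must match record count")
    levels = pd.unique(labels)
    if len(levels) < 2:
        warnings.warn("stratification feature has a single level", stacklevel=2)
    rows = []
    for level in levels:
        m = labels == level
        rows.append(
            {
                "level": level,
                "count": int(m.sum()),
                "rmse": rmse(y[m], yhat[m]),
                "nrmse": nrmse(y[m], yhat[m]),
                "flagged_small": bool(m.sum() < min_group_size),
            }
        )
    return pd.DataFrame(rows).set_index("level")


@dataclass
class GroupCalibrationTable:
    """Per-subpopulation fidelity: the framework's central audit object.

    ``table`` has one row per group (count, rmse, nrmse, included);
    groups under the minimum size are excluded-and-flagged, not silently
    dropped. The overall row covers every scored record.
    """

    table: pd.DataFrame
    overall_rmse: float
    overall_nrmse: float
    min_group_size: int

    @property
    def included(self) -> pd.DataFrame:
        return self.table[self.table["included"]]

    @property
    def group_nrmse(self) -> pd.Series:
        return self.included["nrmse"]


def group_calibration(
    y, yhat, assignment: GroupAssignment | np.ndarray, config: CalibrationConfig | None = None
) -> GroupCalibrationTable:
    """Count / RMSE / NRMSE per discovered group, plus the overall row."""
    config = config or CalibrationConfig()
    y, yhat = _paired(y, yhat)
    labels = assignment.labels if isinstance(assignment, GroupAssignment) else np.asarray(assignment)
    if labels.size != y.size:
        raise ValueError("assignment must cover every scored record")
    if labels.size == 0:
        raise ValueError("empty assignment")
    rows = []
    for g in np.unique(labels):
        m = labels == g
        count = int(m.sum())
        rows.append(
            {
                "group": int(g),
                "count": count,
                "rmse": rmse(y[m], yhat[m]),
                "nrmse": nrmse(y[m], yhat[m]),
                "included": count >= config.min_group_size,
            }
        )
    table = pd.DataFrame(rows).set_index("group")
    return GroupCalibrationTable(
        table=table,
        overall_rmse=rmse(y, yhat),
        overall_nrmse=nrmse(y, yhat),
        min_group_size=config.min_group_size,
    )


# ---------------------------------------------------------------------------
# Gini inequality index


def gini(values, method: str = "sort") -> float:
    """Gini coefficient: half the relative mean absolute difference.

    G = sum_ij |v_i - v_j| / (2 n sum_j v_j), in [0, 1). 0 means perfect
    equality; independent uniform draws give ~1/3. ``method='pairwise'``
    evaluates the double sum literally (an O(n^2) oracle); ``'sort'`` uses
    the equivalent sorted-vector (Lorenz) form.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("gini of an empty vector is undefined")
    if (v < 0).any():
        raise ValueError("gini requires nonnegative values")
    total = v.sum()
    if total == 0:
        raise ValueError("gini undefined for an all-zero vector")
    n = v.size
    if method == "pairwise":
        return float(np.abs(v[:, None] - v[None, :]).sum() / (2 * n * total))
    if method == "sort":
        s = np.sort(v)
        i = np.arange(1, n + 1)
        return float((2 * np.sum(i * s) - (n + 1) * total) / (n * total))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class EquitySummary:
    """Overall fidelity plus the dispersion of group fidelities."""

    gini_coefficient: float
    overall_nrmse: float
    group_nrmse_min: float
    group_nrmse_median: float
    group_nrmse_max: float
    n_groups: int

    def to_dict(self) -> dict:
        return {
            "gini_coefficient": self.gini_coefficient,
            "overall_nrmse": self.overall_nrmse,
            "group_nrmse_min": self.group_nrmse_min,
            "group_nrmse_median": self.group_nrmse_median,
            "group_nrmse_max": self.group_nrmse_max,
            "n_groups": self.n_groups,
        }


def equity_summary(table: GroupCalibrationTable, weighted: bool = False) -> EquitySummary:
    """Gini over group NRMSE values (one per included group, unweighted by
    default; ``weighted=True`` repeats each group's NRMSE by its count)."""
    g = table.included
    if len(g) < 2:
        raise ValueError("equity summary needs at least 2 included groups")
    values = g["nrmse"].to_numpy()
    if weighted:
        values = np.repeat(values, g["count"].to_numpy())
    return EquitySummary(
        gini_coefficient=gini(values),
        overall_nrmse=table.overall_nrmse,
        group_nrmse_min=float(g["nrmse"].min()),
        group_nrmse_median=float(g["nrmse"].median()),
        group_nrmse_max=float(g["nrmse"].max()),
        n_groups=len(g),
    )


# ---------------------------------------------------------------------------
# permutation characterisation


@dataclass
class PermutationResult:
    group: int | None
    variable: str
    statistic: float  # |mean(in group) - mean(out of group)|
    p_value: float  # (r+1)/(B+1), ties counted as exceedances
    bh_rejected: bool | None = None


def _perm_stats(
    V: np.ndarray, in_group: np.ndarray, B: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and permuted |difference of means| for each column of V."""
    n, _ = V.shape
    n_in = int(in_group.sum())
    n_out = n - n_in
    col_sums = V.sum(axis=0)

    def stats(mask_rows: np.ndarray) -> np.ndarray:
        s_in = mask_rows @ V  # (B, p) or (p,)
        return np.abs(s_in / n_in - (col_sums - s_in) / n_out)

    obs = stats(in_group.astype(float))
    perm = np.empty((B, V.shape[1]))
    mask = np.zeros(n)
    for b in range(B):
        mask[:] = 0.0
        mask[rng.permutation(n)[:n_in]] = 1.0
        perm[b] = stats(mask)
    return obs, perm


def permutation_test(
    variable, in_group, B: int = 1000, seed: int = 0
) -> PermutationResult:
    """Two-sided permutation test of a variable's mean inside vs outside a group.

    The statistic is the absolute difference of means; ``B`` seeded random
    re-assignments of group membership approximate its null distribution and
    p = (r+1)/(B+1), where r counts permuted statistics >= the observed one.
    The smallest attainable p is therefore 1/(B+1) — 0.0010 at the customary
    B = 1000.
    """
    v = np.asarray(variable, dtype=float).ravel()
    mask = np.asarray(in_group, dtype=bool).ravel()
    if v.size != mask.size:
        raise ValueError("variable and membership must have equal length")
    if mask.all() or not mask.any():
        raise ValueError("both sides of the grouping must be nonempty")
    rng = np.random.default_rng(seed)
    obs, perm = _perm_stats(v[:, None], mask, B, rng)
    r = int((perm[:, 0] >= obs[0]).sum())
    return PermutationResult(
        group=None,
        variable="",
        statistic=float(obs[0]),
        p_value=(r + 1) / (B + 1),
    )


def benjamini_hochberg(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Step-up FDR control: reject the k smallest p with p_(k) <= k*alpha/m."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


def analysis_variables(cohort: Cohort) -> pd.DataFrame:
    """Numeric view of every cohort feature for group characterisation.

    Continuous and binary features pass through; each categorical level
    becomes a 0/1 indicator named ``feature=level``. The target is included:
    characterisation describes groups, it does not fit models.
    """
    out: dict[str, np.ndarray] = {}
    for f in cohort.schema.fields:
        col = cohort.records[f.name]
        if f.kind == "categorical":
            raw = col.astype(str).to_numpy()
            for level in f.levels:
                out[f"{f.name}={level}"] = (raw == level).astype(float)
        else:
            out[f.name] = col.to_numpy(dtype=float)
    return pd.DataFrame(out)


def characterize_worst_groups(
    cohort: Cohort,
    table: GroupCalibrationTable,
    assignment: GroupAssignment | np.ndarray,
    config: CalibrationConfig | None = None,
    seed: int = 0,
    variables: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Permutation profile of the largest groups in the worst fidelity tail.

    Selects groups whose NRMSE falls in the worst ``worst_percentile`` of
    included groups (boundary ties included), keeps the ``top_n_groups``
    largest by count, and tests every analysis variable's mean in each
    selected group against the remaining records. Benjamini-Hochberg is
    applied across the full set of tests at level ``alpha``.
    """
    config = config or CalibrationConfig()
    labels = assignment.labels if isinstance(assignment, GroupAssignment) else np.asarray(assignment)
    V_df = variables if variables is not None else analysis_variables(cohort)
    if len(V_df) != labels.size:
        raise ValueError("analysis variables must cover every assigned record")

    g = table.included
    if len(g) == 0:
        raise ValueError("no group passes the size filter")
    threshold = np.percentile(g["nrmse"].to_numpy(), 100 - config.worst_percentile)
    worst = g[g["nrmse"] >= threshold]
    selected = worst.sort_values("count", ascending=False).head(config.top_n_groups)

    V = V_df.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for gid in selected.index:
        mask = labels == gid
        obs, perm = _perm_stats(V, mask, config.B, rng)
        r = (perm >= obs[None, :]).sum(axis=0)
        p = (r + 1) / (config.B + 1)
        for j, var in enumerate(V_df.columns):
            rows.append(
                {"group": int(gid), "variable": var, "statistic": float(obs[j]), "p_value": float(p[j])}
            )
    result = pd.DataFrame(rows)
    result["bh_rejected"] = benjamini_hochberg(result["p_value"].to_numpy(), config.alpha)
    logger.info(
        "characterised %d groups x %d variables = %d permutation tests (%d BH-significant)",
        len(selected),
        V_df.shape[1],
        len(result),
        int(result["bh_rejected"].sum()),
    )
    return result
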