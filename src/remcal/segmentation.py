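"""Gaussian-mixture segmentation of the latent space and silhouette diagnostics.

A K-component mixture of full-covariance bivariate Gaussians (default K=50)
is fitted to the embedding by expectation-maximisation; records are assigned
to the component with the highest posterior responsibility. K=50 trades off
diverse subpopulation identification against keeping enough records per
group; the mean silhouette score diagnoses — but does not gate — how
separated the resulting groups are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from .representation import Embedding


@dataclass
class SegmentationModel:
    K: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    seed: int
    log_likelihood_trace: list[float]
    _gm: GaussianMixture

    @property
    def latent_dim(self) -> int:
        return self.means.shape[1]


@dataclass
class GroupAssignment:
    """Hard labels (0..K-1) plus full posterior responsibilities for audit."""

    labels: np.ndarray
    responsibilities: np.ndarray

    @property
    def n_groups(self) -> int:
        return self.responsibilities.shape[1]


def fit_segmentation(
    embedding: Embedding,
    K: int = 50,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    reg_covar: float = 1e-6,
) -> SegmentationModel:
    """EM fit of a K-component full-covariance Gaussian mixture.

    The fit is run one EM step at a time (warm-started) so the per-iteration
    mean log-likelihood trace can be recorded; EM guarantees it is
    non-decreasing. Initialisation is seeded k-means++ responsibilities.
    """
    X = embedding.coordinates
    n = X.shape[0]
    if n < K:
        raise ValueError(f"need at least K={K} records to fit, got {n}")
    gm = GaussianMixture(
        n_components=K,
        covariance_type="full",
        reg_covar=reg_covar,
        max_iter=1,
        n_init=1,
        init_params="k-means++",
        warm_start=True,
        random_state=seed,
        tol=0.0,  # convergence handled by the outer loop
    )
    trace: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(max_iter):
            gm.fit(X)
            trace.append(float(gm.lower_bound_))
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                break
    if not np.isfinite(trace[-1]):
        raise RuntimeError("EM failed: non-finite log-likelihood")
    return SegmentationModel(
        K=K,
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=gm.covariances_.copy(),
        seed=seed,
        log_likelihood_trace=trace,
        _gm=gm,
    )


def assign_groups(model: SegmentationModel, embedding: Embedding) -> GroupAssignment:
    """Hard assignment to the most responsible component."""
    X = embedding.coordinates
    if X.shape[1] != model.latent_dim:
        raise ValueError(
            f"embedding has dimension {X.shape[1]}, model expects {model.latent_dim}"
        )
    resp = model._gm.predict_proba(X)
    return GroupAssignment(labels=np.argmax(resp, axis=1), responsibilities=resp)


def silhouette_diagnostic(embedding: Embedding, assignment: GroupAssignment) -> float:
    """Mean silhouette score of the hard grouping (Euclidean, latent space).

    Per point: (b - a) / max(a, b) with a the mean intra-group distance and
    b the smallest mean distance to another group. Near 1 for well-separated
    groups, near 0 or negative for poorly separated ones.
    """
    labels = assignment.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette is undefined for fewer than 2 nonempty groups")
    return float(silhouette_score(embedding.coordinates, labels, metric="euclidean"))
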