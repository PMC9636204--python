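"""Shared fixtures: one audit-mode study and one replication-mode study.

Both are session-scoped because they train networks and fit mixtures; every
consumer treats them as read-only.
"""

from dataclasses import dataclass, replace

import numpy as np
import pytest

import remcal as rc
from remcal.remediation import RemediationRunner


@dataclass
class Study:
    cohort: object
    truth: object
    train_idx: np.ndarray
    val_idx: np.ndarray
    prep: object
    autoencoder: object
    emb_train: object
    segmentation: object
    labels: np.ndarray  # over all records
    runner: RemediationRunner
    yhat_raw: np.ndarray  # baseline predictions, raw units, all records


def _build_study(n_records: int, include_withheld: bool) -> Study:
    spec = rc.biobank_like_spec(n_records=n_records, seed=3)
    cohort, truth = rc.generate_cohort(spec)
    train_idx, val_idx = rc.split_cohort(cohort, 0.75, seed=3)
    prep = rc.preprocess(cohort, train_idx)
    X_ae = prep.X
    if include_withheld:
        X_ae = np.hstack(
            [
                prep.X,
                prep.y_norm[:, None],
                cohort.records["diabetes"].to_numpy(float)[:, None],
            ]
        )
    ae = rc.train_autoencoder(
        X_ae[train_idx],
        rc.AutoencoderConfig(input_dim=X_ae.shape[1], n_epochs=5, seed=7),
    )
    emb_train = rc.encode(ae, X_ae[train_idx])
    seg = rc.fit_segmentation(emb_train, K=50, seed=11)
    labels = rc.assign_groups(seg, rc.encode(ae, X_ae)).labels

    reg_cfg = rc.RegressorConfig(input_dim=prep.input_dim, n_epochs=3)
    runner = RemediationRunner(
        X_train=prep.X[train_idx],
        y_train_fit=prep.y_norm[train_idx],
        y_train_raw=prep.y_raw[train_idx],
        X_val=prep.X[val_idx],
        y_val_raw=prep.y_raw[val_idx],
        labels_train=labels[train_idx],
        labels_val=labels[val_idx],
        make_predictor=lambda s: rc.build_regressor(replace(reg_cfg, seed=s)),
        denormalise=prep.denormalise_target,
    )
    model = rc.train_regressor(
        rc.build_regressor(replace(reg_cfg, seed=101)), prep.X[train_idx], prep.y_norm[train_idx]
    )
    yhat_raw = prep.denormalise_target(rc.predict(model, prep.X))
    return Study(
        cohort=cohort,
        truth=truth,
        train_idx=train_idx,
        val_idx=val_idx,
        prep=prep,
        autoencoder=ae,
        emb_train=emb_train,
        segmentation=seg,
        labels=labels,
        runner=runner,
        yhat_raw=yhat_raw,
    )


@pytest.fixture(scope="session")
def default_study() -> Study:
    """Audit-mode study: target and diabetes flag withheld from the latent space."""
    return _build_study(n_records=5000, include_withheld=False)


@pytest.fixture(scope="session")
def replication_study() -> Study:
    """Replication-mode study: latent space may organise by the target itself."""
    return _build_study(n_records=8000, include_withheld=True)
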