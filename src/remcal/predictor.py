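"""Reference feed-forward regression model and the pluggable-predictor contract.

The reference regressor is a fully-connected net with three ReLU hidden
layers of (16, 16, 8) neurons and a linear scalar output — with 20 inputs
this is 753 trainable parameters — trained by mini-batch Adam (batch 10,
learning rate 1e-3) on mean squared error. Any object exposing
``fit(X, y)`` / ``predict(X)`` with the same shapes can stand in for it
throughout the framework.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .nn import MLP, mlp_parameter_count


@dataclass(frozen=True)
class RegressorConfig:
    input_dim: int
    hidden_sizes: tuple[int, ...] = (16, 16, 8)
    learning_rate: float = 1e-3
    batch_size: int = 10
    n_epochs: int = 5
    seed: int = 0
    early_stop_patience: int | None = None  # needs validation data at fit time

    def __post_init__(self) -> None:
        if self.input_dim <= 0 or any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("all layer sizes must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size <= 0 or self.n_epochs < 0:
            raise ValueError("batch_size must be positive and n_epochs non-negative")

    @property
    def layer_sizes(self) -> list[int]:
        return [self.input_dim, *self.hidden_sizes, 1]


def parameter_count(
    input_dim: int, hidden_sizes: tuple[int, ...] = (16, 16, 8), output_dim: int = 1
) -> int:
    """Trainable parameters of the dense net: sum of fan_in*fan_out + fan_out."""
    return mlp_parameter_count([input_dim, *hidden_sizes, output_dim])


@dataclass
class TrainedRegressor:
    """A (possibly untrained) reference regressor; satisfies fit/predict."""

    net: MLP
    config: RegressorConfig
    loss_trace: list[float] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters

    def fit(self, X: np.ndarray, y: np.ndarray, **kw) -> "TrainedRegressor":
        return train_regressor(self, X, y, **kw)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)

    # -- persistence --------------------------------------------------------

    def save(self, weights_path: str, config_path: str) -> None:
        np.savez(weights_path, **{f"W{i}": w for i, w in enumerate(self.net.W)},
                 **{f"b{i}": b for i, b in enumerate(self.net.b)})
        with open(config_path, "w") as fh:
            json.dump(
                {
                    "input_dim": self.config.input_dim,
                    "hidden_sizes": list(self.config.hidden_sizes),
                    "learning_rate": self.config.learning_rate,
                    "batch_size": self.config.batch_size,
                    "n_epochs": self.config.n_epochs,
                    "seed": self.config.seed,
                    "loss_trace": self.loss_trace,
                },
                fh,
            )

    @classmethod
    def load(cls, weights_path: str, config_path: str) -> "TrainedRegressor":
        with open(config_path) as fh:
            cfg = json.load(fh)
        trace = cfg.pop("loss_trace", [])
        config = RegressorConfig(
            input_dim=cfg["input_dim"],
            hidden_sizes=tuple(cfg["hidden_sizes"]),
            learning_rate=cfg["learning_rate"],
            batch_size=cfg["batch_size"],
            n_epochs=cfg["n_epochs"],
            seed=cfg["seed"],
        )
        model = build_regressor(config)
        data = np.load(weights_path)
        model.net.W = [data[f"W{i}"] for i in range(len(model.net.W))]
        model.net.b = [data[f"b{i}"] for i in range(len(model.net.b))]
        model.loss_trace = list(trace)
        return model


def build_regressor(config: RegressorConfig) -> TrainedRegressor:
    """Seeded untrained network per the config (ReLU hidden, linear output)."""
    net = MLP(config.layer_sizes, seed=config.seed)
    return TrainedRegressor(net=net, config=config)


def train_regressor(
    model: TrainedRegressor,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    n_epochs: int | None = None,
) -> TrainedRegressor:
    """Seeded mini-batch Adam on MSE; mutates and returns the model.

    The training seed is derived from the config seed so that building and
    training with one config is fully reproducible.
    """
    cfg = model.config
    if n_epochs is not None:
        cfg = replace(cfg, n_epochs=n_epochs)
    trace = model.net.fit(
        X,
        np.asarray(y, dtype=float),
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        n_epochs=cfg.n_epochs,
        seed=cfg.seed + 1,  # distinct stream from initialisation
        X_val=X_val,
        Y_val=y_val,
        patience=cfg.early_stop_patience,
    )
    model.loss_trace = trace
    return model


def predict(model: TrainedRegressor, X: np.ndarray) -> np.ndarray:
    """One prediction per row, on the scale the model was trained on."""
    return model.net.forward(np.asarray(X, dtype=float)).ravel()


class MeanPredictor:
    """Trivial baseline honouring the pluggable contract: predicts mean(y)."""

    def __init__(self) -> None:
        self.mean_ = 0.0

    def fit(self, X: np.ndarray, y: np.ndarray, **kw) -> "MeanPredictor":
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(X).shape[0], self.mean_)
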