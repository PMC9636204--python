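"""Autoencoder representation learning: compress the cohort to 2-D coordinates.

The encoder passes the prepared feature matrix through (8, 4) ReLU hidden
layers into a linear two-neuron bottleneck; the decoder mirrors the encoder
back to the input dimension. Training minimises reconstruction MSE. Two
dimensions are deliberately restrictive — the aim is a compact, segmentable
and plottable description of population structure, not lossless compression.

By default the autoencoder sees the predictor features only: the target and
any feature excluded from prediction are withheld, so the latent space
cannot trivially encode the very quantity whose fidelity is being audited.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .nn import MLP


@dataclass(frozen=True)
class AutoencoderConfig:
    input_dim: int
    encoder_hidden: tuple[int, ...] = (8, 4)
    latent_dim: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 10
    n_epochs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim >= self.input_dim:
            raise ValueError("latent_dim must be smaller than input_dim")
        if any(h <= 0 for h in self.encoder_hidden) or self.latent_dim <= 0:
            raise ValueError("all layer sizes must be positive")

    @property
    def layer_sizes(self) -> list[int]:
        decoder = list(reversed(self.encoder_hidden))
        return [
            self.input_dim,
            *self.encoder_hidden,
            self.latent_dim,
            *decoder,
            self.input_dim,
        ]

    @property
    def activations(self) -> list[str]:
        # ReLU hidden layers; linear bottleneck and linear output
        n_enc = len(self.encoder_hidden)
        return ["relu"] * n_enc + ["linear"] + ["relu"] * n_enc + ["linear"]

    @property
    def bottleneck_layer(self) -> int:
        """Index (into post-activation outputs) of the bottleneck layer."""
        return len(self.encoder_hidden) + 1


@dataclass
class TrainedAutoencoder:
    net: MLP
    config: AutoencoderConfig
    loss_trace: list[float] = field(default_factory=list)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.net.forward(X)

    def reconstruction_mse(self, X: np.ndarray) -> float:
        X = np.asarray(X, dtype=float)
        return float(np.mean((self.reconstruct(X) - X) ** 2))

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for a in (*self.net.W, *self.net.b):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()[:16]


@dataclass
class Embedding:
    """Per-record latent coordinates; row i corresponds to input record i."""

    coordinates: np.ndarray
    source_fingerprint: str

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.isfinite(self.coordinates).all():
            raise ValueError("embedding contains non-finite coordinates")

    @property
    def n_records(self) -> int:
        return self.coordinates.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.coordinates.shape[1]


def build_autoencoder(config: AutoencoderConfig) -> TrainedAutoencoder:
    net = MLP(config.layer_sizes, seed=config.seed, activations=config.activations)
    return TrainedAutoencoder(net=net, config=config)


def train_autoencoder(X: np.ndarray, config: AutoencoderConfig) -> TrainedAutoencoder:
    """Jointly train encoder and decoder to minimise reconstruction MSE."""
    X = np.asarray(X, dtype=float)
    ae = build_autoencoder(config)
    ae.loss_trace = ae.net.fit(
        X,
        X,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        n_epochs=config.n_epochs,
        seed=config.seed + 1,
    )
    return ae


def encode(ae: TrainedAutoencoder, X: np.ndarray) -> Embedding:
    """Deterministic bottleneck coordinates for each row of X."""
    coords = ae.net.forward(np.asarray(X, dtype=float), upto=ae.config.bottleneck_layer)
    return Embedding(coordinates=coords, source_fingerprint=ae.fingerprint())
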