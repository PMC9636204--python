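"""Minimal seeded feed-forward networks on numpy.

Dense layers with biases, per-layer activation (ReLU or linear), mean squared
error loss, and mini-batch Adam. Everything is driven by explicit generators,
so identical seeds and inputs give bit-identical weights and predictions.
Small fully-connected nets of this size train comfortably on one CPU; the
implementation exists so the framework has a self-contained, reproducible
reference model rather than for generality.
"""

from __future__ import annotations

import numpy as np


class DataError(ValueError):
    """Training data contain non-finite values or mismatched shapes."""


def _check_finite(name: str, a: np.ndarray) -> None:
    if not np.isfinite(a).all():
        raise DataError(f"{name} contains non-finite values")


class MLP:
    """Fully-connected net: sizes ``[d_in, h1, ..., d_out]``.

    ``activations`` gives one of {"relu", "linear"} per weight layer;
    by default every hidden layer is ReLU and the output is linear.
    Initialisation is fan-in-scaled uniform, U(-1/sqrt(fan_in), +1/sqrt(fan_in)),
    for weights and biases alike.
    """

    def __init__(
        self,
        layer_sizes: list[int],
        seed: int,
        activations: list[str] | None = None,
    ) -> None:
        if any(s <= 0 for s in layer_sizes):
            raise ValueError(f"layer sizes must be positive, got {layer_sizes}")
        self.layer_sizes = list(layer_sizes)
        n_layers = len(layer_sizes) - 1
        if activations is None:
            activations = ["relu"] * (n_layers - 1) + ["linear"]
        if len(activations) != n_layers:
            raise ValueError("need one activation per weight layer")
        if any(a not in ("relu", "linear") for a in activations):
            raise ValueError(f"unknown activation in {activations}")
        self.activations = list(activations)

        rng = np.random.default_rng(seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.W.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.b.append(rng.uniform(-bound, bound, size=fan_out))

    # -- introspection ------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.W, self.b))

    @property
    def input_dim(self) -> int:
        return self.layer_sizes[0]

    def copy_weights(self) -> list[np.ndarray]:
        return [a.copy() for a in (*self.W, *self.b)]

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Post-activation outputs per layer; element 0 is the input."""
        acts = [X]
        h = X
        for W, b, act in zip(self.W, self.b, self.activations):
            z = h @ W + b
            h = np.maximum(z, 0.0) if act == "relu" else z
            acts.append(h)
        return acts

    def forward(self, X: np.ndarray, upto: int | None = None) -> np.ndarray:
        """Output of layer ``upto`` (default: the final layer)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise DataError(
                f"expected input of shape (n, {self.input_dim}), got {X.shape}"
            )
        _check_finite("input", X)
        acts = self._forward(X)
        return acts[upto if upto is not None else -1]

    def _backward(
        self, acts: list[np.ndarray], Y: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray], float]:
        """Gradients of mean squared error over the batch; returns batch loss."""
        n = acts[0].shape[0]
        diff = acts[-1] - Y
        loss = float(np.mean(diff**2))
        # d(loss)/d(output), loss averaged over all elements
        delta = (2.0 / diff.size) * diff
        gW: list[np.ndarray] = [np.empty(0)] * len(self.W)
        gb: list[np.ndarray] = [np.empty(0)] * len(self.b)
        for i in range(len(self.W) - 1, -1, -1):
            if self.activations[i] == "relu":
                delta = delta * (acts[i + 1] > 0)
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
        return gW, gb, loss

    # -- training -----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        learning_rate: float = 1e-3,
        batch_size: int = 10,
        n_epochs: int = 5,
        seed: int = 0,
        X_val: np.ndarray | None = None,
        Y_val: np.ndarray | None = None,
        patience: int | None = None,
    ) -> list[float]:
        """Seeded mini-batch Adam on MSE; returns the per-epoch loss trace.

        The trace holds the mean training MSE of each epoch (computed over
        the batches as seen, before each update). If validation data and a
        ``patience`` are given, training stops once validation MSE has not
        improved for that many consecutive epochs, and the best-validation
        weights are restored.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.shape[0] != Y.shape[0]:
            raise DataError(f"X has {X.shape[0]} rows but Y has {Y.shape[0]}")
        _check_finite("X", X)
        _check_finite("Y", Y)
        n = X.shape[0]
        if n_epochs > 0 and n < batch_size:
            raise DataError(f"need at least batch_size={batch_size} rows, got {n}")

        params = [*self.W, *self.b]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        rng = np.random.default_rng(seed)
        trace: list[float] = []
        best_val = np.inf
        best_weights: list[np.ndarray] | None = None
        stale = 0

        for _ in range(n_epochs):
            order = rng.permutation(n)
            batch_losses = []
            for start in range(0, n - batch_size + 1, batch_size):
                idx = order[start : start + batch_size]
                acts = self._forward(X[idx])
                gW, gb, loss = self._backward(acts, Y[idx])
                batch_losses.append(loss)
                t += 1
                grads = [*gW, *gb]
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g**2
                    mhat = mi / (1 - beta1**t)
                    vhat = vi / (1 - beta2**t)
                    p -= learning_rate * mhat / (np.sqrt(vhat) + eps)
            trace.append(float(np.mean(batch_losses)))
            if X_val is not None and patience is not None:
                val = float(np.mean((self.forward(X_val) - np.atleast_2d(Y_val).reshape(len(X_val), -1)) ** 2))
                if val < best_val - 1e-12:
                    best_val = val
                    best_weights = self.copy_weights()
                    stale = 0
                else:
                    stale += 1
                    if stale >= patience:
                        break
        if best_weights is not None:
            k = len(self.W)
            self.W = [w.copy() for w in best_weights[:k]]
            self.b = [b.copy() for b in best_weights[k:]]
        return trace


def mlp_parameter_count(layer_sizes: list[int]) -> int:
    """Closed form: sum over layers of fan_in*fan_out + fan_out."""
    return sum(
        fan_in * fan_out + fan_out
        for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:])
    )
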