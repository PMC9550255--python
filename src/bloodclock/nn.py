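"""Compact numpy feed-forward regressor trained with an MAE objective.

Architecture: a stack of identical dense hidden layers with ELU
activation, inverted dropout and L2 weight decay after each layer, and a
linear single-unit output. Optimization is minibatch Adam on the mean
absolute error, with early stopping on a held-out validation split (the
best-validation weights are restored). Everything is float32 and runs on
BLAS matmuls, so training a 5×256 network on a few thousand rows takes
tens of seconds on one CPU.

The implementation is deliberately minimal — exactly the pieces the aging
clock needs — and fully deterministic given its seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MAENetRegressor", "TrainingError"]


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss or weights)."""


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(x))


def _elu_grad(x: np.ndarray, fx: np.ndarray) -> np.ndarray:
    # d/dx elu(x) = 1 for x > 0, elu(x) + 1 otherwise
    return np.where(x > 0, 1.0, fx + 1.0).astype(np.float32)


class MAENetRegressor:
    """Feed-forward MAE regressor (see module docstring).

    Parameters
    ----------
    hidden_layers, units
        Depth and width of the hidden stack.
    dropout
        Per-layer dropout probability in [0, 1).
    l2
        L2 weight-decay coefficient applied to all weight matrices.
    val_fraction
        Fraction of the training rows held out for early stopping when no
        explicit validation set is passed to :meth:`fit`.
    patience
        Epochs without validation improvement (> ``min_delta``) tolerated
        before stopping.
    """

    def __init__(
        self,
        hidden_layers: int = 5,
        units: int = 256,
        dropout: float = 0.35,
        l2: float = 1e-5,
        learning_rate: float = 1.5e-3,
        batch_size: int = 128,
        max_epochs: int = 500,
        patience: int = 20,
        min_delta: float = 1e-3,
        val_fraction: float = 0.1,
        seed: int = 0,
    ) -> None:
        if not 0 <= dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if hidden_layers < 1 or units < 1:
            raise ValueError("hidden_layers and units must be >= 1")
        if l2 < 0:
            raise ValueError("l2 must be >= 0")
        self.hidden_layers = hidden_layers
        self.units = units
        self.dropout = dropout
        self.l2 = l2
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_delta = min_delta
        self.val_fraction = val_fraction
        self.seed = seed
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None
        self.history_: dict[str, list[float]] = {}

    # -- parameters --------------------------------------------------------
    def n_parameters(self, n_features: int) -> int:
        dims = [n_features] + [self.units] * self.hidden_layers + [1]
        return sum(a * b + b for a, b in zip(dims[:-1], dims[1:]))

    def _init_params(self, n_features: int, rng: np.random.Generator) -> None:
        dims = [n_features] + [self.units] * self.hidden_layers + [1]
        self.weights_ = [
            (rng.standard_normal((a, b)) * np.sqrt(2.0 / a)).astype(np.float32)
            for a, b in zip(dims[:-1], dims[1:])
        ]
        self.biases_ = [np.zeros(b, dtype=np.float32) for b in dims[1:]]

    # -- forward / backward ------------------------------------------------
    def _forward(self, X: np.ndarray, rng: np.random.Generator | None):
        """Return (prediction, cache); dropout active iff rng is given."""
        a = X
        pre, act, masks = [], [a], []
        n_hidden = len(self.weights_) - 1
        for i in range(n_hidden):
            z = a @ self.weights_[i] + self.biases_[i]
            a = _elu(z)
            if rng is not None and self.dropout > 0:
                mask = (rng.random(a.shape) >= self.dropout).astype(np.float32)
                a = a * mask / np.float32(1.0 - self.dropout)
            else:
                mask = None
            pre.append(z)
            act.append(a)
            masks.append(mask)
        out = (a @ self.weights_[-1] + self.biases_[-1]).ravel()
        return out, (pre, act, masks)

    def _backward(self, y: np.ndarray, out: np.ndarray, cache) -> tuple[list, list]:
        pre, act, masks = cache
        n = len(y)
        delta = (np.sign(out - y) / n).astype(np.float32)[:, None]
        gW = [None] * len(self.weights_)
        gb = [None] * len(self.biases_)
        gW[-1] = act[-1].T @ delta + self.l2 * self.weights_[-1]
        gb[-1] = delta.sum(axis=0)
        grad = delta @ self.weights_[-1].T
        for i in range(len(self.weights_) - 2, -1, -1):
            if masks[i] is not None:
                grad = grad * masks[i] / np.float32(1.0 - self.dropout)
            grad = grad * _elu_grad(pre[i], _elu(pre[i]))
            gW[i] = act[i].T @ grad + self.l2 * self.weights_[i]
            gb[i] = grad.sum(axis=0)
            grad = grad @ self.weights_[i].T
        return gW, gb

    # -- API ---------------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "MAENetRegressor":
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        rng = np.random.default_rng(self.seed)
        if X_val is None:
            n_val = max(1, int(round(self.val_fraction * len(X))))
            perm = rng.permutation(len(X))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[tr_idx], y[tr_idx]
        else:
            X_val = np.asarray(X_val, dtype=np.float32)
            y_val = np.asarray(y_val, dtype=np.float32)
        if len(X) < 2:
            raise TrainingError("need at least 2 training rows after validation split")

        self._init_params(X.shape[1], rng)
        mW = [np.zeros_like(w) for w in self.weights_]
        vW = [np.zeros_like(w) for w in self.weights_]
        mb = [np.zeros_like(b) for b in self.biases_]
        vb = [np.zeros_like(b) for b in self.biases_]
        b1, b2, eps = 0.9, 0.999, 1e-8
        lr = self.learning_rate
        t = 0

        best_val = np.inf
        best = None
        stale = 0
        self.history_ = {"train_mae": [], "val_mae": []}
        n = len(X)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                out, cache = self._forward(X[idx], rng)
                gW, gb = self._backward(y[idx], out, cache)
                epoch_loss += float(np.abs(out - y[idx]).sum())
                t += 1
                scale = np.sqrt(1 - b2**t) / (1 - b1**t)
                for params, grads, m, v in (
                    (self.weights_, gW, mW, vW),
                    (self.biases_, gb, mb, vb),
                ):
                    for j in range(len(params)):
                        m[j] += (1 - b1) * (grads[j] - m[j])
                        v[j] += (1 - b2) * (grads[j] ** 2 - v[j])
                        params[j] -= lr * scale * m[j] / (np.sqrt(v[j]) + eps)
            train_mae = epoch_loss / n
            val_pred, _ = self._forward(X_val, None)
            val_mae = float(np.mean(np.abs(val_pred - y_val)))
            if not np.isfinite(train_mae) or not np.isfinite(val_mae):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch} "
                    f"(train={train_mae}, val={val_mae}); reduce learning_rate"
                )
            self.history_["train_mae"].append(train_mae)
            self.history_["val_mae"].append(val_mae)
            if val_mae < best_val - self.min_delta:
                best_val = val_mae
                best = (
                    [w.copy() for w in self.weights_],
                    [b.copy() for b in self.biases_],
                )
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        if best is not None:
            self.weights_, self.biases_ = best
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.weights_ is None:
            raise RuntimeError("model is not fitted")
        out, _ = self._forward(np.asarray(X, dtype=np.float32), None)
        return out.astype(float)

    # -- (de)serialization -------------------------------------------------
    def get_params_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        for i, (w, b) in enumerate(zip(self.weights_, self.biases_)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        return arrays

    def set_params_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        n_layers = sum(1 for k in arrays if k.startswith("W"))
        self.weights_ = [np.asarray(arrays[f"W{i}"], np.float32) for i in range(n_layers)]
        self.biases_ = [np.asarray(arrays[f"b{i}"], np.float32) for i in range(n_layers)]
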