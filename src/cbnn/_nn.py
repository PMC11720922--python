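"""Minimal feed-forward network with Adam, written on numpy.

Only what the offset-logistic hazard model needs: two dense hidden layers,
ReLU or identity activations, inverted dropout, a single linear output unit,
binary cross-entropy on ``sigmoid(f(x) + offset)``, and Adam updates.  All
randomness flows through an explicit ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DenseNet"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class DenseNet:
    """Fully connected net ``p -> hidden... -> 1`` with a fixed output offset."""

    def __init__(
        self,
        n_inputs: int,
        hidden: tuple[int, ...],
        activation: str = "relu",
        dropout: float = 0.0,
        rng: np.random.Generator | int | None = None,
    ) -> None:
        if any(h < 1 for h in hidden):
            raise ValueError("hidden layer widths must be positive")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if activation not in ("relu", "linear"):
            raise ValueError("activation must be 'relu' or 'linear'")
        self.activation = activation
        self.dropout = dropout
        rng = np.random.default_rng(rng)
        sizes = [n_inputs, *hidden, 1]
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.W.append(
                rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32)
            )
            self.b.append(np.zeros(fan_out, dtype=np.float32))

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size + b.size for w, b in zip(self.W, self.b)))

    def copy_weights(self) -> list[np.ndarray]:
        return [w.copy() for w in self.W] + [b.copy() for b in self.b]

    def set_weights(self, flat: list[np.ndarray]) -> None:
        k = len(self.W)
        self.W = [w.copy() for w in flat[:k]]
        self.b = [b.copy() for b in flat[k:]]

    def _act(self, z: np.ndarray) -> np.ndarray:
        return np.maximum(z, 0.0) if self.activation == "relu" else z

    def forward(
        self, X: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list]:
        """Return output ``f(X)`` (shape (n,)) and the cache for backprop.

        Dropout is applied to hidden activations only when ``rng`` is given
        (training mode), using inverted scaling so inference needs no rescale.
        """
        a = np.asarray(X, dtype=np.float32)
        cache = []
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            z = a @ w + b
            last = i == len(self.W) - 1
            h = z if last else self._act(z)
            mask = None
            if not last and rng is not None and self.dropout > 0.0:
                mask = (
                    rng.random(size=h.shape, dtype=np.float32) >= self.dropout
                ).astype(np.float32) / np.float32(1.0 - self.dropout)
                h = h * mask
            cache.append((a, z, mask))
            a = h
        return a[:, 0], cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0].astype(float)

    def backward(self, cache: list, dout: np.ndarray) -> list[np.ndarray]:
        """Gradients of the scalar loss wrt (W..., b...); ``dout = dL/df``."""
        grad_W = [np.empty(0)] * len(self.W)
        grad_b = [np.empty(0)] * len(self.b)
        delta = dout[:, None]
        for i in reversed(range(len(self.W))):
            a, z, mask = cache[i]
            grad_W[i] = a.T @ delta
            grad_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                _, z_prev, mask_prev = cache[i - 1]
                if self.activation == "relu":
                    delta = delta * (z_prev > 0)
                if mask_prev is not None:
                    delta = delta * mask_prev
        return grad_W + grad_b

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        offset: float,
        learning_rate: float = 1e-3,
        n_batches: int = 100,
        max_epochs: int = 200,
        patience: int = 10,
        val_fraction: float = 0.2,
        rng: np.random.Generator | int | None = None,
        adam_betas: tuple[float, float] = (0.9, 0.999),
        adam_eps: float = 1e-7,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> dict:
        """Minimize BCE of ``sigmoid(f(X) + offset)`` against ``y`` with Adam.

        A ``val_fraction`` share of the rows is held out for early stopping:
        training stops after ``patience`` epochs without improvement of the
        held-out loss, restoring the best weights seen.  When an explicit
        validation set ``(X_val, y_val)`` is given it is used instead and
        every row of ``X`` is trained on.  With ``max_epochs == 0`` the
        model is returned unchanged.
        """
        rng = np.random.default_rng(rng)
        X = np.ascontiguousarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        offset = np.float32(offset)
        n = X.shape[0]
        history = {"train_loss": [], "val_loss": []}
        if max_epochs == 0:
            return history
        if X_val is not None:
            Xtr, ytr = X, y
            Xval = np.ascontiguousarray(X_val, dtype=np.float32)
            yval = np.asarray(y_val, dtype=np.float32)
            n_val = len(Xval)
        else:
            perm = rng.permutation(n)
            n_val = int(round(val_fraction * n)) if patience is not None else 0
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            Xtr, ytr = X[tr_idx], y[tr_idx]
            Xval, yval = X[val_idx], y[val_idx]

        params = self.W + self.b
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2 = adam_betas
        step = 0
        best_val = np.inf
        best_weights = self.copy_weights()
        bad_epochs = 0

        for _ in range(max_epochs):
            order = rng.permutation(len(Xtr))
            epoch_loss = 0.0
            for batch in np.array_split(order, n_batches):
                if batch.size == 0:
                    continue
                xb, yb = Xtr[batch], ytr[batch]
                f, cache = self.forward(xb, rng=rng)
                p = _sigmoid(f + offset)
                eps = 1e-12
                loss = -np.mean(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))
                if not np.isfinite(loss):
                    raise FloatingPointError("non-finite training loss")
                epoch_loss += loss * batch.size
                grads = self.backward(cache, ((p - yb) / np.float32(len(yb))).astype(np.float32))
                step += 1
                params = self.W + self.b
                for j, (prm, g) in enumerate(zip(params, grads)):
                    m[j] = b1 * m[j] + (1 - b1) * g
                    v[j] = b2 * v[j] + (1 - b2) * g * g
                    mhat = m[j] / (1 - b1**step)
                    vhat = v[j] / (1 - b2**step)
                    prm -= learning_rate * mhat / (np.sqrt(vhat) + adam_eps)
            history["train_loss"].append(epoch_loss / len(Xtr))
            if n_val:
                fval = self.predict(Xval)
                pval = _sigmoid(fval + offset)
                eps = 1e-12
                val_loss = -np.mean(
                    yval * np.log(pval + eps) + (1 - yval) * np.log(1 - pval + eps)
                )
                history["val_loss"].append(val_loss)
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_weights = self.copy_weights()
                    bad_epochs = 0
                else:
                    bad_epochs += 1
                    if bad_epochs >= patience:
                        break
        if n_val:
            self.set_weights(best_weights)
        return history
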