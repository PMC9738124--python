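"""A small pure-numpy convolutional network for binary patch classification.

Architecture: a stack of conv blocks (3x3 kernels, same padding, ReLU,
2x2 max-pooling with floor semantics, inverted dropout) followed by two
fully connected layers and a 2-way softmax, trained with Adam on the
cross-entropy loss.  Sized to stay well under ~1.5M parameters at the
default widths.

No deep-learning framework is assumed; forward and backward passes are
written against numpy only so the package runs on a bare scientific stack.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["TinyConvNet", "cross_entropy", "softmax", "TrainHistory"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray, eps: float = 1e-12) -> float:
    """Mean per-sample cross-entropy  -sum_i Y_i log(P_i)."""
    probs = np.asarray(probs, dtype=np.float64)
    onehot = np.asarray(onehot, dtype=np.float64)
    return float(-(onehot * np.log(probs + eps)).sum(axis=-1).mean())


def _im2col(x: np.ndarray) -> np.ndarray:
    """3x3 same-padding patch matrix: (N,H,W,C) -> (N*H*W, 9*C)."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.empty((n, h, w, 9 * c), dtype=x.dtype)
    k = 0
    for i in range(3):
        for j in range(3):
            cols[..., k * c : (k + 1) * c] = xp[:, i : i + h, j : j + w, :]
            k += 1
    return cols.reshape(n * h * w, 9 * c)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, h, w, c = shape
    dxp = np.zeros((n, h + 2, w + 2, c), dtype=dcols.dtype)
    dcols = dcols.reshape(n, h, w, 9 * c)
    k = 0
    for i in range(3):
        for j in range(3):
            dxp[:, i : i + h, j : j + w, :] += dcols[..., k * c : (k + 1) * c]
            k += 1
    return dxp[:, 1 : 1 + h, 1 : 1 + w, :]


def _maxpool(x: np.ndarray) -> tuple[np.ndarray, tuple]:
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
    out = xc.max(axis=(2, 4))
    return out, (x.shape, xc, out)


def _maxpool_backward(dout: np.ndarray, cache: tuple) -> np.ndarray:
    x_shape, xc, out = cache
    n, h, w, c = x_shape
    h2, w2 = h // 2, w // 2
    mask = xc == out[:, :, None, :, None, :]
    counts = mask.sum(axis=(2, 4), keepdims=True)
    dxc = mask * (dout[:, :, None, :, None, :] / counts)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, : 2 * h2, : 2 * w2, :] = dxc.reshape(n, 2 * h2, 2 * w2, c)
    return dx


@dataclasses.dataclass
class TrainHistory:
    train_loss: list[float] = dataclasses.field(default_factory=list)
    val_loss: list[float] = dataclasses.field(default_factory=list)
    val_accuracy: list[float] = dataclasses.field(default_factory=list)


class TinyConvNet:
    """Conv blocks + 2 FC layers + softmax, with fit/predict_proba API.

    Parameters
    ----------
    input_shape : (H, W, C) of the incoming patches.
    filters : filter count per conv block (one block per entry).
    fc_units : width of the first fully connected layer.
    dropout : drop probability applied after each pooling stage.
    lr : Adam learning rate.
    seed : seed for weight init, shuffling and dropout masks.
    """

    def __init__(
        self,
        input_shape: tuple[int, int, int],
        filters: tuple[int, ...] = (8, 16),
        fc_units: int = 32,
        dropout: float = 0.25,
        lr: float = 3e-3,
        seed: int = 0,
    ):
        self.input_shape = tuple(input_shape)
        self.filters = tuple(filters)
        self.fc_units = int(fc_units)
        self.dropout = float(dropout)
        self.lr = float(lr)
        self.seed = int(seed)
        self.rng = np.random.default_rng(seed)

        h, w, c = input_shape
        self.params: dict[str, np.ndarray] = {}
        c_in = c
        for b, f in enumerate(self.filters):
            fan_in = 9 * c_in
            self.params[f"Wc{b}"] = (
                self.rng.normal(scale=np.sqrt(2.0 / fan_in), size=(fan_in, f))
            ).astype(np.float32)
            self.params[f"bc{b}"] = np.full(f, 0.01, dtype=np.float32)
            c_in = f
            h, w = h // 2, w // 2
        self.flat_dim = h * w * c_in
        self.params["W1"] = self.rng.normal(
            scale=np.sqrt(2.0 / self.flat_dim), size=(self.flat_dim, self.fc_units)
        ).astype(np.float32)
        self.params["b1"] = np.full(self.fc_units, 0.01, dtype=np.float32)
        self.params["W2"] = self.rng.normal(
            scale=np.sqrt(2.0 / self.fc_units), size=(self.fc_units, 2)
        ).astype(np.float32)
        self.params["b2"] = np.zeros(2, dtype=np.float32)

        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self.history = TrainHistory()
        # per-channel input standardization, fitted from the training set
        self.in_mean = np.zeros(input_shape[2], dtype=np.float32)
        self.in_std = np.ones(input_shape[2], dtype=np.float32)

    # -- bookkeeping --------------------------------------------------------

    @property
    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {k: v.copy() for k, v in self.params.items()}
        out["in_mean"] = self.in_mean.copy()
        out["in_std"] = self.in_std.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(weights[k]).astype(np.float32)
        if "in_mean" in weights:
            self.in_mean = np.asarray(weights["in_mean"]).astype(np.float32)
            self.in_std = np.asarray(weights["in_std"]).astype(np.float32)

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray, train: bool) -> tuple[np.ndarray, list]:
        caches: list = []
        a = (x - self.in_mean) / self.in_std
        for b in range(len(self.filters)):
            n, h, w, c = a.shape
            cols = _im2col(a)
            z = cols @ self.params[f"Wc{b}"] + self.params[f"bc{b}"]
            z = z.reshape(n, h, w, -1)
            relu_mask = z > 0
            a_relu = z * relu_mask
            pooled, pool_cache = _maxpool(a_relu)
            if train and self.dropout > 0:
                keep = 1.0 - self.dropout
                drop_mask = ((self.rng.random(pooled.shape) < keep) / keep).astype(np.float32)
                out = pooled * drop_mask
            else:
                drop_mask = None
                out = pooled
            caches.append((a.shape, cols, relu_mask, pool_cache, drop_mask))
            a = out
        n = a.shape[0]
        flat = a.reshape(n, -1)
        z1 = flat @ self.params["W1"] + self.params["b1"]
        relu1 = z1 > 0
        a1 = z1 * relu1
        logits = a1 @ self.params["W2"] + self.params["b2"]
        caches.append((a.shape, flat, relu1, a1))
        return logits, caches

    def _backward(self, dlogits: np.ndarray, caches: list) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        a_shape, flat, relu1, a1 = caches[-1]
        grads["W2"] = a1.T @ dlogits
        grads["b2"] = dlogits.sum(axis=0)
        da1 = dlogits @ self.params["W2"].T
        dz1 = da1 * relu1
        grads["W1"] = flat.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        dflat = dz1 @ self.params["W1"].T
        da = dflat.reshape(a_shape)
        for b in range(len(self.filters) - 1, -1, -1):
            in_shape, cols, relu_mask, pool_cache, drop_mask = caches[b]
            if drop_mask is not None:
                da = da * drop_mask
            da_relu = _maxpool_backward(da, pool_cache)
            dz = da_relu * relu_mask
            n, h, w, f = dz.shape
            dz2 = dz.reshape(n * h * w, f)
            grads[f"Wc{b}"] = cols.T @ dz2
            grads[f"bc{b}"] = dz2.sum(axis=0)
            dcols = dz2 @ self.params[f"Wc{b}"].T
            da = _col2im(dcols, in_shape)
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = self._adam_m[k] / (1 - b1**t)
            vhat = self._adam_v[k] / (1 - b2**t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)

    # -- public API ---------------------------------------------------------

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        outs = []
        for start in range(0, x.shape[0], batch_size):
            logits, _ = self._forward(x[start : start + batch_size], train=False)
            outs.append(softmax(logits))
        return np.concatenate(outs, axis=0)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        epochs: int = 15,
        batch_size: int = 32,
        patience: int = 4,
    ) -> TrainHistory:
        """Train until the validation loss stops improving (early stopping).

        ``y`` holds class indices in {0, 1}.  The weights of the best
        validation epoch are restored at the end.
        """
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        n = x.shape[0]
        self.in_mean = x.mean(axis=(0, 1, 2)).astype(np.float32)
        self.in_std = (x.std(axis=(0, 1, 2)) + 1e-6).astype(np.float32)
        have_val = x_val is not None and len(x_val) > 0
        best_val = np.inf
        best_weights = self.get_weights()
        stale = 0
        for _epoch in range(epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], y[idx]
                logits, caches = self._forward(xb, train=True)
                probs = softmax(logits)
                onehot = np.eye(2)[yb]
                losses.append(cross_entropy(probs, onehot))
                dlogits = ((probs - onehot) / xb.shape[0]).astype(np.float32)
                grads = self._backward(dlogits, caches)
                self._adam_step(grads)
            self.history.train_loss.append(float(np.mean(losses)))
            if have_val:
                pv = self.predict_proba(np.asarray(x_val, dtype=np.float32))
                yv = np.asarray(y_val, dtype=np.int64)
                vloss = cross_entropy(pv, np.eye(2)[yv])
                vacc = float((pv.argmax(axis=1) == yv).mean())
                self.history.val_loss.append(vloss)
                self.history.val_accuracy.append(vacc)
                if vloss < best_val - 1e-6:
                    best_val = vloss
                    best_weights = self.get_weights()
                    stale = 0
                else:
                    stale += 1
                    if stale >= patience:
                        break
        if have_val:
            self.set_weights(best_weights)
        return self.history
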