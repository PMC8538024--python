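"""Minimal neural-network engine for small image-regression models.

Implements exactly what the eyelid pipeline needs and nothing more: stride-1
3x3 convolutions (im2col), 2x2 max pooling, dense layers, ReLU, inverted
dropout, Adam, a one-cycle cosine learning-rate schedule and an MSE training
loop.  Everything is plain numpy, deterministic given a seed, and sized for
CPU training of networks in the 10^5-10^6 parameter range.

Layout convention: NCHW float32 for images, (N, D) for dense activations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dense",
    "Conv2d",
    "MaxPool2d",
    "ReLU",
    "Dropout",
    "SoftArgmax2d",
    "Flatten",
    "Sequential",
    "Adam",
    "one_cycle_lr",
    "fit_regressor",
]


class Layer:
    """Base layer: stateless unless it owns parameters."""

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He-normal fan-in initialisation
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N*Ho*Wo, C*k*k) patch matrix, stride 1."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # N, C, Ho, Wo, k, k
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols)


class Conv2d(Layer):
    """3x3 (or kxk) stride-1 convolution with 'same' padding by default."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3,
                 pad: int | None = None):
        self.k = k
        self.pad = (k - 1) // 2 if pad is None else pad
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x, rng=None):
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        ho, wo = h + 2 * p - k + 1, w + 2 * p - k + 1
        cols = _im2col(x, k, p)
        self._cols, self._shape = cols, (n, c, h, w, ho, wo)
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, c, h, w, ho, wo = self._shape
        k, p = self.k, self.pad
        g = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, -1)  # rows match cols
        self.dW[...] = (g.T @ self._cols).reshape(self.W.shape)
        self.db[...] = g.sum(axis=0)
        # dX as a full correlation of grad with the flipped kernel
        wf = self.W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (c_in, c_out, k, k)
        gim = grad.reshape(n, -1, ho, wo)
        cols_g = _im2col(gim, k, k - 1 - p)
        dx = cols_g @ wf.reshape(c, -1).T
        return dx.reshape(n, h, w, c).transpose(0, 3, 1, 2)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class MaxPool2d(Layer):
    """Non-overlapping 2x2 max pool (input H, W must be even)."""

    def forward(self, x, rng=None):
        n, c, h, w = x.shape
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        self._arg = win.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(win, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(out, self._arg[..., None], grad[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)


class ReLU(Layer):
    def forward(self, x, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; active only when a generator is supplied (training)."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self._mask: np.ndarray | None = None

    def forward(self, x, rng=None):
        if rng is None or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class SoftArgmax2d(Layer):
    """Spatial softmax over a single-channel map -> normalized (x, y).

    Output coordinates are probability-weighted cell centers in [0, 1],
    so a downstream MSE on normalized coordinates trains the map to place
    its mass on the target location with sub-cell precision.
    """

    def forward(self, x, rng=None):
        n, c, h, w = x.shape
        if c != 1:
            raise ValueError("SoftArgmax2d expects a single-channel map")
        z = x.reshape(n, h * w)
        z = z - z.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        jj, ii = np.meshgrid(np.arange(w), np.arange(h))
        cx = ((jj.ravel() + 0.5) / w).astype(np.float32)
        cy = ((ii.ravel() + 0.5) / h).astype(np.float32)
        out = np.stack([p @ cx, p @ cy], axis=1)
        self._cache = (p, cx, cy, out, (n, c, h, w))
        return out

    def backward(self, grad):
        p, cx, cy, out, shape = self._cache
        # d z_i = p_i * sum_k grad_k (c_ik - out_k)
        gz = p * (grad[:, 0:1] * (cx[None, :] - out[:, 0:1])
                  + grad[:, 1:2] * (cy[None, :] - out[:, 1:2]))
        return gz.reshape(shape)


class Flatten(Layer):
    def forward(self, x, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    # --- checkpointing -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(state):
            raise ValueError("checkpoint parameter count mismatch")
        for i, p in enumerate(own):
            src = state[f"p{i}"]
            if src.shape != p.shape:
                raise ValueError(f"parameter {i} shape mismatch: {src.shape} vs {p.shape}")
            p[...] = src


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params, self.grad_refs = params, grads
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, self.grad_refs, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


def one_cycle_lr(step: int, total_steps: int, max_lr: float,
                 pct_start: float = 0.3, div: float = 10.0,
                 final_div: float = 100.0) -> float:
    """One-cycle schedule with cosine ramp-up and cosine annealing decay."""
    warm = max(1, int(total_steps * pct_start))
    lo, final = max_lr / div, max_lr / final_div
    if step < warm:
        f = step / warm
        return lo + (max_lr - lo) * 0.5 * (1 - np.cos(np.pi * f))
    f = (step - warm) / max(1, total_steps - warm)
    return final + (max_lr - final) * 0.5 * (1 + np.cos(np.pi * f))


@dataclass
class FitHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"train_loss": self.train_loss, "val_loss": self.val_loss})


def fit_regressor(model: Sequential, x: np.ndarray, y: np.ndarray, *,
                  epochs: int, batch_size: int, max_lr: float, seed: int,
                  x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
                  augment_fn=None, weight_decay: float = 0.0) -> FitHistory:
    """Adam + MSE training loop with a one-cycle cosine LR schedule.

    Deterministic given ``seed``: weight init is the caller's concern, batch
    order and dropout masks derive from a single generator created here.
    A terminal minibatch smaller than ``batch_size`` is allowed.
    """
    if len(x) != len(y):
        raise ValueError("x and y length mismatch")
    y = y.reshape(len(y), -1).astype(np.float32)
    rng = np.random.default_rng(seed)
    n = len(x)
    n_batches = max(1, int(np.ceil(n / batch_size)))
    total_steps = epochs * n_batches
    opt = Adam(model.params(), model.grads(), weight_decay=weight_decay)
    history = FitHistory()
    step = 0
    for _ in range(epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for b in range(n_batches):
            idx = perm[b * batch_size:(b + 1) * batch_size]
            xb = x[idx].astype(np.float32)
            if augment_fn is not None:
                xb = augment_fn(xb, rng)
            yb = y[idx]
            pred = model.forward(xb, rng)
            diff = pred - yb
            loss = float(np.mean(diff * diff))
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss; aborting fold")
            epoch_loss += loss * len(idx)
            model.backward(2.0 * diff / diff.size)
            opt.step(one_cycle_lr(step, total_steps, max_lr))
            step += 1
        history.train_loss.append(epoch_loss / n)
        if x_val is not None:
            pv = predict_in_batches(model, x_val, batch_size)
            history.val_loss.append(float(np.mean((pv - y_val.reshape(len(y_val), -1)) ** 2)))
    return history


def predict_in_batches(model: Sequential, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    out = []
    for b in range(0, len(x), batch_size):
        out.append(model.forward(x[b:b + batch_size].astype(np.float32), rng=None))
    return np.concatenate(out, axis=0)
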