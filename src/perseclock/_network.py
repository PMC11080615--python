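"""Minimal feed-forward network engine: layers, backprop, and Adam.

Everything operates on float64 numpy arrays of shape (batch, features).
Layers cache what their backward pass needs on forward; ``backward`` returns
the gradient w.r.t. the layer input and stores parameter gradients in
``layer.grads`` aligned with ``layer.params``.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Linear(Layer):
    """Affine map with the uniform +-1/sqrt(fan_in) init common in deep-learning frameworks."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        bound = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.b = rng.uniform(-bound, bound, size=n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x, training, rng=None):
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, grad):
        return np.where(self._neg, self.slope * grad, grad)


class BatchNorm1d(Layer):
    """Per-feature batch normalization with running statistics for eval mode."""

    def __init__(self, n_features: int, momentum: float = 0.1,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x, training, rng=None):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            n = x.shape[0]
            unbiased = var * n / max(n - 1, 1)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        self.grads[0][...] = (grad * self._xhat).sum(axis=0)
        self.grads[1][...] = grad.sum(axis=0)
        if not self._training:
            return grad * self.gamma * self._inv_std
        n = grad.shape[0]
        gxhat = grad * self.gamma
        return (self._inv_std / n) * (
            n * gxhat - gxhat.sum(axis=0)
            - self._xhat * (gxhat * self._xhat).sum(axis=0)
        )


class Dropout(Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class SqueezeExcite(Layer):
    """Channel-attention block operating on flattened block tensors.

    Input rows are length ``positions * channels`` vectors laid out so that
    consecutive entries fall in consecutive channels (element i belongs to
    channel ``i % channels``).  Squeeze = per-channel mean over the
    ``positions`` entries; excitation = two fully connected layers
    (ReLU bottleneck of width ``max(1, channels // reduction)``, sigmoid
    output); scale = multiply each channel by its gate.
    """

    def __init__(self, positions: int, channels: int, reduction: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if reduction > channels:
            raise ValueError(
                f"se_reduction ({reduction}) must not exceed channels ({channels})")
        self.positions = positions
        self.channels = channels
        self.bottleneck = max(1, channels // reduction)
        self.fc1 = Linear(channels, self.bottleneck, rng)
        self.fc2 = Linear(self.bottleneck, channels, rng)
        self.params = self.fc1.params + self.fc2.params
        self.grads = self.fc1.grads + self.fc2.grads

    def gates(self, x: np.ndarray) -> np.ndarray:
        """Per-sample excitation gates in (0, 1), shape (batch, channels)."""
        t = x.reshape(x.shape[0], self.positions, self.channels)
        pooled = t.mean(axis=1)
        h = np.maximum(self.fc1.forward(pooled, False), 0.0)
        return _sigmoid(self.fc2.forward(h, False))

    def forward(self, x, training, rng=None):
        b = x.shape[0]
        t = x.reshape(b, self.positions, self.channels)
        pooled = t.mean(axis=1)
        z1 = self.fc1.forward(pooled, training)
        h = np.maximum(z1, 0.0)
        self._relu_neg = z1 < 0
        g = _sigmoid(self.fc2.forward(h, training))
        self._t, self._g = t, g
        return (t * g[:, None, :]).reshape(b, -1)

    def backward(self, grad):
        b = grad.shape[0]
        gt = grad.reshape(b, self.positions, self.channels)
        d_direct = gt * self._g[:, None, :]
        d_gate = (gt * self._t).sum(axis=1)               # (b, channels)
        d_u = d_gate * self._g * (1.0 - self._g)          # sigmoid'
        d_h = self.fc2.backward(d_u)
        d_z1 = np.where(self._relu_neg, 0.0, d_h)
        d_pooled = self.fc1.backward(d_z1)
        d_t = d_direct + d_pooled[:, None, :] / self.positions
        return d_t.reshape(b, -1)


class Network:
    """A sequence of layers with a shared forward/backward pass."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays defining the model state, incl. batch-norm running stats."""
        out = []
        for layer in self.layers:
            out.extend(layer.params)
            if isinstance(layer, BatchNorm1d):
                out.extend([layer.running_mean, layer.running_var])
        return out

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        arrays = self.state_arrays()
        if len(arrays) != len(state):
            raise ValueError("state length mismatch")
        for dst, src in zip(arrays, state):
            if dst.shape != src.shape:
                raise ValueError(f"state shape mismatch: {dst.shape} vs {src.shape}")
            dst[...] = src


class Adam:
    """Adam with framework-default betas (0.9, 0.999) and eps 1e-8."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
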