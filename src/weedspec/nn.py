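"""Minimal numpy neural-network engine for the spectral-spatial classifier.

Layers use channels-last layout: 3-D convolution inputs are
``(batch, H, W, D, C)`` with D the spectral axis, 2-D inputs ``(batch, H, W, C)``.
All convolutions are valid (no spatial padding), matching the architecture's
shrinking shape chain.  Convolutions are evaluated by looping over the small
set of kernel offsets and accumulating batched matmuls, which keeps memory flat
and lets BLAS do the work; backward passes mirror the loops exactly.

Weight initialization is variance-scaling uniform (limit sqrt(6 / fan_in)),
drawn from a generator owned by the network so that a seed fully determines
training.  The optimizer is Adam; the loss is softmax cross-entropy.
"""

from __future__ import annotations

import itertools

import numpy as np

from .errors import ParameterError, ShapeMismatchError

__all__ = [
    "relu",
    "softsign",
    "sigmoid",
    "Layer",
    "Conv3D",
    "Conv2D",
    "BatchNorm",
    "Activation",
    "Reshape",
    "Flatten",
    "Dense",
    "Dropout",
    "SEBlock",
    "Network",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softsign(x):
    """Softsign activation x / (1 + |x|): odd, bounded in (-1, 1), gentle slope."""
    x = np.asarray(x, dtype=float)
    out = x / (1.0 + np.abs(x))
    return out if out.ndim else float(out)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _uniform_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: ``params``/``grads`` dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv3D(Layer):
    def __init__(self, in_ch: int, filters: int, kernel: tuple[int, int, int], rng):
        super().__init__()
        kh, kw, kd = kernel
        if min(kh, kw, kd) < 1 or not all(k % 2 == 1 for k in kernel):
            raise ParameterError("kernel dims must be odd and positive")
        self.kernel = kernel
        fan_in = kh * kw * kd * in_ch
        self.params["W"] = _uniform_init(rng, (kh, kw, kd, in_ch, filters), fan_in)
        self.params["b"] = np.zeros(filters)

    def forward(self, x, training):
        self._x = x
        kh, kw, kd = self.kernel
        n, h, w, d, _ = x.shape
        ho, wo, do = h - kh + 1, w - kw + 1, d - kd + 1
        if min(ho, wo, do) < 1:
            raise ShapeMismatchError("input smaller than kernel")
        W, b = self.params["W"], self.params["b"]
        out = np.broadcast_to(b, (n, ho, wo, do, b.size)).copy()
        for i, j, k in itertools.product(range(kh), range(kw), range(kd)):
            out += x[:, i : i + ho, j : j + wo, k : k + do, :] @ W[i, j, k]
        return out

    def backward(self, g):
        x = self._x
        kh, kw, kd = self.kernel
        n, ho, wo, do, _ = g.shape
        W = self.params["W"]
        dW = np.zeros_like(W)
        dx = np.zeros_like(x)
        for i, j, k in itertools.product(range(kh), range(kw), range(kd)):
            xs = x[:, i : i + ho, j : j + wo, k : k + do, :]
            dW[i, j, k] = np.tensordot(xs, g, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
            dx[:, i : i + ho, j : j + wo, k : k + do, :] += g @ W[i, j, k].T
        self.grads["W"] = dW
        self.grads["b"] = g.sum(axis=(0, 1, 2, 3))
        return dx


class Conv2D(Layer):
    def __init__(self, in_ch: int, filters: int, kernel: tuple[int, int], rng):
        super().__init__()
        kh, kw = kernel
        if min(kh, kw) < 1 or kh % 2 == 0 or kw % 2 == 0:
            raise ParameterError("kernel dims must be odd and positive")
        self.kernel = kernel
        fan_in = kh * kw * in_ch
        self.params["W"] = _uniform_init(rng, (kh, kw, in_ch, filters), fan_in)
        self.params["b"] = np.zeros(filters)

    def forward(self, x, training):
        self._x = x
        kh, kw = self.kernel
        n, h, w, _ = x.shape
        ho, wo = h - kh + 1, w - kw + 1
        if min(ho, wo) < 1:
            raise ShapeMismatchError("input smaller than kernel")
        W, b = self.params["W"], self.params["b"]
        out = np.broadcast_to(b, (n, ho, wo, b.size)).copy()
        for i, j in itertools.product(range(kh), range(kw)):
            out += x[:, i : i + ho, j : j + wo, :] @ W[i, j]
        return out

    def backward(self, g):
        x = self._x
        kh, kw = self.kernel
        n, ho, wo, _ = g.shape
        W = self.params["W"]
        dW = np.zeros_like(W)
        dx = np.zeros_like(x)
        for i, j in itertools.product(range(kh), range(kw)):
            xs = x[:, i : i + ho, j : j + wo, :]
            dW[i, j] = np.tensordot(xs, g, axes=([0, 1, 2], [0, 1, 2]))
            dx[:, i : i + ho, j : j + wo, :] += g @ W[i, j].T
        self.grads["W"] = dW
        self.grads["b"] = g.sum(axis=(0, 1, 2))
        return dx


class BatchNorm(Layer):
    """Channels-last batch normalization over all non-channel axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, g):
        axes = tuple(range(g.ndim - 1))
        xhat = self._xhat
        self.grads["gamma"] = (g * xhat).sum(axis=axes)
        self.grads["beta"] = g.sum(axis=axes)
        gam = self.params["gamma"]
        if not self._training:
            return g * gam / self._std
        m = self._m
        dxhat = g * gam
        return (
            dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)
        ) / self._std


class Activation(Layer):
    def __init__(self, kind: str):
        super().__init__()
        if kind not in ("relu", "softsign"):
            raise ParameterError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x, training):
        self._x = x
        return relu(x) if self.kind == "relu" else softsign(x)

    def backward(self, g):
        if self.kind == "relu":
            return g * (self._x > 0)
        return g / (1.0 + np.abs(self._x)) ** 2


class Reshape(Layer):
    def __init__(self, target: tuple):
        super().__init__()
        self.target = target

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, g):
        return g.reshape(self._shape)


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng):
        super().__init__()
        self.params["W"] = _uniform_init(rng, (in_dim, out_dim), in_dim)
        self.params["b"] = np.zeros(out_dim)

    def forward(self, x, training):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads["W"] = self._x.T @ g
        self.grads["b"] = g.sum(axis=0)
        return g @ self.params["W"].T


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ParameterError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, training):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class SEBlock(Layer):
    """Squeeze-and-excitation channel attention.

    Squeeze: global spatial mean -> per-channel descriptor.  Excitation: a
    two-layer bottleneck gate (ReLU then sigmoid) that rescales each channel
    by a factor in (0, 1).
    """

    def __init__(self, channels: int, reduction: int, rng):
        super().__init__()
        if channels % reduction != 0:
            raise ParameterError("channels must be divisible by the SE reduction")
        hidden = channels // reduction
        self.channels = channels
        self.params["W1"] = _uniform_init(rng, (channels, hidden), channels)
        self.params["b1"] = np.zeros(hidden)
        self.params["W2"] = _uniform_init(rng, (hidden, channels), hidden)
        self.params["b2"] = np.zeros(channels)

    def forward(self, x, training):
        if x.shape[-1] != self.channels:
            raise ShapeMismatchError(
                f"SE block built for {self.channels} channels, got {x.shape[-1]}"
            )
        self._x = x
        self._spatial = x.shape[1:-1]
        z = x.mean(axis=tuple(range(1, x.ndim - 1)))  # (n, C)
        h = relu(z @ self.params["W1"] + self.params["b1"])
        gate = sigmoid(h @ self.params["W2"] + self.params["b2"])
        self._z, self._h, self._gate = z, h, gate
        shape = (x.shape[0],) + (1,) * (x.ndim - 2) + (self.channels,)
        return x * gate.reshape(shape)

    def backward(self, g):
        x, z, h, gate = self._x, self._z, self._h, self._gate
        spatial_axes = tuple(range(1, x.ndim - 1))
        shape = (x.shape[0],) + (1,) * (x.ndim - 2) + (self.channels,)
        dgate = (g * x).sum(axis=spatial_axes)  # (n, C)
        dx = g * gate.reshape(shape)
        dpre2 = dgate * gate * (1.0 - gate)
        self.grads["W2"] = h.T @ dpre2
        self.grads["b2"] = dpre2.sum(axis=0)
        dh = dpre2 @ self.params["W2"].T
        dpre1 = dh * (h > 0)
        self.grads["W1"] = z.T @ dpre1
        self.grads["b1"] = dpre1.sum(axis=0)
        dz = dpre1 @ self.params["W1"].T
        n_spatial = int(np.prod(self._spatial))
        dx = dx + dz.reshape(shape) / n_spatial
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.sum(onehot * np.log(np.maximum(p, 1e-300))) / n
    return loss, (p - onehot) / n


class Network:
    """A plain layer stack with shared parameter access for the optimizer."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(ly, k) for ly in self.layers for k in ly.params]

    def get_state(self) -> dict[str, np.ndarray]:
        state = {}
        for i, ly in enumerate(self.layers):
            for k, v in ly.params.items():
                state[f"layer{i}.{k}"] = v
            if isinstance(ly, BatchNorm):
                state[f"layer{i}.running_mean"] = ly.running_mean
                state[f"layer{i}.running_var"] = ly.running_var
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, ly in enumerate(self.layers):
            for k in ly.params:
                ly.params[k] = np.array(state[f"layer{i}.{k}"])
            if isinstance(ly, BatchNorm):
                ly.running_mean = np.array(state[f"layer{i}.running_mean"])
                ly.running_var = np.array(state[f"layer{i}.running_var"])


class Adam:
    def __init__(self, net: Network, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {id(ly): {k: np.zeros_like(v) for k, v in ly.params.items()}
                  for ly in net.layers}
        self.v = {id(ly): {k: np.zeros_like(v) for k, v in ly.params.items()}
                  for ly in net.layers}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for ly in self.net.layers:
            for k, p in ly.params.items():
                g = ly.grads.get(k)
                if g is None:
                    continue
                m = self.m[id(ly)][k]
                v = self.v[id(ly)][k]
                m += (1 - self.beta1) * (g - m)
                v += (1 - self.beta2) * (g * g - v)
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
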