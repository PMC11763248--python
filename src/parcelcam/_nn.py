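"""Minimal deterministic neural-network layers in numpy.

Reverse-mode gradients are hand-written per layer; a network is an ordered
list of layers, some of which are flagged as *taps* whose activations and
upstream gradients are captured for class-activation mapping.  Everything is
seeded through an explicit ``numpy.random.Generator``, so two builds from
the same seed are bitwise identical.

Tensor layouts: conv features are ``(B, C, X, Y, Z)``, edge features are
``(B, C, N, N)``, dense features are ``(B, F)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "Param", "Layer", "Conv3d", "BatchNorm", "ReLU", "Linear",
    "GlobalAvgPool", "Flatten", "ResidualBlock3d", "TapNet", "Adam",
    "sigmoid", "bce_with_logits", "ClassScore",
]


def sigmoid(z):
    z = np.asarray(z)
    if not np.issubdtype(z.dtype, np.floating):
        z = z.astype(float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class ClassScore:
    """Binary class score: a single pre-sigmoid logit.

    The AD score is the logit itself and the HC score its negation, so the
    two class scores always sum to zero and the sigmoid of the logit is the
    AD probability.
    """

    logit: float

    @property
    def probability(self) -> float:
        return float(sigmoid(self.logit))

    @property
    def s_ad(self) -> float:
        return float(self.logit)

    @property
    def s_hc(self) -> float:
        return -float(self.logit)

    @property
    def predicted_label(self) -> str:
        return "AD" if self.probability >= 0.5 else "HC"


def class_sign(label: str) -> float:
    """Sign applied to the logit gradient to attribute a class."""
    if label == "AD":
        return 1.0
    if label == "HC":
        return -1.0
    raise ValueError(f"unknown class {label!r}")


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """3D convolution, stride s, symmetric zero padding."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        std = np.sqrt(2.0 / (cin * k ** 3))
        self.W = Param(rng.normal(0.0, std, size=(cout, cin, k, k, k)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.W, self.b]

    def _out_spatial(self, shape):
        return tuple((s + 2 * self.pad - self.k) // self.stride + 1 for s in shape)

    def forward(self, x, train=True):
        B, C = x.shape[:2]
        p, s, k = self.pad, self.stride, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        ox, oy, oz = self._out_spatial(x.shape[2:])
        if min(ox, oy, oz) < 1:
            raise ValueError(f"input spatial shape {x.shape[2:]} too small for conv")
        cout = self.W.value.shape[0]
        # im2col: one patch matrix, one GEMM
        win = np.lib.stride_tricks.sliding_window_view(
            xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
            B * ox * oy * oz, C * k ** 3)
        w2 = self.W.value.reshape(cout, C * k ** 3).astype(xp.dtype, copy=False)
        out = (cols @ w2.T).reshape(B, ox, oy, oz, cout)
        out = np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))
        out += self.b.value[None, :, None, None, None].astype(xp.dtype,
                                                              copy=False)
        self._cache = (cols, xp.shape, x.shape)
        return out

    def backward(self, g):
        cols, xp_shape, in_shape = self._cache
        B, C = in_shape[:2]
        p, s, k = self.pad, self.stride, self.k
        ox, oy, oz = g.shape[2:]
        cout = g.shape[1]
        g2 = g.transpose(0, 2, 3, 4, 1).reshape(-1, cout)  # (B*V, cout)
        self.b.grad += g.sum(axis=(0, 2, 3, 4))
        self.W.grad += (g2.T @ cols).reshape(self.W.value.shape)
        w2 = self.W.value.reshape(cout, C * k ** 3).astype(g2.dtype, copy=False)
        dcols = (g2 @ w2).reshape(B, ox, oy, oz, C, k, k, k)
        # col2im: scatter-add each kernel offset back onto the padded grid
        dxp = np.zeros(xp_shape, dtype=g.dtype)
        for di, dj, dk in product(range(k), repeat=3):
            dxp[:, :, di:di + s * ox:s, dj:dj + s * oy:s, dk:dk + s * oz:s] += \
                dcols[:, :, :, :, :, di, dj, dk].transpose(0, 4, 1, 2, 3)
        if p:
            return dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (1)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def params(self):
        return [self.gamma, self.beta]

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train=True):
        axes = (0,) + tuple(range(2, x.ndim))
        sh = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            std = np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(sh)) / std.reshape(sh)
            self._cache = ("train", xhat, std, axes, sh)
        else:
            std = np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean.reshape(sh)) / std.reshape(sh)
            self._cache = ("eval", None, std, axes, sh)
        return self.gamma.value.reshape(sh) * xhat + self.beta.value.reshape(sh)

    def backward(self, g):
        mode, xhat, std, axes, sh = self._cache
        if mode == "eval":
            return g * (self.gamma.value / std).reshape(sh)
        n = g.size // g.shape[1]
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        dxhat = g * self.gamma.value.reshape(sh)
        m1 = dxhat.mean(axis=axes).reshape(sh)
        m2 = (dxhat * xhat).mean(axis=axes).reshape(sh)
        return (dxhat - m1 - xhat * m2) / std.reshape(sh)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Linear(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / nin)
        self.W = Param(rng.normal(0.0, std, size=(nin, nout)))
        self.b = Param(np.zeros(nout))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g):
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T


class GlobalAvgPool(Layer):
    """Mean over all spatial axes: (B, C, ...) -> (B, C)."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, g):
        sh = self._shape
        n = int(np.prod(sh[2:]))
        out = np.broadcast_to(
            g.reshape(g.shape + (1,) * (len(sh) - 2)), sh
        ) / n
        return np.ascontiguousarray(out)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class ResidualBlock3d(Layer):
    """conv-bn-relu-conv-bn + shortcut, then relu.

    The shortcut is the identity when shape is preserved, else a strided
    1x1x1 projection with its own batchnorm.
    """

    def __init__(self, cin: int, cout: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv3d(cin, cout, k=3, stride=stride, rng=rng)
        self.bn1 = BatchNorm(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(cout, cout, k=3, stride=1, rng=rng)
        self.bn2 = BatchNorm(cout)
        self.relu_out = ReLU()
        if stride != 1 or cin != cout:
            self.proj: Sequential | None = Sequential(
                [Conv3d(cin, cout, k=1, stride=stride, pad=0, rng=rng), BatchNorm(cout)]
            )
        else:
            self.proj = None

    def params(self):
        out = (self.conv1.params() + self.bn1.params()
               + self.conv2.params() + self.bn2.params())
        if self.proj is not None:
            out += self.proj.params()
        return out

    def forward(self, x, train=True):
        h = self.conv1.forward(x, train)
        h = self.bn1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.bn2.forward(h, train)
        short = x if self.proj is None else self.proj.forward(x, train)
        return self.relu_out.forward(h + short, train)

    def backward(self, g):
        g = self.relu_out.backward(g)
        gm = self.bn2.backward(g)
        gm = self.conv2.backward(gm)
        gm = self.relu1.backward(gm)
        gm = self.bn1.backward(gm)
        gm = self.conv1.backward(gm)
        gs = g if self.proj is None else self.proj.backward(g)
        return gm + gs


def cast_layer(layer: "Layer", dtype) -> None:
    """Cast a layer's parameters (and batchnorm statistics) in place."""
    for p in layer.params():
        p.value = p.value.astype(dtype)
        p.grad = p.grad.astype(dtype)
    for bn in _batchnorms(layer):
        bn.running_mean = bn.running_mean.astype(dtype)
        bn.running_var = bn.running_var.astype(dtype)


class TapNet:
    """An ordered layer chain with named tap points.

    A tap captures the activation of the flagged layer's output on the
    forward pass and, on the backward pass, the gradient of the scalar score
    with respect to that same activation — exactly the two ingredients of
    gradient-weighted class activation mapping.
    """

    def __init__(self, units: list[tuple[str, Layer, bool]]):
        self.units = units
        self.taps: dict[str, np.ndarray] = {}
        self.tap_grads: dict[str, np.ndarray] = {}

    @property
    def tap_names(self) -> list[str]:
        return [name for name, _, is_tap in self.units if is_tap]

    def params(self) -> list[Param]:
        return [p for _, l, _ in self.units for p in l.params()]

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self.taps = {}
        for name, layer, is_tap in self.units:
            x = layer.forward(x, train)
            if is_tap:
                self.taps[name] = x
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.tap_grads = {}
        for name, layer, is_tap in reversed(self.units):
            if is_tap:
                self.tap_grads[name] = g
            g = layer.backward(g)
        return g

    def get_state(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params()]
        for _, l, _ in self.units:
            for bn in _batchnorms(l):
                state.append(bn.running_mean.copy())
                state.append(bn.running_var.copy())
        return state

    def astype(self, dtype) -> None:
        for _, l, _ in self.units:
            cast_layer(l, dtype)

    def set_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, v in zip(ps, state[: len(ps)]):
            p.value[...] = v
        i = len(ps)
        for _, l, _ in self.units:
            for bn in _batchnorms(l):
                bn.running_mean[...] = state[i]
                bn.running_var[...] = state[i + 1]
                i += 2


def _batchnorms(layer: Layer):
    if isinstance(layer, BatchNorm):
        yield layer
    for attr in vars(layer).values() if hasattr(layer, "__dict__") else []:
        if isinstance(attr, Layer):
            yield from _batchnorms(attr)
        elif isinstance(attr, list):
            for a in attr:
                if isinstance(a, Layer):
                    yield from _batchnorms(a)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 clip_norm: float = 5.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        if self.clip_norm:
            norm = np.sqrt(sum(float((p.grad ** 2).sum()) for p in self.params))
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
                for p in self.params:
                    p.grad *= scale
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad ** 2 - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_with_logits(logits: np.ndarray, y: np.ndarray,
                    weights: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Weighted binary cross-entropy on logits; returns (loss, dloss/dlogits).

    With both class weights equal to 1 this is the plain mean BCE.
    """
    z = np.asarray(logits, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    w = np.ones_like(z) if weights is None else np.asarray(weights, float).ravel()
    # log(1 + e^z) computed stably
    softplus = np.maximum(z, 0) + np.log1p(np.exp(-np.abs(z)))
    loss = float(np.mean(w * (softplus - y * z)))
    grad = w * (sigmoid(z) - y) / len(z)
    return loss, grad
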