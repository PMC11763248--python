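"""Edge-based graph network (BC-GCN-SE) for dense structural connectomes.

The connectivity matrix enters as a single-channel ``N x N`` edge-feature
map.  Three graph path convolution (GPC) layers — each mixing, per output
channel, a row aggregate, a column aggregate and the edge's own value, so
that stacking composes information along multi-step paths — are each
followed by a squeeze-and-excitation (SE) channel reweighting.  Edge pooling
(EP) then averages each node's edges into node features, node pooling (NP)
averages nodes into a graph feature vector, and two fully connected layers
produce the single classification logit.

Edge-feature maps keep the full ``N x N`` shape through all three GPC-SE
blocks, which are the tap points for class activation mapping.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._nn import (Adam, BatchNorm, ClassScore, Layer, Linear, Param, ReLU,
                  TapNet, class_sign, sigmoid)
from .atlas import ConnectivityGraph

__all__ = [
    "GraphNetConfig", "GraphNet", "GPCLayer", "SEBlock", "EdgePool", "NodePool",
    "build_graph_net", "predict", "gpc_layer", "se_block", "edge_pool", "node_pool",
]


@dataclass(frozen=True)
class GraphNetConfig:
    n_nodes: int = 132
    gpc_channels: tuple[int, int, int] = (16, 16, 16)
    se_reduction: int = 4
    fc_sizes: tuple[int, int] = (64, 1)
    pooling: str = "mean"  # or "sum"
    se: bool = True
    batch_norm: bool = True
    standardize: bool = True

    def __post_init__(self) -> None:
        if len(self.gpc_channels) != 3:
            raise ValueError("exactly 3 GPC layers required")
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.pooling not in ("mean", "sum"):
            raise ValueError("pooling must be mean or sum")


class GPCLayer(Layer):
    """Graph path convolution on edge-feature maps, ReLU-activated.

    out_o(i,j) = ReLU( sum_c [ alpha_oc * mean_h in_c(i,h)
                             + beta_oc  * mean_h in_c(h,j)
                             + gamma_oc * in_c(i,j) ] + b_o )

    Row and column aggregates extend paths by one hop, so stacked layers see
    progressively higher-order paths; the map stays N x N.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None,
                 relu: bool = True):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (3 * cin))
        self.alpha = Param(rng.normal(0.0, std, size=(cout, cin)))
        self.beta = Param(rng.normal(0.0, std, size=(cout, cin)))
        self.gamma = Param(rng.normal(0.0, std, size=(cout, cin)))
        self.b = Param(np.zeros(cout))
        self.relu = relu

    def params(self):
        return [self.alpha, self.beta, self.gamma, self.b]

    def forward(self, x, train=True):
        if x.ndim != 4 or x.shape[2] != x.shape[3]:
            raise ValueError(f"expected square edge maps (B, C, N, N), got {x.shape}")
        B, C, N, _ = x.shape
        r = x.mean(axis=3)  # (B, C, N) row aggregate
        s = x.mean(axis=2)  # (B, C, N) column aggregate
        pre = (self.gamma.value[None] @ x.reshape(B, C, -1)).reshape(
            B, -1, N, N)
        pre += (self.alpha.value[None] @ r)[:, :, :, None]
        pre += (self.beta.value[None] @ s)[:, :, None, :]
        pre += self.b.value[None, :, None, None]
        if self.relu:
            self._cache = (x, r, s, pre > 0)
            return pre * (pre > 0)
        self._cache = (x, r, s, None)
        return pre

    def backward(self, g):
        x, r, s, mask = self._cache
        B, C, N, _ = x.shape
        gp = g if mask is None else g * mask
        O = gp.shape[1]
        g_row = gp.sum(axis=3)  # (B, O, N)
        g_col = gp.sum(axis=2)  # (B, O, N)
        gp2 = gp.reshape(B, O, -1)
        x2 = x.reshape(B, C, -1)
        self.b.grad += gp.sum(axis=(0, 2, 3))
        self.alpha.grad += (
            g_row.transpose(1, 0, 2).reshape(O, -1)
            @ r.transpose(0, 2, 1).reshape(-1, C))
        self.beta.grad += (
            g_col.transpose(1, 0, 2).reshape(O, -1)
            @ s.transpose(0, 2, 1).reshape(-1, C))
        self.gamma.grad += (
            gp2.transpose(1, 0, 2).reshape(O, -1)
            @ x2.transpose(0, 2, 1).reshape(-1, C))
        dx = (self.gamma.value.T[None] @ gp2).reshape(B, C, N, N)
        dr = self.alpha.value.T[None] @ g_row  # (B, C, N), d/d r_c(i)
        ds = self.beta.value.T[None] @ g_col
        dx += dr[:, :, :, None] / N
        dx += ds[:, :, None, :] / N
        return dx


class SEBlock(Layer):
    """Squeeze-and-excitation over edge-feature channels.

    Squeeze: per-channel mean over all N^2 entries.  Excitation: a two-layer
    bottleneck (reduction r, ReLU, sigmoid) producing a gate in (0,1) per
    channel that rescales the channel.
    """

    def __init__(self, c: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        hidden = max(1, -(-c // reduction))
        self.W1 = Param(rng.normal(0.0, np.sqrt(2.0 / c), size=(c, hidden)))
        self.b1 = Param(np.zeros(hidden))
        self.W2 = Param(rng.normal(0.0, np.sqrt(2.0 / hidden), size=(hidden, c)))
        self.b2 = Param(np.zeros(c))

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, x, train=True):
        B, C, N, _ = x.shape
        z = x.mean(axis=(2, 3))  # (B, C)
        h_pre = z @ self.W1.value + self.b1.value
        h = h_pre * (h_pre > 0)
        gate = sigmoid(h @ self.W2.value + self.b2.value)  # (B, C)
        self._cache = (x, z, h_pre, h, gate)
        return x * gate[:, :, None, None]

    def backward(self, g):
        x, z, h_pre, h, gate = self._cache
        B, C, N, _ = x.shape
        dx = g * gate[:, :, None, None]
        dgate = (g * x).sum(axis=(2, 3))  # (B, C)
        dpre2 = dgate * gate * (1 - gate)
        self.W2.grad += h.T @ dpre2
        self.b2.grad += dpre2.sum(axis=0)
        dh = dpre2 @ self.W2.value.T
        dpre1 = dh * (h_pre > 0)
        self.W1.grad += z.T @ dpre1
        self.b1.grad += dpre1.sum(axis=0)
        dz = dpre1 @ self.W1.value.T
        dx += dz[:, :, None, None] / (N * N)
        return dx


class Identity(Layer):
    def forward(self, x, train=True):
        return x

    def backward(self, g):
        return g


class EdgePool(Layer):
    """Edges -> node features: n_k(i) = mean_j (or sum_j) e_k(i,j)."""

    def __init__(self, mode: str = "mean"):
        self.mode = mode

    def forward(self, x, train=True):
        self._n = x.shape[3]
        out = x.sum(axis=3)
        return out / self._n if self.mode == "mean" else out

    def backward(self, g):
        scale = self._n if self.mode == "mean" else 1
        return np.repeat(g[:, :, :, None], self._n, axis=3) / scale


class NodePool(Layer):
    """Node features -> graph features: v_k = mean_i (or sum_i) n_k(i)."""

    def __init__(self, mode: str = "mean"):
        self.mode = mode

    def forward(self, x, train=True):
        self._n = x.shape[2]
        out = x.sum(axis=2)
        return out / self._n if self.mode == "mean" else out

    def backward(self, g):
        scale = self._n if self.mode == "mean" else 1
        return np.repeat(g[:, :, None], self._n, axis=2) / scale


class GraphNet:
    """The BC-GCN-SE classifier; see module docstring."""

    TAPS = ("block1", "block2", "block3")

    def __init__(self, cfg: GraphNetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        # edge-weight standardization (set from the training set)
        self.input_mean = np.zeros(1)
        self.input_sd = np.ones(1)
        units: list[tuple[str, Layer, bool]] = []
        cin = 1
        for i, cout in enumerate(cfg.gpc_channels, start=1):
            # normalization sits between the linear path convolution and its
            # ReLU, so tapped activation maps stay nonnegative and sparse
            units.append((f"gpc{i}",
                          GPCLayer(cin, cout, rng=rng, relu=not cfg.batch_norm),
                          False))
            if cfg.batch_norm:
                units.append((f"bn{i}", BatchNorm(cout), False))
                units.append((f"relu{i}", ReLU(), False))
            se: Layer = (SEBlock(cout, cfg.se_reduction, rng=rng)
                         if cfg.se else Identity())
            units.append((f"block{i}", se, True))
            cin = cout
        units.append(("edge_pool", EdgePool(cfg.pooling), False))
        units.append(("node_pool", NodePool(cfg.pooling), False))
        if cfg.batch_norm:
            # pooled graph features have tiny between-sample variance;
            # normalizing them stabilizes the decision boundary
            units.append(("bn_np", BatchNorm(cin), False))
        units.append(("fc1", Linear(cin, cfg.fc_sizes[0], rng=rng), False))
        units.append(("fc1_relu", ReLU(), False))
        units.append(("out", Linear(cfg.fc_sizes[0], cfg.fc_sizes[1], rng=rng), False))
        self.net = TapNet(units)

    def set_input_stats(self, mean: float, sd: float) -> None:
        """Fix the edge-weight standardization from training-set statistics."""
        if sd <= 0:
            raise ValueError("sd must be positive")
        self.input_mean = np.array([float(mean)])
        self.input_sd = np.array([float(sd)])

    def fit_input_stats(self, x: np.ndarray) -> None:
        """Derive the standardization from training matrices (off-diagonal)."""
        n = x.shape[-1]
        iu = np.triu_indices(n, k=1)
        edges = x[:, 0][:, iu[0], iu[1]]
        sd = edges.std()
        if sd > 0:
            self.set_input_stats(edges.mean(), sd)

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        if not self.cfg.standardize:
            return x
        mean = x.dtype.type(self.input_mean[0])
        sd = x.dtype.type(self.input_sd[0])
        out = (x - mean) / sd
        n = x.shape[-1]
        out[..., np.arange(n), np.arange(n)] = 0.0  # keep the zero diagonal
        return out

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (B, 1, N, N) -> logits (B,)."""
        self._check_shape(x)
        return self.net.forward(self._standardize(x), train=train)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        # match parameter precision so the whole chain stays in one dtype
        dtype = self.params()[0].value.dtype
        self.net.backward(np.asarray(dlogits, dtype=dtype).reshape(-1, 1))

    def params(self):
        return self.net.params()

    def zero_grad(self):
        self.net.zero_grad()

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.params(), lr=lr)

    def get_state(self):
        return self.net.get_state() + [self.input_mean.copy(), self.input_sd.copy()]

    def set_state(self, state):
        self.net.set_state(state[:-2])
        self.input_mean = state[-2].copy()
        self.input_sd = state[-1].copy()

    def astype(self, dtype):
        self.net.astype(dtype)

    @property
    def tap_names(self) -> list[str]:
        return self.net.tap_names

    def gradcam_taps(self, x: np.ndarray, label: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Activations and class-score gradients at the three GPC-SE blocks."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        batch = x[None]
        self._check_shape(batch)
        self.net.forward(self._standardize(batch), train=False)
        self.net.backward(np.full((1, 1), class_sign(label)))
        return {
            name: (self.net.taps[name][0], self.net.tap_grads[name][0])
            for name in self.tap_names
        }

    def _check_shape(self, x: np.ndarray) -> None:
        n = self.cfg.n_nodes
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2:] != (n, n):
            raise ValueError(f"expected (B, 1, {n}, {n}), got {x.shape}")

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as f:
            pickle.dump({"cfg": self.cfg, "state": self.get_state()}, f)

    @classmethod
    def load(cls, path: str | Path) -> "GraphNet":
        with open(path, "rb") as f:
            blob = pickle.load(f)
        model = cls(blob["cfg"], seed=0)
        model.set_state(blob["state"])
        return model


def build_graph_net(cfg: GraphNetConfig, seed: int = 0) -> GraphNet:
    return GraphNet(cfg, seed=seed)


def predict(model: GraphNet, g: ConnectivityGraph | np.ndarray) -> ClassScore:
    m = g.matrix if isinstance(g, ConnectivityGraph) else np.asarray(g, dtype=float)
    logit = model.forward_logits(m[None, None], train=False)[0]
    return ClassScore(logit=float(logit))


# ---------------------------------------------------------------------------
# functional forms (single sample, explicit parameters)

def gpc_layer(x: np.ndarray, alpha: np.ndarray, beta: np.ndarray,
              gamma: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Functional GPC on a (C, N, N) map with explicit (O, C) parameters."""
    layer = GPCLayer(alpha.shape[1], alpha.shape[0])
    layer.alpha.value[...] = alpha
    layer.beta.value[...] = beta
    layer.gamma.value[...] = gamma
    layer.b.value[...] = b
    return layer.forward(np.asarray(x, dtype=float)[None])[0]


def se_block(x: np.ndarray, W1: np.ndarray, b1: np.ndarray,
             W2: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Functional SE on a (C, N, N) map with explicit bottleneck weights."""
    blk = SEBlock(W1.shape[0], reduction=max(1, W1.shape[0] // max(1, W1.shape[1])))
    blk.W1 = Param(W1)
    blk.b1 = Param(b1)
    blk.W2 = Param(W2)
    blk.b2 = Param(b2)
    return blk.forward(np.asarray(x, dtype=float)[None])[0]


def edge_pool(x: np.ndarray, mode: str = "mean") -> np.ndarray:
    """(C, N, N) edge maps -> (C, N) node features."""
    return EdgePool(mode).forward(np.asarray(x, dtype=float)[None])[0]


def node_pool(x: np.ndarray, mode: str = "mean") -> np.ndarray:
    """(C, N) node features -> (C,) graph features."""
    return NodePool(mode).forward(np.asarray(x, dtype=float)[None])[0]
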