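"""Residual 3D convolutional classifier for T1-weighted-style volumes.

A ResNet-style backbone — a stem convolution followed by four stages of
residual blocks (each block two 3x3x3 convolutions with a shortcut), stages
2-4 halving resolution — topped by the transfer head used for the binary
AD/HC task: global average pooling, two fully connected ReLU layers (128 and
32 units), and a final single-logit output read through a sigmoid.

The outputs of the four stages are registered as tap points: class
activation maps are computed from exactly these four activation sets.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import (
    Adam, BatchNorm, ClassScore, Conv3d, GlobalAvgPool, Linear, ReLU,
    ResidualBlock3d, TapNet, class_sign,
)
from .atlas import VolumeScan

__all__ = ["VolumeNetConfig", "VolumeNet", "build_volume_net", "predict"]

#: stage widths of the full-size backbone and the reduced desk-scale presets
PRESETS = {
    "full": (64, 128, 256, 512),
    "reduced": (8, 16, 32, 64),
    "tiny": (4, 8, 16, 32),
    # flat desk-scale profile: keeps late-stage maps cheap enough to run
    # without downsampling, for high-resolution attribution on small inputs
    "flat": (4, 4, 4, 4),
}

# the stem and stages 2-4 each stride by 2: four halvings per axis
MIN_AXIS = 16


@dataclass(frozen=True)
class VolumeNetConfig:
    stage_channels: tuple[int, int, int, int] = PRESETS["full"]
    blocks_per_stage: int = 2
    input_shape: tuple[int, int, int] = (115, 144, 118)
    fc_sizes: tuple[int, int] = (128, 32)
    stem_stride: int = 2  # backbone stems downsample before stage 1
    stage_strides: tuple[int, int, int, int] = (1, 2, 2, 2)
    standardize: bool = True  # intensity standardization from training stats

    def __post_init__(self) -> None:
        if len(self.stage_channels) != 4:
            raise ValueError("exactly 4 stages required")
        if self.blocks_per_stage < 1:
            raise ValueError("blocks_per_stage must be >= 1")


class VolumeNet:
    """The classifier; see module docstring.  Use :func:`build_volume_net`."""

    TAPS = ("stage1", "stage2", "stage3", "stage4")

    def __init__(self, cfg: VolumeNetConfig, seed: int = 0):
        total_stride = cfg.stem_stride * int(np.prod(cfg.stage_strides))
        if min(cfg.input_shape) < total_stride:
            raise ValueError(
                f"input shape {cfg.input_shape} too small; every axis must be "
                f">= {total_stride} for the configured strides"
            )
        self.cfg = cfg
        self.input_mean = np.zeros(1)
        self.input_sd = np.ones(1)
        rng = np.random.default_rng(seed)
        ch = cfg.stage_channels
        units: list[tuple[str, object, bool]] = []
        units.append(("stem_conv",
                      Conv3d(1, ch[0], k=3, stride=cfg.stem_stride, rng=rng),
                      False))
        units.append(("stem_bn", BatchNorm(ch[0]), False))
        units.append(("stem_relu", ReLU(), False))
        cin = ch[0]
        for i, cout in enumerate(ch):
            stride = cfg.stage_strides[i]
            for b in range(cfg.blocks_per_stage):
                name = f"stage{i + 1}_block{b + 1}"
                blk = ResidualBlock3d(cin, cout, stride=stride if b == 0 else 1,
                                      rng=rng)
                is_tap = b == cfg.blocks_per_stage - 1
                units.append((f"stage{i + 1}" if is_tap else name, blk, is_tap))
                cin = cout
        units.append(("gap", GlobalAvgPool(), False))
        units.append(("fc1", Linear(ch[3], cfg.fc_sizes[0], rng=rng), False))
        units.append(("fc1_relu", ReLU(), False))
        units.append(("fc2", Linear(cfg.fc_sizes[0], cfg.fc_sizes[1], rng=rng), False))
        units.append(("fc2_relu", ReLU(), False))
        units.append(("out", Linear(cfg.fc_sizes[1], 1, rng=rng), False))
        self.net = TapNet(units)

    # -- training-facing API -------------------------------------------------
    def fit_input_stats(self, x: np.ndarray) -> None:
        """Fix intensity standardization from training-set voxel statistics."""
        sd = x.std()
        if sd > 0:
            self.input_mean = np.array([float(x.mean())])
            self.input_sd = np.array([float(sd)])

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        if not self.cfg.standardize:
            return x
        mean = x.dtype.type(self.input_mean[0])
        sd = x.dtype.type(self.input_sd[0])
        return (x - mean) / sd

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (B, 1, X, Y, Z) -> logits (B,)."""
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
        return self.net.get_state() + [self.input_mean.copy(),
                                       self.input_sd.copy()]

    def set_state(self, state):
        self.net.set_state(state[:-2])
        self.input_mean = state[-2].copy()
        self.input_sd = state[-1].copy()

    def astype(self, dtype):
        self.net.astype(dtype)

    # -- attribution-facing API ----------------------------------------------
    @property
    def tap_names(self) -> list[str]:
        return self.net.tap_names

    def gradcam_taps(self, x: np.ndarray, label: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Activations and score gradients at the four stage outputs.

        ``x`` is a single input (1, X, Y, Z) or (X, Y, Z); the score is the
        class score s_c (logit for AD, negated logit for HC).  Uses
        evaluation-mode statistics.
        """
        x = np.asarray(x, dtype=float)
        if x.ndim == 3:
            x = x[None]
        batch = x[None]  # (1, 1, X, Y, Z)
        self._check_shape(batch)
        self.net.forward(self._standardize(batch), train=False)
        self.net.backward(np.full((1, 1), class_sign(label)))
        return {
            name: (self.net.taps[name][0], self.net.tap_grads[name][0])
            for name in self.tap_names
        }

    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError(f"expected (B, 1, X, Y, Z), got {x.shape}")
        if tuple(x.shape[2:]) != tuple(self.cfg.input_shape):
            raise ValueError(
                f"input spatial shape {x.shape[2:]} != configured "
                f"{self.cfg.input_shape}"
            )

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        with open(path, "wb") as f:
            pickle.dump({"cfg": self.cfg, "state": self.get_state()}, f)

    @classmethod
    def load(cls, path: str | Path) -> "VolumeNet":
        with open(path, "rb") as f:
            blob = pickle.load(f)
        model = cls(blob["cfg"], seed=0)
        model.set_state(blob["state"])
        return model


def build_volume_net(cfg: VolumeNetConfig, seed: int = 0) -> VolumeNet:
    """Deterministically initialize a volume classifier from a config."""
    return VolumeNet(cfg, seed=seed)


def predict(model: VolumeNet, v: VolumeScan | np.ndarray) -> ClassScore:
    """Score one preprocessed volume; decision threshold 0.5 on probability."""
    vox = v.voxels if isinstance(v, VolumeScan) else np.asarray(v, dtype=float)
    logit = model.forward_logits(vox[None, None], train=False)[0]
    return ClassScore(logit=float(logit))
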