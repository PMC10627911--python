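"""Truncated 50-layer residual encoder, NumPy forward pass.

Digital-pathology pipelines conventionally embed 256x256 tiles with a
ResNet-50 truncated after its third residual stage (the 1024-channel
stage) followed by global average pooling, giving a 1024-d feature per
tile. This module implements that exact architecture as a pure forward
computation: stem (7x7/2 conv, 3x3/2 max pool) then bottleneck stages of
3, 4 and 6 blocks with channel widths (256, 512, 1024) and a stride-2
transition at each stage boundary.

Weights are user-supplied (``.npz`` mapping parameter names to arrays)
or randomly initialised (He fan-in, seeded); nothing is downloaded.
Batch normalisation runs in inference mode with identity statistics
under random initialisation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["TruncatedResNet50", "FEATURE_DIM"]

FEATURE_DIM = 1024
# (n_blocks, bottleneck width, output channels, first-block stride)
_STAGES = [(3, 64, 256, 1), (4, 128, 512, 2), (6, 256, 1024, 2)]


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """x: (C, H, W); w: (O, C, kh, kw) -> (O, H', W')."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    kh, kw = w.shape[2:]
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]                     # (C, H', W', kh, kw)
    return np.einsum("chwkl,ockl->ohw", win, w, optimize=True)


def _maxpool(x: np.ndarray, k: int = 3, stride: int = 2, pad: int = 1) -> np.ndarray:
    x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    return win[:, ::stride, ::stride].max(axis=(-1, -2))


def _bn(x: np.ndarray, gamma, beta, mean, var, eps: float = 1e-5) -> np.ndarray:
    scale = (gamma / np.sqrt(var + eps))[:, None, None]
    return x * scale + (beta - mean * gamma / np.sqrt(var + eps))[:, None, None]


class TruncatedResNet50:
    """Maps a 256x256x3 uint8/float tile to a 1024-d feature vector."""

    def __init__(self, weights: str | Path | None = None, seed: int = 0):
        if weights is not None:
            path = Path(weights)
            if not path.exists():
                raise FileNotFoundError(
                    f"encoder weights file not found: {path}. Supply a .npz of named "
                    "parameters or pass weights=None for seeded random initialisation."
                )
            self.params = dict(np.load(path))
        else:
            self.params = self._random_init(np.random.default_rng(seed))

    # ------------------------------------------------------------------ init
    @staticmethod
    def _he(rng, o, c, kh, kw):
        fan_in = c * kh * kw
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(o, c, kh, kw)).astype(np.float32)

    def _random_init(self, rng) -> dict[str, np.ndarray]:
        p: dict[str, np.ndarray] = {"stem.conv": self._he(rng, 64, 3, 7, 7)}
        self._add_bn(p, "stem.bn", 64)
        c_in = 64
        for s, (n_blocks, width, c_out, stride) in enumerate(_STAGES, start=1):
            for b in range(n_blocks):
                pre = f"stage{s}.block{b}"
                p[f"{pre}.conv1"] = self._he(rng, width, c_in, 1, 1)
                self._add_bn(p, f"{pre}.bn1", width)
                p[f"{pre}.conv2"] = self._he(rng, width, width, 3, 3)
                self._add_bn(p, f"{pre}.bn2", width)
                p[f"{pre}.conv3"] = self._he(rng, c_out, width, 1, 1)
                self._add_bn(p, f"{pre}.bn3", c_out)
                if b == 0:
                    p[f"{pre}.down"] = self._he(rng, c_out, c_in, 1, 1)
                    self._add_bn(p, f"{pre}.bn_down", c_out)
                c_in = c_out
        return p

    @staticmethod
    def _add_bn(p: dict, name: str, c: int) -> None:
        p[f"{name}.gamma"] = np.ones(c, np.float32)
        p[f"{name}.beta"] = np.zeros(c, np.float32)
        p[f"{name}.mean"] = np.zeros(c, np.float32)
        p[f"{name}.var"] = np.ones(c, np.float32)

    # --------------------------------------------------------------- forward
    def _bn_fw(self, x, name):
        p = self.params
        return _bn(x, p[f"{name}.gamma"], p[f"{name}.beta"], p[f"{name}.mean"], p[f"{name}.var"])

    def _bottleneck(self, x, pre: str, stride: int) -> np.ndarray:
        p = self.params
        out = np.maximum(self._bn_fw(_conv2d(x, p[f"{pre}.conv1"], 1, 0), f"{pre}.bn1"), 0)
        out = np.maximum(self._bn_fw(_conv2d(out, p[f"{pre}.conv2"], stride, 1), f"{pre}.bn2"), 0)
        out = self._bn_fw(_conv2d(out, p[f"{pre}.conv3"], 1, 0), f"{pre}.bn3")
        if f"{pre}.down" in p:
            x = self._bn_fw(_conv2d(x, p[f"{pre}.down"], stride, 0), f"{pre}.bn_down")
        return np.maximum(out + x, 0)

    def encode(self, tile: np.ndarray) -> np.ndarray:
        """Embed one (256, 256, 3) tile; returns a float32 vector of length 1024."""
        if tile.shape != (256, 256, 3):
            raise ValueError(f"expected a (256, 256, 3) tile, got {tile.shape}")
        x = np.ascontiguousarray(tile, dtype=np.float32).transpose(2, 0, 1) / 255.0
        x = np.maximum(self._bn_fw(_conv2d(x, self.params["stem.conv"], 2, 3), "stem.bn"), 0)
        x = _maxpool(x)
        for s, (n_blocks, _width, _c_out, stride) in enumerate(_STAGES, start=1):
            for b in range(n_blocks):
                x = self._bottleneck(x, f"stage{s}.block{b}", stride if b == 0 else 1)
        return x.mean(axis=(1, 2)).astype(np.float32)
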