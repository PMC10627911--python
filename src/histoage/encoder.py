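"""Tile-to-feature encoding behind a pluggable encoder contract.

Two encoders are provided:

``deep``
    The truncated 50-layer residual network (:mod:`histoage.resnet`),
    emitting the conventional 1024-d pathology embedding. Pretrained
    weights are a user-supplied file; by default the architecture runs
    with seeded random initialisation (shape and determinism contracts
    hold regardless of weights).

``toy``
    A fast hand-crafted descriptor for desk-scale experiments: dark-
    puncta fraction, per-channel moments, HSV statistics and an 8-bin
    intensity histogram, zero-padded to the requested width. Feature 0
    (dark-pixel fraction) tracks the puncta density the synthetic image
    cohort uses to encode effective age.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import color

from .resnet import FEATURE_DIM, TruncatedResNet50

__all__ = ["EncoderSpec", "encode_tiles", "toy_encode_tile", "TOY_BASE_DIM",
           "save_features", "load_features"]

TOY_BASE_DIM = 19
DARK_THRESHOLD = 80  # uint8 intensity below which a pixel counts as puncta-dark


@dataclass(frozen=True)
class EncoderSpec:
    name: str = "toy"                      # "toy" | "deep"
    output_dim: int = 32
    deterministic: bool = True
    weights: str | None = None
    seed: int = 0

    def __post_init__(self):
        if self.output_dim <= 0:
            raise ValueError("output dim must be positive")
        if self.name not in ("toy", "deep"):
            raise ValueError(f"unknown encoder {self.name!r}")


def toy_encode_tile(tile: np.ndarray, output_dim: int = 32) -> np.ndarray:
    """Hand-crafted descriptor of a (256, 256, 3) tile."""
    f = np.empty(TOY_BASE_DIM)
    gray = tile.mean(axis=2)
    f[0] = (gray < DARK_THRESHOLD).mean()
    f[1:4] = tile.reshape(-1, 3).mean(axis=0) / 255.0
    f[4:7] = tile.reshape(-1, 3).std(axis=0) / 255.0
    hsv = color.rgb2hsv(tile)
    f[7] = hsv[..., 1].mean()
    f[8] = hsv[..., 1].std()
    f[9] = hsv[..., 2].mean()
    f[10] = hsv[..., 2].std()
    hist, _ = np.histogram(gray, bins=8, range=(0, 255))
    f[11:19] = hist / gray.size
    if output_dim < TOY_BASE_DIM:
        return f[:output_dim]
    out = np.zeros(output_dim)
    out[:TOY_BASE_DIM] = f
    return out


def encode_tiles(tiles: list[np.ndarray] | np.ndarray, spec: EncoderSpec) -> np.ndarray:
    """Stack tile embeddings into X (M, F), preserving tile order."""
    rows = []
    if spec.name == "deep":
        if spec.output_dim != FEATURE_DIM:
            raise ValueError(f"deep encoder emits {FEATURE_DIM}-d features")
        net = TruncatedResNet50(weights=spec.weights, seed=spec.seed)
        encode = net.encode
    else:
        def encode(t):
            return toy_encode_tile(t, spec.output_dim)
    for tile in tiles:
        tile = np.asarray(tile)
        if tile.shape != (256, 256, 3):
            raise ValueError(f"tiles must be (256, 256, 3); got {tile.shape}")
        rows.append(np.asarray(encode(tile), dtype=np.float64))
    if not rows:
        return np.zeros((0, spec.output_dim))
    return np.stack(rows)


def save_features(path: str | Path, X: np.ndarray, coords: np.ndarray,
                  tile_ids: np.ndarray, spec: EncoderSpec) -> None:
    """Per-slide feature archive (compressed) with a JSON sidecar of the spec."""
    path = Path(path)
    np.savez_compressed(path, X=X, coords=coords, tile_ids=tile_ids)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"name": spec.name, "output_dim": spec.output_dim,
         "deterministic": spec.deterministic, "weights": spec.weights}
    ))


def load_features(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    with np.load(Path(path)) as z:
        return z["X"], z["coords"], z["tile_ids"]
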