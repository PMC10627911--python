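"""Tissue segmentation and non-overlapping tile extraction.

Segmentation follows the standard H&E preprocessing recipe: downsample,
convert to HSV, Otsu-threshold the saturation channel (stained tissue is
saturated, glass background is not), then median-filter, close and drop
small components. Tiles are 256-px grid-aligned squares anchored at the
slide origin; a tile is retained when its tissue fraction meets a
threshold. Coordinates are 0-based full-resolution pixels of the tile's
top-left corner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import color, filters, morphology

logger = logging.getLogger(__name__)

TILE_SIZE = 256

__all__ = ["SlideImage", "TissueMask", "TileRecord", "segment_tissue",
           "extract_tiles", "read_slide", "tiles_to_frame", "TILE_SIZE"]


@dataclass
class SlideImage:
    """Full-resolution RGB slide with optional provenance."""

    pixels: np.ndarray                 # (H, W, 3) uint8
    source: str | None = None
    pixel_size_um: float | None = None

    def __post_init__(self):
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("slide must be an RGB (H, W, 3) array")


@dataclass
class TissueMask:
    mask: np.ndarray                   # bool, at segmentation resolution
    scale: int                         # factor back to full resolution

    def __post_init__(self):
        if self.mask.dtype != bool:
            raise ValueError("mask must be boolean")
        if self.scale < 1:
            raise ValueError("scale factor must be >= 1")


@dataclass(frozen=True)
class TileRecord:
    tile_id: int
    x: int                             # top-left, full resolution, 0-based
    y: int
    tissue_frac: float


def read_slide(path: str | Path) -> SlideImage:
    """Read a flat TIFF/PNG slide into memory.

    Pyramidal WSI formats can be supported by passing a pre-extracted
    level array to :class:`SlideImage` directly (plugin contract:
    ``open(path, level) -> array``).
    """
    arr = np.asarray(Image.open(path).convert("RGB"))
    return SlideImage(pixels=arr, source=str(path))


def segment_tissue(
    slide: SlideImage,
    downsample: int = 4,
    median_radius: int = 2,
    closing_radius: int = 2,
    min_area: int = 64,
) -> TissueMask:
    """Otsu saturation thresholding with morphological cleanup.

    A fully uniform image (e.g. blank glass) yields an empty mask rather
    than an error.
    """
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    small = slide.pixels[::downsample, ::downsample]
    sat = color.rgb2hsv(small)[..., 1]
    if np.ptp(sat) < 1e-12:
        return TissueMask(mask=np.zeros(sat.shape, dtype=bool), scale=downsample)
    thresh = filters.threshold_otsu(sat)
    mask = sat > thresh
    mask = filters.median(mask, morphology.disk(median_radius))
    mask = morphology.closing(mask, morphology.disk(closing_radius))
    mask = morphology.remove_small_objects(mask, max_size=min_area - 1)
    return TissueMask(mask=mask.astype(bool), scale=downsample)


def extract_tiles(
    slide: SlideImage,
    mask: TissueMask,
    tile_size: int = TILE_SIZE,
    min_tissue: float = 0.5,
) -> list[TileRecord]:
    """Grid-aligned non-overlapping tiles with tissue fraction >= min_tissue.

    Tiles are enumerated row-major; partial tiles at the right/bottom
    margins are discarded. The tissue fraction is measured on the
    segmentation mask over the tile footprint ``[x, x+tile) x [y, y+tile)``.
    """
    h, w = slide.pixels.shape[:2]
    mh, mw = mask.mask.shape
    if abs(mh * mask.scale - h) >= mask.scale * 2 or abs(mw * mask.scale - w) >= mask.scale * 2:
        raise ValueError("mask and slide are not geometrically consistent")
    n_rows, n_cols = h // tile_size, w // tile_size
    if h % tile_size or w % tile_size:
        logger.info("discarding partial tiles at margins of %dx%d slide", w, h)
    records: list[TileRecord] = []
    tid = 0
    ts = tile_size // mask.scale
    for r in range(n_rows):
        for c in range(n_cols):
            sub = mask.mask[r * ts:(r + 1) * ts, c * ts:(c + 1) * ts]
            frac = float(sub.mean()) if sub.size else 0.0
            if frac >= min_tissue:
                records.append(
                    TileRecord(tile_id=tid, x=c * tile_size, y=r * tile_size,
                               tissue_frac=frac)
                )
                tid += 1
    return records


def tile_pixels(slide: SlideImage, rec: TileRecord, tile_size: int = TILE_SIZE) -> np.ndarray:
    return slide.pixels[rec.y:rec.y + tile_size, rec.x:rec.x + tile_size]


def tiles_to_frame(records: list[TileRecord], slide_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "slide_id": slide_id,
            "tile_id": [r.tile_id for r in records],
            "x": [r.x for r in records],
            "y": [r.y for r in records],
            "tissue_frac": [r.tissue_frac for r in records],
        }
    )
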