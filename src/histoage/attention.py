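"""Attention topography: export, regional aggregation and heatmaps.

All analyses use the *head-mean* attention weight per tile (arithmetic
mean of the post-softmax weights of the two heads); display heatmaps are
min-max normalised per slide, which never reorders regions, while the
statistics always run on the raw softmax weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
import pandas as pd
from PIL import Image
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .prep import TILE_SIZE

__all__ = ["AttentionResult", "tile_region_label", "region_attention_summary",
           "region_comparison", "render_heatmap"]


@dataclass
class AttentionResult:
    slide_id: str
    coords: np.ndarray            # (M, 2)
    head_weights: np.ndarray      # (heads, M) post-softmax

    @property
    def head_mean(self) -> np.ndarray:
        return self.head_weights.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"slide_id": self.slide_id,
                           "tile_id": np.arange(self.coords.shape[0]),
                           "x": self.coords[:, 0], "y": self.coords[:, 1]})
        for h in range(self.head_weights.shape[0]):
            df[f"head{h + 1}"] = self.head_weights[h]
        df["mean"] = self.head_mean
        return df


def tile_region_label(coords: np.ndarray, annotation: np.ndarray,
                      tile_size: int = TILE_SIZE, min_labeled: float = 0.5) -> np.ndarray:
    """Majority pixel label per tile footprint; ties go to the smaller id.

    Label 0 is 'unlabeled'; tiles with more than ``1 - min_labeled`` of
    their pixels unlabeled are assigned -1 (unassigned). The annotation
    must cover the slide extent implied by the coordinates.
    """
    coords = np.asarray(coords)
    h, w = annotation.shape[:2]
    if coords.size and (coords[:, 0].max() + tile_size > w or
                        coords[:, 1].max() + tile_size > h):
        raise ValueError("annotation does not cover the slide extent")
    out = np.empty(coords.shape[0], dtype=np.int64)
    for i, (x, y) in enumerate(coords):
        patch = annotation[y:y + tile_size, x:x + tile_size].ravel()
        counts = np.bincount(patch)
        unlabeled = counts[0] if len(counts) else 0
        if unlabeled > (1 - min_labeled) * patch.size:
            out[i] = -1
            continue
        labeled = counts.copy()
        labeled[0] = 0
        # argmax returns the smallest index among ties — the declared tie rule
        out[i] = int(labeled.argmax())
    return out


def region_attention_summary(results: list[AttentionResult],
                             labels: list[np.ndarray],
                             legend: dict[int, str] | None = None) -> pd.DataFrame:
    """Median head-mean attention per region per slide.

    Regions absent from a slide are simply missing (no zero filling).
    Returns a long table: slide_id, region, median_attention, n_tiles.
    """
    rows = []
    for res, lab in zip(results, labels):
        lab = np.asarray(lab)
        w = res.head_mean
        for region in np.unique(lab[lab >= 0]):
            if legend is not None and region not in legend:
                continue
            sel = lab == region
            rows.append({
                "slide_id": res.slide_id,
                "region": legend[region] if legend else int(region),
                "median_attention": float(np.median(w[sel])),
                "n_tiles": int(sel.sum()),
            })
    return pd.DataFrame(rows)


def region_comparison(medians: pd.DataFrame,
                      region_col: str = "region",
                      value_col: str = "median_attention") -> dict:
    """One-way ANOVA across regions of per-subject medians, plus Tukey HSD.

    Regions contributed by a single subject are dropped with a warning
    entry; returns {"anova_f", "anova_p", "tukey": DataFrame, "dropped"}.
    """
    counts = medians.groupby(region_col)[value_col].count()
    keep = counts[counts >= 2].index
    dropped = sorted(set(counts.index) - set(keep))
    df = medians[medians[region_col].isin(keep)]
    groups = [g[value_col].to_numpy() for _, g in df.groupby(region_col)]
    if len(groups) < 2:
        raise ValueError("need >= 2 regions with >= 2 subjects each")
    if np.ptp(np.concatenate(groups)) == 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = sps.f_oneway(*groups)
    tukey = pairwise_tukeyhsd(df[value_col].to_numpy(),
                              df[region_col].to_numpy().astype(str))
    tukey_df = pd.DataFrame(tukey.summary().data[1:],
                            columns=[str(c) for c in tukey.summary().data[0]])
    return {"anova_f": float(f_stat), "anova_p": float(p), "tukey": tukey_df,
            "dropped": dropped}


def render_heatmap(result: AttentionResult, slide: np.ndarray,
                   tile_size: int = TILE_SIZE, alpha: float = 0.5) -> np.ndarray:
    """Blue-to-red tile heatmap alpha-blended over the slide (uint8 RGB).

    Head-mean weights are min-max normalised per slide for display;
    tiles outside the attention set are left untouched (transparent).
    Output bytes are deterministic for fixed input.
    """
    h, w = slide.shape[:2]
    if result.coords.size and (result.coords[:, 0].max() + tile_size > w or
                               result.coords[:, 1].max() + tile_size > h):
        raise ValueError("tile coordinates fall outside the slide")
    weights = result.head_mean
    span = np.ptp(weights)
    norm = (weights - weights.min()) / span if span > 0 else np.full_like(weights, 0.5)
    cmap = matplotlib.colormaps["coolwarm"]
    out = slide.astype(np.float64).copy()
    for (x, y), v in zip(result.coords, norm):
        rgb = np.array(cmap(float(v))[:3]) * 255.0
        region = out[y:y + tile_size, x:x + tile_size]
        out[y:y + tile_size, x:x + tile_size] = (1 - alpha) * region + alpha * rgb
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def save_heatmap_png(image: np.ndarray, path) -> None:
    Image.fromarray(image).save(path, format="PNG")
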