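"""Synthetic cohorts with the statistical structure of an autopsy WSI study.

Real whole-slide cohorts of aged human hippocampus are not publicly
depositable, so every downstream stage of this package is exercised on
simulated data whose generative process mirrors the modelling
assumptions:

* each subject has a chronological age ``Y`` (uniform over a study range)
  and a latent *acceleration* ``delta`` (truncated Gaussian), giving an
  effective biological age ``Y_eff = Y + delta``;
* a grid of tiles per subject carries region labels (signal / context /
  background; or pseudo-stained white matter / gray matter /
  leptomeninges in image mode);
* tiles in the signal region encode ``Y_eff`` in the first
  ``N_SIGNAL_DIMS`` feature dimensions through the affine readout
  ``g(Y_eff) = G_SLOPE * (Y_eff - G_CENTER)``, plus Gaussian noise;
  all other tiles are pure noise;
* with ``context_coupling`` on, a signal tile expresses the full mean
  only when at least one of its 8 grid neighbours is context-labelled
  (otherwise attenuated by ``CONTEXT_GATE``) — a task where spatial
  message passing provably helps and tile-wise models partially fail;
* clinical covariates (binary, continuous, ordinal) are drawn with
  declared effect sizes per standard deviation of ``delta``.

The generator is fully seeded: identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SimConfig",
    "SimTruth",
    "FeatureBag",
    "simulate_feature_cohort",
    "simulate_image_cohort",
    "G_SLOPE",
    "G_CENTER",
    "N_SIGNAL_DIMS",
    "CONTEXT_DIM",
    "CONTEXT_GATE",
    "signal_readout",
    "TISSUE_LEGEND",
]

# affine map from effective age to signal-tile feature mean
G_SLOPE = 0.05
G_CENTER = 50.0
N_SIGNAL_DIMS = 4          # feature dims 0..3 carry the age signal
CONTEXT_DIM = 4            # feature dim 4 flags context-region tiles
CONTEXT_GATE = 0.1         # attenuation of un-coupled signal tiles

TILE = 256

# image-mode pseudo-stain palette (RGB) and label legend
TISSUE_LEGEND = {0: "background", 1: "leptomeninges", 2: "gray_matter", 3: "white_matter"}
_TISSUE_RGB = {
    0: (255, 255, 255),
    1: (225, 195, 225),   # pale violet rim
    2: (240, 175, 190),   # eosinophilic pink
    3: (185, 200, 235),   # myelin blue
}
_PUNCTA_RGB = (45, 30, 30)
PUNCTA_DENSITY_PER_PX_PER_YEAR = 1.2e-5  # Poisson rate of dark puncta in signal region


def signal_readout(effective_age: np.ndarray | float) -> np.ndarray | float:
    """Mean of the signal feature dimensions at a given effective age."""
    return G_SLOPE * (np.asarray(effective_age, dtype=float) - G_CENTER)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated cohort (ages in years)."""

    n_subjects: int = 200
    age_range: tuple[float, float] = (51.0, 108.0)
    accel_sd: float = 5.0
    noise_sd: float = 1.0
    grid_shape: tuple[int, int] = (10, 10)
    signal_region_fraction: float = 0.3
    context_region_fraction: float = 0.1
    context_coupling: bool = False
    feature_dim: int = 64
    covariate_effects: tuple[tuple[str, str, float], ...] = (
        ("impairment", "binary", 0.5),
        ("nft_density", "continuous", 0.5),
        ("braak", "ordinal", 0.5),
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must satisfy low < high")
        if not 0 < self.signal_region_fraction < 1:
            raise ValueError("signal_region_fraction must lie in (0, 1)")
        if self.accel_sd < 0:
            raise ValueError("accel_sd must be >= 0")
        if self.feature_dim < N_SIGNAL_DIMS + 1:
            raise ValueError(
                f"feature_dim must be >= {N_SIGNAL_DIMS + 1} "
                "(signal dims + context indicator)"
            )


@dataclass
class FeatureBag:
    """Per-slide bag of tile features, ready for graph construction."""

    slide_id: str
    X: np.ndarray          # (M, F)
    coords: np.ndarray     # (M, 2) top-left pixel coords
    age: float


@dataclass
class SimTruth:
    """Ground truth retained for recovery tests."""

    subjects: pd.DataFrame            # id, age, accel, effective_age, covariates
    tile_labels: np.ndarray           # (n_subjects, M) region label per tile
    coords: np.ndarray                # (M, 2) shared grid coords
    legend: dict = field(default_factory=lambda: {0: "background", 1: "signal", 2: "context"})


def _draw_subjects(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = cfg.age_range
    age = rng.uniform(lo, hi, size=cfg.n_subjects)
    # truncated so the effective age stays within 10 y of the study range
    delta = np.zeros(cfg.n_subjects)
    if cfg.accel_sd > 0:
        for i in range(cfg.n_subjects):
            while True:
                d = rng.normal(0.0, cfg.accel_sd)
                if lo - 10.0 <= age[i] + d <= hi + 10.0:
                    delta[i] = d
                    break
    eff = age + delta
    df = pd.DataFrame(
        {
            "id": [f"s{i:04d}" for i in range(cfg.n_subjects)],
            "age": age,
            "accel": delta,
            "effective_age": eff,
            "sex": rng.integers(0, 2, size=cfg.n_subjects),
        }
    )
    dstd = delta / cfg.accel_sd if cfg.accel_sd > 0 else np.zeros_like(delta)
    for name, kind, effect in cfg.covariate_effects:
        if kind == "binary":
            p = 1.0 / (1.0 + np.exp(-(effect * dstd)))
            df[name] = (rng.uniform(size=cfg.n_subjects) < p).astype(int)
        elif kind == "continuous":
            df[name] = effect * dstd + rng.normal(0.0, 1.0, size=cfg.n_subjects)
        elif kind == "ordinal":
            latent = effect * dstd + rng.logistic(0.0, 1.0, size=cfg.n_subjects)
            cuts = np.quantile(latent, [0.25, 0.5, 0.75])
            df[name] = np.searchsorted(cuts, latent)
        else:
            raise ValueError(f"unknown covariate type {kind!r}")
    return df


def _region_layout(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Random tile labels: 1 = signal, 2 = context, 0 = background."""
    rows, cols = cfg.grid_shape
    m = rows * cols
    labels = np.zeros(m, dtype=np.int64)
    n_sig = max(1, round(cfg.signal_region_fraction * m))
    n_ctx = max(1, round(cfg.context_region_fraction * m))
    perm = rng.permutation(m)
    labels[perm[:n_sig]] = 1
    labels[perm[n_sig:n_sig + n_ctx]] = 2
    return labels.reshape(rows, cols)


def _context_adjacent(labels2d: np.ndarray) -> np.ndarray:
    """Boolean grid: tile has >= 1 context-labelled tile among 8 neighbours."""
    ctx = (labels2d == 2)
    padded = np.pad(ctx, 1)
    acc = np.zeros_like(ctx, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            acc |= padded[1 + dr:1 + dr + ctx.shape[0], 1 + dc:1 + dc + ctx.shape[1]]
    return acc


def _grid_coords(grid_shape: tuple[int, int]) -> np.ndarray:
    rows, cols = grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.stack([cc.ravel() * TILE, rr.ravel() * TILE], axis=1).astype(np.int64)


def simulate_feature_cohort(cfg: SimConfig) -> tuple[list[FeatureBag], pd.DataFrame, SimTruth]:
    """Generate tile-feature bags, a subject table and the ground truth.

    Returns
    -------
    bags : list of FeatureBag, one per subject (row-major tile order)
    subjects : DataFrame with id, age, sex and covariate columns
    truth : SimTruth with accelerations and tile region labels
    """
    rng = np.random.default_rng(cfg.seed)
    subjects = _draw_subjects(cfg, rng)
    coords = _grid_coords(cfg.grid_shape)
    m = coords.shape[0]

    bags: list[FeatureBag] = []
    all_labels = np.zeros((cfg.n_subjects, m), dtype=np.int64)
    for i in range(cfg.n_subjects):
        labels2d = _region_layout(cfg, rng)
        labels = labels2d.ravel()
        all_labels[i] = labels
        X = rng.normal(0.0, 1.0, size=(m, cfg.feature_dim)) * cfg.noise_sd
        gate = np.ones(m)
        if cfg.context_coupling:
            coupled = _context_adjacent(labels2d).ravel()
            gate = np.where(coupled, 1.0, CONTEXT_GATE)
        sig = labels == 1
        mean = signal_readout(subjects["effective_age"].iloc[i])
        X[sig, :N_SIGNAL_DIMS] += (gate[sig] * mean)[:, None]
        X[labels == 2, CONTEXT_DIM] += 1.0
        bags.append(
            FeatureBag(
                slide_id=subjects["id"].iloc[i],
                X=X,
                coords=coords.copy(),
                age=float(subjects["age"].iloc[i]),
            )
        )
    truth = SimTruth(subjects=subjects, tile_labels=all_labels, coords=coords)
    record = subjects.drop(columns=["accel", "effective_age"])
    return bags, record, truth


# --------------------------------------------------------------------- images
def _ellipse_mask(shape: tuple[int, int], center, radii) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - center[0]) / radii[0]) ** 2 + ((xx - center[1]) / radii[1]) ** 2 <= 1.0


def _tissue_label_map(shape: tuple[int, int]) -> np.ndarray:
    """Nested-ellipse anatomy: rim of leptomeninges, gray-matter band, white-matter core."""
    h, w = shape
    center = (h / 2.0, w / 2.0)
    outer = (0.44 * h, 0.44 * w)
    labels = np.zeros(shape, dtype=np.uint8)
    labels[_ellipse_mask(shape, center, outer)] = 1
    labels[_ellipse_mask(shape, center, (outer[0] - 20, outer[1] - 20))] = 2
    labels[_ellipse_mask(shape, center, (0.58 * outer[0], 0.58 * outer[1]))] = 3
    return labels


def simulate_image_cohort(
    cfg: SimConfig,
) -> tuple[list[np.ndarray], list[np.ndarray], pd.DataFrame, SimTruth]:
    """Generate pseudo-stained slide images plus pixel-level annotation masks.

    Each slide is a white canvas of ``grid_shape * 256`` pixels carrying a
    nested-ellipse tissue blob (leptomeningeal rim, gray-matter band,
    white-matter core). Dark puncta are scattered in the white-matter core
    with Poisson intensity proportional to the subject's effective age —
    the image-domain analogue of the feature-space age signal. Puncta are
    placed on an 8-px lattice so they never merge, keeping the count
    recoverable by connected-component analysis, and are drawn by inverse
    transform from a layout-shared uniform so the count is monotone in
    effective age at a fixed seed.

    Returns (images, masks, subjects, truth); images are uint8 RGB arrays,
    masks uint8 label arrays over :data:`TISSUE_LEGEND`.
    """
    rows, cols = cfg.grid_shape
    h, w = rows * TILE, cols * TILE
    if min(h, w) < 512:
        raise ValueError("canvas too small to contain the requested regions (min 512 px)")
    if h * w > 4096 ** 2:
        raise ValueError("canvas exceeds the desk-scale limit of 4096^2 px")
    rng = np.random.default_rng(cfg.seed)
    subjects = _draw_subjects(cfg, rng)

    label_map = _tissue_label_map((h, w))
    signal = label_map == 3
    # collision-free candidate sites on an 8-px lattice inside the core
    ys, xs = np.nonzero(signal)
    lattice = (ys % 8 == 4) & (xs % 8 == 4)
    sites = np.stack([ys[lattice], xs[lattice]], axis=1)
    inner = (
        _ellipse_mask((5, 5), (2, 2), (2.6, 2.6))  # disk stamp, radius 2
    )
    sy, sx = np.nonzero(inner)
    sy, sx = sy - 2, sx - 2

    base = np.zeros((h, w, 3), dtype=np.uint8)
    for lab, rgb in _TISSUE_RGB.items():
        base[label_map == lab] = rgb

    images: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    m = rows * cols
    all_labels = np.zeros((cfg.n_subjects, m), dtype=np.int64)
    coords = _grid_coords(cfg.grid_shape)
    lam_area = PUNCTA_DENSITY_PER_PX_PER_YEAR * signal.sum()
    for i in range(cfg.n_subjects):
        img = base.copy()
        u = rng.uniform()
        order = rng.permutation(len(sites))
        lam = lam_area * max(subjects["effective_age"].iloc[i], 0.0)
        count = int(sps.poisson.ppf(u, lam)) if lam > 0 else 0
        count = min(count, len(sites))
        for y, x in sites[order[:count]]:
            img[y + sy, x + sx] = _PUNCTA_RGB
        images.append(img)
        masks.append(label_map.copy())
        # tile-level majority label for truth bookkeeping
        tl = label_map.reshape(rows, TILE, cols, TILE).transpose(0, 2, 1, 3)
        flat = tl.reshape(m, -1)
        all_labels[i] = np.array(
            [np.bincount(t, minlength=4).argmax() for t in flat]
        )
    truth = SimTruth(
        subjects=subjects, tile_labels=all_labels, coords=coords, legend=dict(TISSUE_LEGEND)
    )
    record = subjects.drop(columns=["accel", "effective_age"])
    return images, masks, record, truth


def sparse_signal_config(**overrides) -> SimConfig:
    """Cohort where only a few tiles per slide carry signal (attention stress test)."""
    base = SimConfig(signal_region_fraction=0.05, context_region_fraction=0.05)
    return replace(base, **overrides)


def context_coupled_config(**overrides) -> SimConfig:
    """Cohort where signal expression depends on spatial adjacency to context tissue."""
    base = SimConfig(context_coupling=True)
    return replace(base, **overrides)


def write_truth(truth: SimTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.subjects.to_csv(out / "truth_subjects.csv", index=False)
    pd.DataFrame(
        truth.tile_labels,
        index=truth.subjects["id"],
        columns=[f"tile{j}" for j in range(truth.tile_labels.shape[1])],
    ).to_csv(out / "truth_tile_labels.csv")
    (out / "legend.json").write_text(json.dumps({str(k): v for k, v in truth.legend.items()}))
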