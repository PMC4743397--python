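"""Seeded synthetic whole-slide cervical cell images with block ground truth.

No clinical imagery ships with this package, so every pipeline stage is
exercised on synthetic 800×1000 renders built from the six block phenotypes
seen on H&E-stained slides:

* ``background`` — bare glass: near-uniform bright pink-white, fine sensor
  noise, a slow illumination ramp.
* ``few_white`` / ``many_white`` / ``clustered_white`` — leukocytes: small,
  very dark round nuclei (gray below ~50) at increasing density, scattered
  or clustered, on a mottled mucus/cytoplasm wash.
* ``normal`` — normal epithelial cells: large pale cytoplasm discs with
  small, regular, lightly stained nuclei (gray ≈ 100–125).
* ``suspicious`` — abnormal epithelial cells: enlarged, darker,
  boundary-perturbed nuclei (gray ≈ 50–100, the epithelial nuclear interval
  that drives the R4 ratio) with coarse chromatin texture and a high
  nuclear-to-block area fraction, on a denser cytoplasm wash.

Only ``suspicious`` maps to the abnormal class; every other non-background
phenotype is normal.  All pixels are a deterministic function of the seed.
The renders are a synthetic stand-in — they reproduce the *contrasts* the
screen relies on, not clinical appearance (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image_prep import BACKGROUND, WorkingImage, from_array

PHENOTYPES = ("background", "few_white", "many_white", "clustered_white", "normal", "suspicious")

#: Mix of a generic test slide: about half bare glass, ~4 % suspicious.
DEFAULT_MIX: dict[str, float] = {
    "background": 0.49,
    "few_white": 0.17,
    "many_white": 0.10,
    "clustered_white": 0.08,
    "normal": 0.12,
    "suspicious": 0.04,
}

#: Mix used for training slides: curated non-background fields of view with
#: roughly a 10:1 normal:suspicious imbalance (≈100 suspicious blocks in a
#: 1120-block training set).
TRAIN_MIX: dict[str, float] = {
    "background": 0.0,
    "few_white": 0.35,
    "many_white": 0.20,
    "clustered_white": 0.15,
    "normal": 0.21,
    "suspicious": 0.09,
}

# Stain colors (RGB).  Gray values: white-cell nucleus ≈ 38 (< 50),
# suspicious nuclear chromatin ≈ 74–84 (in [50, 100)), normal epithelial
# nucleus and leukocyte cytoplasm rim ≈ 112 (in [100, 125)), so the
# R3/R4 nuclear gray intervals separate as on real H&E material; the
# corresponding intensities fall in [0, 0.2), [0.2, 0.4) and [0.4, 0.5).
_BG_RGB = (236.0, 224.0, 229.0)
_WHITE_NUCLEUS_RGB = (40.0, 28.0, 72.0)
_NORMAL_CYTO_RGB = (206.0, 174.0, 196.0)
_NORMAL_NUCLEUS_RGB = (120.0, 100.0, 160.0)
_SUSP_CYTO_RGB = (160.0, 138.0, 134.0)
_SUSP_GRANULE_RGB = (98.0, 74.0, 123.0)
_SUSP_NUCLEUS_RGB = (82.0, 62.0, 112.0)

#: Per-phenotype rendering parameters (ranges are inclusive low/high).
DEFAULT_PHENOTYPE_PARAMS: dict[str, dict] = {
    "few_white": {"n_cells": (1, 2), "nucleus_radius": (2.5, 3.5), "alpha": 0.6},
    "many_white": {"n_cells": (4, 7), "nucleus_radius": (2.5, 3.5), "alpha": 0.6},
    "clustered_white": {"n_cells": (5, 9), "nucleus_radius": (2.5, 3.5), "alpha": 0.6,
                        "cluster_sigma": 9.0},
    "normal": {"n_cells": (1, 3), "cyto_radius": (26.0, 40.0), "nucleus_radius": (5.0, 7.0)},
    "suspicious": {
        "n_nuclei": (1, 2),
        "nucleus_radius": (8.5, 10.5),
        "irregularity": 0.18,
        "n_granules": (15, 20),
        "granule_radius": (3.5, 5.0),
        "granule_blur": 0.0,
        "cyto_mottle_amp": 0.0,
        "cyto_mottle_sigma": 2.5,
        "cyto_dither_amp": 14.0,
        "cyto_dither_sigma": 1.5,
    },
    # Mucus/cytoplasm wash over non-background blocks: a patchy, smoothly
    # mottled stain film covering ~80 % of the tile, the rest staying bare
    # glass.  The washed part carries the smooth gradients that put the
    # RIU-LBP peak of cell-bearing tiles in bin 5; the glass patches keep
    # the tie-heavy near-255 codes that real non-background blocks retain.
    "wash": {"coverage": 0.7, "coverage_sigma": 6.0, "depth": 36.0,
             "mottle_amp": 31.0, "mottle_sigma": 6.25},
}


@dataclass
class SyntheticSpec:
    """Everything that determines a synthetic slide's pixels."""

    seed: int = 0
    grid: tuple[int, int] = (8, 10)
    block_size: int = 100
    phenotype_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIX))
    noise_sigma: float = 0.6            # additive Gaussian noise, 8-bit levels
    illumination_amplitude: float = 6.0  # peak-to-center ramp, 8-bit levels
    meso_amplitude: float = 4.5         # slow within-block shading field, 8-bit levels
    meso_sigma: float = 25.0            # correlation scale of that field, px
    background_rgb: tuple[float, float, float] = _BG_RGB
    cell_overflow: float = 0.0          # fraction of nucleus radius allowed past block edges
    phenotype_params: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PHENOTYPE_PARAMS.items()}
    )

    def validate(self) -> None:
        mix = self.phenotype_mix
        if set(mix) - set(PHENOTYPES):
            raise ValueError(f"unknown phenotypes in mix: {set(mix) - set(PHENOTYPES)}")
        probs = np.array([mix.get(p, 0.0) for p in PHENOTYPES])
        if (probs < 0).any():
            raise ValueError("phenotype proportions must be nonnegative")
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError(f"phenotype mix must sum to 1, got {probs.sum():.4f}")


@dataclass
class GroundTruth:
    """Per-block truth of one synthetic image."""

    phenotypes: np.ndarray        # (rows, cols) of str
    labels: np.ndarray            # (rows, cols): +1 normal, −1 suspicious, 0 background
    cell_fractions: np.ndarray    # (rows, cols): largest suspicious-cell area fraction

    def label_tag(self, row: int, col: int) -> str:
        lab = self.labels[row, col]
        return BACKGROUND if lab == 0 else ("suspicious" if lab == -1 else "normal")


# --- rendering primitives ---------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape, sigma: float, amplitude: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    s = f.std()
    return f * (amplitude / s) if s > 0 else f


def _disk_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    rng: np.random.Generator | None = None,
    irregularity: float = 0.0,
) -> np.ndarray:
    """Anti-aliased filled disc, optionally with a low-frequency perturbed
    boundary (harmonics 2–5 of amplitude ``irregularity``·radius)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - center[0], xx - center[1]
    r = np.hypot(dy, dx)
    boundary = np.full(shape, radius)
    if irregularity > 0 and rng is not None:
        theta = np.arctan2(dy, dx)
        for k in range(2, 6):
            amp = irregularity * radius * rng.uniform(0.2, 0.5)
            boundary = boundary + amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    return np.clip(boundary - r + 0.5, 0.0, 1.0)


def _paint(canvas: np.ndarray, mask: np.ndarray, color) -> None:
    for c in range(3):
        canvas[..., c] = canvas[..., c] * (1 - mask) + color[c] * mask


#: Eosin-weighted subtractive channel weights: strongest in G, weakest in
#: R, so stain films read pink and modulate gray by ~0.8 of the field.
_EOSIN_W = (0.45, 1.0, 0.6)


def _add_mottle(canvas: np.ndarray, rng: np.random.Generator, amp: float, sigma: float) -> None:
    f = _smooth_field(rng, canvas.shape[:2], sigma, amp)
    for c, w in enumerate(_EOSIN_W):
        canvas[..., c] -= w * f


def _add_wash(canvas: np.ndarray, rng: np.random.Generator, params: dict) -> None:
    """Patchy stain film: a soft-edged coverage mask times (depth + mottle)."""
    shape = canvas.shape[:2]
    cover = _smooth_field(rng, shape, params["coverage_sigma"], 1.0)
    threshold = np.quantile(cover, 1.0 - params["coverage"])
    mask = np.clip((cover - threshold) / 0.3, 0.0, 1.0)   # soft 0→1 edge
    film = params["depth"] + _smooth_field(rng, shape, params["mottle_sigma"], params["mottle_amp"])
    for c, w in enumerate(_EOSIN_W):
        canvas[..., c] -= w * film * mask


def _uniform_int(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def _place(rng: np.random.Generator, size: int, margin: float) -> float:
    lo, hi = margin, size - margin
    if hi <= lo:
        return size / 2.0
    return float(rng.uniform(lo, hi))


# --- phenotype painters -----------------------------------------------------

def _paint_white_cells(block: np.ndarray, rng: np.random.Generator, params: dict, clustered: bool) -> None:
    n = _uniform_int(rng, params["n_cells"])
    size = block.shape[0]
    if clustered:
        cy = rng.uniform(0.3 * size, 0.7 * size)
        cx = rng.uniform(0.3 * size, 0.7 * size)
    for _ in range(n):
        radius = rng.uniform(*params["nucleus_radius"])
        if clustered:
            y = float(np.clip(rng.normal(cy, params["cluster_sigma"]), radius + 1, size - radius - 1))
            x = float(np.clip(rng.normal(cx, params["cluster_sigma"]), radius + 1, size - radius - 1))
        else:
            y, x = _place(rng, size, radius + 1), _place(rng, size, radius + 1)
        # Partial opacity: at this working resolution leukocyte nuclei read
        # as small translucent dark dots whose stained gray lands in the
        # 100–125 band rather than fully saturated ink.
        mask = _disk_mask(block.shape[:2], (y, x), radius, rng, irregularity=0.06)
        _paint(block, mask * params.get("alpha", 0.6), _WHITE_NUCLEUS_RGB)


def _paint_normal_cells(block: np.ndarray, rng: np.random.Generator, params: dict) -> None:
    n = _uniform_int(rng, params["n_cells"])
    size = block.shape[0]
    for _ in range(n):
        cyto_r = rng.uniform(*params["cyto_radius"])
        y, x = _place(rng, size, cyto_r * 0.6), _place(rng, size, cyto_r * 0.6)
        cyto = _disk_mask(block.shape[:2], (y, x), cyto_r, rng, irregularity=0.08)
        _paint(block, cyto * 0.85, _NORMAL_CYTO_RGB)
        nuc_r = rng.uniform(*params["nucleus_radius"])
        mask = _disk_mask(block.shape[:2], (y, x), nuc_r, rng, irregularity=0.05)
        _paint(block, mask, _NORMAL_NUCLEUS_RGB)


def _paint_suspicious(block: np.ndarray, rng: np.random.Generator, params: dict, overflow: float) -> float:
    """Paint one suspicious block; returns the largest cell-area fraction
    lying inside the block (1.0 unless ``overflow`` lets nuclei straddle)."""
    size = block.shape[0]
    # Dense abnormal cell material covers essentially the whole block:
    # hyperchromatic cytoplasm with little bare glass, so the histogram is
    # concentrated in a narrow mid-dark range.
    cyto = _disk_mask(block.shape[:2], (size / 2, size / 2), size * 0.9, rng, irregularity=0.05)
    _paint(block, cyto, _SUSP_CYTO_RGB)
    if params.get("cyto_mottle_amp", 0) > 0:
        _add_mottle(block, rng, params["cyto_mottle_amp"], params.get("cyto_mottle_sigma", 2.5))
    if params.get("cyto_dither_amp", 0) > 0:
        # Fine-grained stain dither at the co-occurrence displacement scale.
        _add_mottle(block, rng, params["cyto_dither_amp"], params.get("cyto_dither_sigma", 1.0))

    # Coarse chromatin granules scattered through the cell material: the
    # fine two-tone texture that separates the co-occurrence statistics of
    # abnormal blocks from the smooth mucus wash of normal ones.
    granules = np.zeros(block.shape[:2])
    for _ in range(_uniform_int(rng, params["n_granules"])):
        radius = rng.uniform(*params["granule_radius"])
        y, x = _place(rng, size, radius), _place(rng, size, radius)
        np.maximum(granules, _disk_mask(block.shape[:2], (y, x), radius), out=granules)
    if params.get("granule_blur", 0) > 0:
        granules = gaussian_filter(granules, params["granule_blur"])
    _paint(block, granules, _SUSP_GRANULE_RGB)

    max_fraction = 0.0
    n = _uniform_int(rng, params["n_nuclei"])
    for _ in range(n):
        radius = rng.uniform(*params["nucleus_radius"])
        reach = radius * (1 + 2.5 * params["irregularity"])
        margin = reach * (1.0 - overflow)
        y, x = _place(rng, size, margin), _place(rng, size, margin)
        # Render on a local canvas large enough for the full nucleus so the
        # area fraction inside the block is known even when it straddles.
        pad = int(np.ceil(reach)) + 2
        local_shape = (size + 2 * pad, size + 2 * pad)
        mask_full = _disk_mask(local_shape, (y + pad, x + pad), radius, rng, irregularity=params["irregularity"])
        mask = mask_full[pad : pad + size, pad : pad + size]
        fraction = float(mask.sum() / max(mask_full.sum(), 1e-9))
        max_fraction = max(max_fraction, fraction)
        _paint(block, mask, _SUSP_NUCLEUS_RGB)
    return max_fraction


# --- image and dataset generation ------------------------------------------

def generate_image(spec: SyntheticSpec) -> tuple[WorkingImage, GroundTruth]:
    """Render one synthetic slide; all pixels are determined by ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_rows, n_cols = spec.grid
    bs = spec.block_size
    shape = (n_rows * bs, n_cols * bs)

    canvas = np.empty(shape + (3,), dtype=float)
    for c in range(3):
        canvas[..., c] = spec.background_rgb[c]

    # Slow illumination ramp in a random direction.
    phi = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    ramp = (np.cos(phi) * xx / shape[1] + np.sin(phi) * yy / shape[0]) * 2 - (np.cos(phi) + np.sin(phi))
    canvas += (spec.illumination_amplitude * ramp / 2)[..., None]
    # Slow stain shading at the sub-block scale (mounting-medium unevenness
    # over cell-bearing regions): spreads the within-block gray histogram of
    # glass patches over a handful of bins while leaving quantized
    # co-occurrence levels essentially intact.  Bare background blocks stay
    # optically flat, so it is added per non-background block below.
    meso = (
        _smooth_field(rng, shape, spec.meso_sigma, spec.meso_amplitude)
        if spec.meso_amplitude > 0
        else None
    )

    probs = np.array([spec.phenotype_mix.get(p, 0.0) for p in PHENOTYPES])
    phenotypes = np.array(
        [rng.choice(PHENOTYPES, p=probs) for _ in range(n_rows * n_cols)], dtype=object
    ).reshape(n_rows, n_cols)

    labels = np.zeros((n_rows, n_cols), dtype=int)
    fractions = np.zeros((n_rows, n_cols))
    wash = spec.phenotype_params["wash"]

    for i in range(n_rows):
        for j in range(n_cols):
            phen = phenotypes[i, j]
            block = canvas[i * bs : (i + 1) * bs, j * bs : (j + 1) * bs]
            if phen == "background":
                continue
            if meso is not None:
                block += meso[i * bs : (i + 1) * bs, j * bs : (j + 1) * bs, None]
            if phen != "suspicious":
                _add_wash(block, rng, wash)
            if phen in ("few_white", "many_white", "clustered_white"):
                _paint_white_cells(block, rng, spec.phenotype_params[phen], clustered=phen == "clustered_white")
                labels[i, j] = 1
            elif phen == "normal":
                _paint_normal_cells(block, rng, spec.phenotype_params[phen])
                labels[i, j] = 1
            else:  # suspicious
                frac = _paint_suspicious(block, rng, spec.phenotype_params[phen], spec.cell_overflow)
                fractions[i, j] = frac
                # >50 %-of-cell-area rule: the block carries the abnormal
                # label only if more than half of some abnormal cell lies in it.
                labels[i, j] = -1 if frac > 0.5 else 1

    canvas += rng.normal(0.0, spec.noise_sigma, canvas.shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    image = from_array(pixels, source=f"synthetic(seed={spec.seed})")
    return image, GroundTruth(phenotypes=phenotypes, labels=labels, cell_fractions=fractions)


@dataclass
class SyntheticDataset:
    train: list[tuple[WorkingImage, GroundTruth]]
    test: list[tuple[WorkingImage, GroundTruth]]
    manifest: pd.DataFrame
    train_seeds: list[int]
    test_seeds: list[int]


def _child_seeds(master_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def generate_dataset(
    n_train_images: int = 14,
    n_test_images: int = 12,
    spec: SyntheticSpec | None = None,
    train_mix: dict[str, float] | None = None,
    test_mix: dict[str, float] | None = None,
) -> SyntheticDataset:
    """Generate a training/testing split of synthetic slides.

    Defaults emulate the study design this package targets: ~1100
    non-background training blocks with ~100 suspicious (14 curated
    80-block fields of view), and 12 ordinary test slides of 80 blocks,
    about half background, with ~40 suspicious blocks among the ~490
    non-background ones.  Each image gets its own child seed derived from
    the master seed, recorded in the manifest, so any slide can be
    regenerated in isolation.
    """
    if n_train_images < 1 or n_test_images < 1:
        raise ValueError("need at least one image per split")
    spec = spec if spec is not None else SyntheticSpec()
    train_mix = train_mix if train_mix is not None else dict(TRAIN_MIX)
    test_mix = test_mix if test_mix is not None else dict(spec.phenotype_mix)

    seeds = _child_seeds(spec.seed, n_train_images + n_test_images)
    train_seeds, test_seeds = seeds[:n_train_images], seeds[n_train_images:]

    rows, train, test = [], [], []
    for split, seed_list, mix, bucket in (
        ("train", train_seeds, train_mix, train),
        ("test", test_seeds, test_mix, test),
    ):
        for idx, child in enumerate(seed_list):
            img_spec = replace(spec, seed=child, phenotype_mix=dict(mix))
            image, truth = generate_image(img_spec)
            bucket.append((image, truth))
            image_id = f"{split}_{idx:03d}"
            for i in range(spec.grid[0]):
                for j in range(spec.grid[1]):
                    rows.append(
                        {
                            "split": split,
                            "image_id": image_id,
                            "image_seed": child,
                            "row": i,
                            "col": j,
                            "phenotype": truth.phenotypes[i, j],
                            "label": int(truth.labels[i, j]),
                            "max_cell_fraction": float(truth.cell_fractions[i, j]),
                        }
                    )
    return SyntheticDataset(
        train=train, test=test, manifest=pd.DataFrame(rows),
        train_seeds=train_seeds, test_seeds=test_seeds,
    )
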