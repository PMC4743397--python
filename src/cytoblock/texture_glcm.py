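"""Gray-level co-occurrence matrices and their texture statistics.

Per channel plane the GLCM counts co-occurring quantized gray levels at a
displacement of d = 2 pixels along the two diagonal directions: 45° pairs
pixels offset by (±d, ∓d) in (row, col), 135° pairs (±d, ±d).  Both
displacement signs are counted, so the matrix is symmetric; it is then
normalized to a probability matrix before the Entropy, Energy, Correlation
and Contrast statistics are taken.

The plane is quantized uniformly from its native value range (not the
per-block min/max) into ``levels`` bins, 16 by default.  Entropy uses the
natural logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_prep import ColorPlanes

DEFAULT_LEVELS = 16
DEFAULT_DISTANCE = 2
DIRECTIONS = (45, 135)


@dataclass
class GLCM:
    matrix: np.ndarray     # (levels, levels), nonnegative, sums to 1
    levels: int
    distance: int
    direction: int         # degrees, 45 or 135


@dataclass
class GLCMStats:
    entropy: float
    energy: float
    correlation: float
    contrast: float


def quantize(plane: np.ndarray, levels: int, value_range: tuple[float, float]) -> np.ndarray:
    """Uniformly quantize a plane from its native range to integer levels."""
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    lo, hi = value_range
    scaled = (np.asarray(plane, dtype=float) - lo) / (hi - lo)
    return np.clip((scaled * levels).astype(np.int64), 0, levels - 1)


def glcm(
    plane: np.ndarray,
    levels: int = DEFAULT_LEVELS,
    distance: int = DEFAULT_DISTANCE,
    direction: int = 45,
    value_range: tuple[float, float] = (0.0, 255.0),
) -> GLCM:
    """Symmetric, probability-normalized co-occurrence matrix of one plane."""
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction}")
    q = quantize(plane, levels, value_range)
    d = distance
    if direction == 135:       # displacement (d, d): pixel (k, l) vs (k−d, l−d)
        a, b = q[d:, d:], q[:-d, :-d]
    else:                      # 45°, displacement (d, −d): (k, l) vs (k−d, l+d)
        a, b = q[d:, :-d], q[:-d, d:]
    counts = np.bincount((a * levels + b).ravel(), minlength=levels * levels).reshape(
        levels, levels
    )
    counts = counts + counts.T          # both displacement signs
    total = counts.sum()
    if total == 0:
        raise ValueError("plane too small for the requested displacement")
    return GLCM(matrix=counts / total, levels=levels, distance=distance, direction=direction)


def glcm_stats(m: GLCM) -> GLCMStats:
    """Entropy, Energy, Correlation, Contrast of a normalized GLCM.

    0·log 0 is taken as 0; a degenerate marginal (σ = 0, e.g. a constant
    block) yields correlation 0 by convention rather than an error.
    """
    p = m.matrix
    k = m.levels
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    energy = float((p**2).sum())

    levels = np.arange(k, dtype=float)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((levels * pi).sum())
    mu_j = float((levels * pj).sum())
    sigma_i = float(np.sqrt(((levels - mu_i) ** 2 * pi).sum()))
    sigma_j = float(np.sqrt(((levels - mu_j) ** 2 * pj).sum()))
    if sigma_i > 0 and sigma_j > 0:
        ii, jj = np.meshgrid(levels, levels, indexing="ij")
        correlation = float((((ii - mu_i) * (jj - mu_j) * p).sum()) / (sigma_i * sigma_j))
    else:
        correlation = 0.0

    ii, jj = np.meshgrid(levels, levels, indexing="ij")
    contrast = float(((ii - jj) ** 2 * p).sum())
    return GLCMStats(entropy=entropy, energy=energy, correlation=correlation, contrast=contrast)


def c_features(
    planes: ColorPlanes,
    levels: int = DEFAULT_LEVELS,
    distance: int = DEFAULT_DISTANCE,
) -> tuple[float, float, float]:
    """The C feature group (ene, cor, con).

    Each statistic is first averaged over the two directions within a
    channel, then over the three channels.
    """
    ene, cor, con = [], [], []
    for _name, plane, value_range in planes.channels():
        per_dir = [
            glcm_stats(glcm(plane, levels, distance, direction, value_range))
            for direction in DIRECTIONS
        ]
        ene.append(np.mean([s.energy for s in per_dir]))
        cor.append(np.mean([s.correlation for s in per_dir]))
        con.append(np.mean([s.contrast for s in per_dir]))
    return float(np.mean(ene)), float(np.mean(cor)), float(np.mean(con))
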