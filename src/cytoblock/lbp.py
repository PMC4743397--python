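"""Local binary patterns: raw, uniform (59-bin) and rotation-invariant-uniform
(10-bin) proportion histograms, plus the U-LBP summary statistics.

The 8-neighbor LBP code of a pixel sets bit ``l`` when neighbor ``l`` is
greater than or equal to the center (s(x)=1 for x ≥ 0).  Neighbors are the
eight integer offsets of the 3×3 ring, enumerated counterclockwise starting
from the right-hand neighbor.  A code is *uniform* when its circular bit
string has at most two 0–1/1–0 transitions; exactly 58 of the 256 codes are
uniform, giving 59 uniform-histogram bins (58 uniform codes in ascending
order plus one aggregate bin for everything non-uniform).  Grouping uniform
codes by their number of set bits gives the 9 rotation-invariant uniform
classes, hence a 10-bin RIU histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: (row, col) offsets of the 8 neighbors, counterclockwise from angle 0.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1),
)

N_UNIFORM_BINS = 59
N_RIU_BINS = 10


def uniformity(code: int) -> int:
    """Number of circular 0–1/1–0 transitions in the 8-bit pattern."""
    if not 0 <= code <= 255:
        raise ValueError(f"LBP code must be in [0, 255], got {code}")
    bits = [(code >> l) & 1 for l in range(8)]
    return sum(bits[l] != bits[(l + 1) % 8] for l in range(8))


def count_uniform_codes() -> int:
    """Count uniform codes by exhaustive enumeration of all 256 patterns."""
    return sum(uniformity(c) <= 2 for c in range(256))


def riu_bin(code: int) -> int:
    """RIU bin of a code, 1-based: set-bit count + 1 if uniform, else 10."""
    if uniformity(code) <= 2:
        return int(bin(code).count("1")) + 1
    return N_RIU_BINS


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u = np.array([uniformity(c) for c in range(256)])
    uniform_codes = np.flatnonzero(u <= 2)           # ascending by code value
    unif = np.full(256, N_UNIFORM_BINS, dtype=np.int64)   # 1-based bins
    unif[uniform_codes] = np.arange(1, uniform_codes.size + 1)
    riu = np.array([riu_bin(c) for c in range(256)], dtype=np.int64)
    return u, unif, riu

#: Per-code lookup tables: uniformity U, uniform bin (1..59), RIU bin (1..10).
UNIFORMITY_TABLE, UNIFORM_BIN_TABLE, RIU_BIN_TABLE = _build_tables()


@dataclass
class LBPHistograms:
    """Proportion histograms of one channel plane (each sums to 1)."""

    raw: np.ndarray       # 256 proportions, indexed by code
    uniform: np.ndarray   # 59 proportions, index b-1 holds 1-based bin b
    riu: np.ndarray       # 10 proportions, index b-1 holds 1-based bin b


@dataclass
class ULBPStats:
    """Summary of uniform bins 51–59: their mean, spread, and the aggregate bin."""

    mean_9: float
    std_9: float
    p59: float


def lbp_code(patch: np.ndarray) -> int:
    """LBP code of a single 3×3 patch (P=8, R=1)."""
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (3, 3):
        raise ValueError(f"expected a 3×3 patch, got shape {patch.shape}")
    center = patch[1, 1]
    code = 0
    for l, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        if patch[1 + dr, 1 + dc] >= center:
            code |= 1 << l
    return code


def code_map(plane: np.ndarray) -> np.ndarray:
    """LBP codes at every interior pixel of a plane (borders excluded)."""
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2 or min(plane.shape) < 3:
        raise ValueError(f"plane must be 2-D and at least 3×3, got shape {plane.shape}")
    center = plane[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int64)
    for l, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        neighbor = plane[1 + dr : plane.shape[0] - 1 + dr, 1 + dc : plane.shape[1] - 1 + dc]
        codes |= (neighbor >= center).astype(np.int64) << l
    return codes


def block_histograms(plane: np.ndarray) -> LBPHistograms:
    """Raw/uniform/RIU proportion histograms of a channel plane.

    Codes are computed at every interior pixel (for a 100×100 block: 98×98
    positions; border pixels are skipped so every code uses real pixels).
    """
    codes = code_map(plane).ravel()
    n = codes.size
    raw = np.bincount(codes, minlength=256) / n
    uniform = np.bincount(UNIFORM_BIN_TABLE[codes] - 1, minlength=N_UNIFORM_BINS) / n
    riu = np.bincount(RIU_BIN_TABLE[codes] - 1, minlength=N_RIU_BINS) / n
    return LBPHistograms(raw=raw, uniform=uniform, riu=riu)


def ulbp_stats(hist: LBPHistograms) -> ULBPStats:
    """Mean, population standard deviation and aggregate-bin proportion of
    uniform bins 51–59."""
    tail = hist.uniform[50:59]
    return ULBPStats(
        mean_9=float(tail.mean()),
        std_9=float(tail.std()),       # population divisor, n = 9
        p59=float(hist.uniform[58]),
    )
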