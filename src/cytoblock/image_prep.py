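"""Working-image preparation: load, resize, tile into blocks, color planes.

A whole-slide cervical cell micrograph is brought to a fixed working
resolution of 800×1000 pixels and cut into an 8×10 grid of 100×100-pixel
blocks; every later stage of the screen operates on blocks, never on whole
images.  Each block is viewed through three single-channel "color models":
the R channel of RGB, the luma gray image, and the intensity channel I of
HSI, each smoothed with a 5×5 median filter before any texture or histogram
statistic is taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import median_filter as _nd_median

#: Working resolution (rows, cols) every input image is forced to.
TARGET_SHAPE: tuple[int, int] = (800, 1000)
#: Side length of a square block, in pixels.
BLOCK_SIZE: int = 100
#: Median-filter window (window × window).
MEDIAN_WINDOW: int = 5
#: Luma weights for the gray color model.
GRAY_WEIGHTS: tuple[float, float, float] = (0.299, 0.587, 0.114)

BACKGROUND, NORMAL, SUSPICIOUS, UNLABELED = "background", "normal", "suspicious", "unlabeled"


@dataclass
class WorkingImage:
    """An RGB raster at the working resolution."""

    pixels: np.ndarray            # (rows, cols, 3) uint8
    source_path: str | None = None
    original_size: tuple[int, int] | None = None  # (rows, cols) before resize

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("WorkingImage requires an RGB raster (rows, cols, 3)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class BlockGrid:
    """An image tiled into disjoint square blocks, indexed (row, col), 0-based."""

    blocks: np.ndarray            # (n_rows, n_cols, bs, bs, 3)
    block_size: int = BLOCK_SIZE
    labels: np.ndarray | None = None  # (n_rows, n_cols) of str tags

    @property
    def n_rows(self) -> int:
        return self.blocks.shape[0]

    @property
    def n_cols(self) -> int:
        return self.blocks.shape[1]

    @property
    def n_blocks(self) -> int:
        return self.n_rows * self.n_cols

    def block(self, row: int, col: int) -> np.ndarray:
        return self.blocks[row, col]

    def __iter__(self):
        for i in range(self.n_rows):
            for j in range(self.n_cols):
                yield (i, j), self.blocks[i, j]


@dataclass
class ColorPlanes:
    """The three filtered single-channel views of one block.

    ``r_channel`` and ``gray`` stay on the native 8-bit scale [0, 255] (kept
    as floats; quantization happens only where a histogram or GLCM needs
    discrete levels), ``intensity`` is (R+G+B)/3 rescaled to [0, 1].
    """

    r_channel: np.ndarray
    gray: np.ndarray
    intensity: np.ndarray

    def channels(self):
        """Iterate (name, plane, value_range) over the three color models."""
        yield "intensity", self.intensity, (0.0, 1.0)
        yield "r_channel", self.r_channel, (0.0, 255.0)
        yield "gray", self.gray, (0.0, 255.0)


def load_and_resize(path: str | Path, target: tuple[int, int] = TARGET_SHAPE) -> WorkingImage:
    """Read an RGB image file and force it to the working resolution.

    The aspect ratio is deliberately not preserved: whatever the source
    shape, the output is exactly ``target`` (rows, cols), matching the fixed
    8×10 block grid downstream.  Resampling is bilinear.
    """
    try:
        im = Image.open(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    with im:
        if im.mode in ("1", "L", "LA", "I", "I;16", "F"):
            raise ValueError(
                f"{path!r} is single-channel ({im.mode}); the screen needs the "
                "R, G and B channels"
            )
        original = (im.height, im.width)
        im = im.convert("RGB")
        if (im.height, im.width) != target:
            im = im.resize((target[1], target[0]), Image.BILINEAR)
        pixels = np.asarray(im, dtype=np.uint8)
    return WorkingImage(pixels, source_path=str(path), original_size=original)


def from_array(pixels: np.ndarray, source: str | None = None) -> WorkingImage:
    """Wrap an in-memory 8-bit RGB array (e.g. a synthetic render)."""
    pixels = np.asarray(pixels, dtype=np.uint8)
    return WorkingImage(pixels, source_path=source, original_size=pixels.shape[:2])


def tile(image: WorkingImage, block_size: int = BLOCK_SIZE) -> BlockGrid:
    """Cut a working image into disjoint ``block_size``-square tiles.

    Block (i, j) covers rows [i·bs, (i+1)·bs) and cols [j·bs, (j+1)·bs);
    dimensions must divide evenly — there are no partial blocks.
    """
    rows, cols = image.shape
    if rows % block_size or cols % block_size:
        raise ValueError(
            f"image shape {rows}×{cols} is not divisible by block size {block_size}"
        )
    n_r, n_c = rows // block_size, cols // block_size
    blocks = (
        image.pixels.reshape(n_r, block_size, n_c, block_size, 3)
        .swapaxes(1, 2)
        .copy()
    )
    return BlockGrid(blocks=blocks, block_size=block_size)


def assemble(grid: BlockGrid) -> np.ndarray:
    """Reassemble the tiles into the full raster (inverse of :func:`tile`)."""
    n_r, n_c, bs = grid.n_rows, grid.n_cols, grid.block_size
    return grid.blocks.swapaxes(1, 2).reshape(n_r * bs, n_c * bs, 3)


def median_filter(plane: np.ndarray, window: int = MEDIAN_WINDOW) -> np.ndarray:
    """Median-filter a single-channel plane (edge-replicated borders)."""
    if window % 2 == 0 or window < 3:
        raise ValueError(f"median window must be odd and >= 3, got {window}")
    return _nd_median(np.asarray(plane, dtype=float), size=window, mode="nearest")


def hsi(block: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full HSI transform of an RGB block; H in degrees, S and I in [0, 1].

    Only I is consumed by the screen; H and S are provided for completeness
    (standard geometric form; H is undefined for achromatic pixels and set
    to 0 there).
    """
    rgb = np.asarray(block, dtype=float)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    total = r + g + b
    i = total / 3.0 / 255.0
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(total > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / total, 0.0)
        num = 0.5 * ((r - g) + (r - b))
        den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
        theta = np.degrees(np.arccos(np.clip(np.where(den > 0, num / den, 1.0), -1.0, 1.0)))
    h = np.where(b <= g, theta, 360.0 - theta)
    h = np.where(den > 0, h, 0.0)
    return h, s, i


def to_color_planes(block: np.ndarray, window: int = MEDIAN_WINDOW) -> ColorPlanes:
    """Convert one RGB block to its three median-filtered color planes."""
    rgb = np.asarray(block, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("block must be an RGB tile (rows, cols, 3)")
    r = rgb[..., 0]
    gray = GRAY_WEIGHTS[0] * rgb[..., 0] + GRAY_WEIGHTS[1] * rgb[..., 1] + GRAY_WEIGHTS[2] * rgb[..., 2]
    intensity = rgb.sum(axis=2) / 3.0 / 255.0
    return ColorPlanes(
        r_channel=median_filter(r, window),
        gray=median_filter(gray, window),
        intensity=median_filter(intensity, window),
    )
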