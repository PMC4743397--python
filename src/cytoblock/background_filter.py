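"""Background-block removal from the gray-plane RIU-LBP signature.

Empty (background) regions of a stained slide are optically flat: nearly
every 3×3 neighborhood ties with its center, so the LBP code 255 dominates
and the RIU histogram peaks in bin 9 (eight set bits).  Cell-bearing blocks
carry smooth local gradients whose codes are half-plane-like uniform
patterns with ~4 set bits, putting the RIU peak in bin 5.  The filter
therefore keeps a block iff the RIU peak of its *gray* plane falls in bin 5
(1-based, matching the "fifth pattern"); the R-channel and intensity planes
are never consulted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .image_prep import BACKGROUND, ColorPlanes
from .lbp import block_histograms

#: 1-based RIU bin whose peak marks a non-background block.
NON_BACKGROUND_PEAK_BIN = 5


@dataclass
class BackgroundDecision:
    is_background: bool
    peak_bin: int          # 1-based argmax of riu_hist, ties toward lower bin
    riu_hist: np.ndarray   # 10 proportions


def classify_background(
    block_planes: ColorPlanes,
    min_peak_proportion: float = 0.0,
    non_background_bin: int = NON_BACKGROUND_PEAK_BIN,
) -> BackgroundDecision:
    """Decide background vs. non-background from the gray RIU-LBP histogram.

    A block is non-background iff the histogram's peak lies in
    ``non_background_bin`` (default 5) and that peak proportion is at least
    ``min_peak_proportion`` (default 0, i.e. pure argmax).
    """
    riu = block_histograms(block_planes.gray).riu
    peak = int(np.argmax(riu)) + 1          # np.argmax already ties toward lower
    is_bg = peak != non_background_bin or riu[peak - 1] < min_peak_proportion
    return BackgroundDecision(is_background=is_bg, peak_bin=peak, riu_hist=riu)


def removal_accuracy_from_counts(fp: int, n_images: int, blocks_per_image: int = 80) -> float:
    """Background-removal accuracy, in percent: (1 − FP/(80·n)) × 100.

    FP counts non-background blocks wrongly judged as background — the one
    error mode that loses cells, hence the one the score is built on.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    total = blocks_per_image * n_images
    if not 0 <= fp <= total:
        raise ValueError(f"FP must be in [0, {total}], got {fp}")
    return (1.0 - fp / total) * 100.0


def background_accuracy(
    decisions: Sequence[BackgroundDecision] | Iterable[bool],
    truth: Sequence[str],
    n_images: int,
    blocks_per_image: int = 80,
) -> float:
    """Score a set of per-block decisions against ground-truth labels.

    ``decisions`` may be BackgroundDecision objects or raw booleans
    (True = judged background); ``truth`` holds per-block label tags where
    ``"background"`` marks true background.  Requires exactly
    ``blocks_per_image × n_images`` aligned entries.
    """
    judged_bg = np.array(
        [d.is_background if isinstance(d, BackgroundDecision) else bool(d) for d in decisions]
    )
    truth_bg = np.array([t == BACKGROUND for t in truth])
    expected = blocks_per_image * n_images
    if judged_bg.size != expected or truth_bg.size != expected:
        raise ValueError(
            f"expected {expected} decisions and labels "
            f"({blocks_per_image} blocks × {n_images} images), "
            f"got {judged_bg.size} decisions / {truth_bg.size} labels"
        )
    fp = int(np.sum(judged_bg & ~truth_bg))
    return removal_accuracy_from_counts(fp, n_images, blocks_per_image)
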