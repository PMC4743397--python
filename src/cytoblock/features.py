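"""Assembly of the 11-dimensional salient feature vector, per-feature
significance reporting, and min–max normalization.

The vector concatenates four groups, each averaged over the intensity,
R-channel and gray planes:

==  ==================  =====================================================
 1  SD                  std. dev. of uniform-LBP bins 51–59 (L group)
 2  p-59                proportion of the non-uniform aggregate bin (L)
 3  Energy (GLCM)       direction-averaged co-occurrence energy (C group)
 4  Correlation         (C)
 5  Contrast            (C)
 6  Variance            color-histogram variance (S group)
 7  Skewness            (S)
 8  Energy (histogram)  (S)
 9  Entropy             (S)
10  R2                  epithelial nuclear ratio, intensity plane (R group)
11  R4                  epithelial nuclear ratio, gray plane (R group)
==  ==================  =====================================================

The set is fixed; the Welch t-test report is diagnostic only and never
drops or adds a feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

from . import color_histogram as ch
from . import texture_glcm as tg
from .background_filter import NON_BACKGROUND_PEAK_BIN
from .image_prep import ColorPlanes
from .lbp import block_histograms, ulbp_stats

N_FEATURES = 11
FEATURE_NAMES: tuple[str, ...] = (
    "sd_ulbp", "p59", "glcm_energy", "glcm_correlation", "glcm_contrast",
    "hist_variance", "hist_skewness", "hist_energy", "hist_entropy", "r2", "r4",
)

#: Label convention: normal = +1, suspicious = −1.
LABEL_NORMAL, LABEL_SUSPICIOUS = 1, -1


class BackgroundBlockError(ValueError):
    """Raised when feature assembly is asked for a background block."""


@dataclass
class FeatureVector:
    values: np.ndarray                      # exactly 11 entries, Table order
    block_ref: tuple[str, int, int] | None = None   # (image_id, row, col)
    label: int | None = None                # +1 normal / −1 suspicious


def assemble(
    block_planes: ColorPlanes,
    check_background: bool = True,
    glcm_levels: int = tg.DEFAULT_LEVELS,
    glcm_distance: int = tg.DEFAULT_DISTANCE,
    block_ref: tuple[str, int, int] | None = None,
    label: int | None = None,
) -> FeatureVector:
    """Compute the 11 salient features of one non-background block.

    Features are undefined for background blocks by the pipeline's
    contract; with ``check_background`` (default) the gray-plane RIU peak is
    re-checked and a :class:`BackgroundBlockError` raised if it is not in
    bin 5.
    """
    hists = {name: block_histograms(plane) for name, plane, _ in block_planes.channels()}

    if check_background:
        riu = hists["gray"].riu
        peak = int(np.argmax(riu)) + 1
        if peak != NON_BACKGROUND_PEAK_BIN:
            raise BackgroundBlockError(
                f"block {block_ref} looks like background (gray RIU peak in bin "
                f"{peak}, not {NON_BACKGROUND_PEAK_BIN}); features are undefined"
            )

    ul = [ulbp_stats(h) for h in hists.values()]
    sd = float(np.mean([u.std_9 for u in ul]))
    p59 = float(np.mean([u.p59 for u in ul]))

    ene, cor, con = tg.c_features(block_planes, glcm_levels, glcm_distance)
    var, skew, h_ene, h_ent = ch.s_features(block_planes)
    ratios = ch.interval_ratios(block_planes)

    values = np.array(
        [sd, p59, ene, cor, con, var, skew, h_ene, h_ent, ratios.r2, ratios.r4]
    )
    return FeatureVector(values=values, block_ref=block_ref, label=label)


def t_test_report(normal: np.ndarray, suspicious: np.ndarray, alpha: float = 0.01) -> dict:
    """Welch two-sample t-test p-value per feature (diagnostic report).

    ``normal`` and ``suspicious`` are (n, 11) arrays.  A feature with zero
    variance in both groups gets p = 1 (no evidence of a difference).
    Returns ``{"p_values": array, "significant": bool array, "alpha": alpha}``.
    """
    normal = np.atleast_2d(np.asarray(normal, dtype=float))
    suspicious = np.atleast_2d(np.asarray(suspicious, dtype=float))
    if normal.shape[0] < 2 or suspicious.shape[0] < 2:
        raise ValueError("need at least 2 samples per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        result = _scipy_stats.ttest_ind(normal, suspicious, axis=0, equal_var=False)
    p = np.where(np.isnan(result.pvalue), 1.0, result.pvalue)
    return {"p_values": p, "significant": p < alpha, "alpha": alpha}


@dataclass
class NormalizationParams:
    """Per-feature training-set extrema for min–max scaling to [0, 1]."""

    minimum: np.ndarray
    maximum: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Scale feature vectors to [0, 1]; out-of-range values are clipped."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.minimum.size:
            raise ValueError(
                f"expected {self.minimum.size} features, got {X.shape[1]}"
            )
        scaled = (X - self.minimum) / (self.maximum - self.minimum)
        return np.clip(scaled, 0.0, 1.0)


def fit_normalizer(training: np.ndarray, feature_names: tuple[str, ...] = FEATURE_NAMES) -> NormalizationParams:
    """Record per-feature Min/Max from the training set.

    A constant feature (Max = Min) cannot be scaled and raises, naming the
    offending feature.
    """
    X = np.atleast_2d(np.asarray(training, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training vectors to fit a normalizer")
    mn, mx = X.min(axis=0), X.max(axis=0)
    constant = np.flatnonzero(mx == mn)
    if constant.size:
        names = ", ".join(feature_names[i] if i < len(feature_names) else str(i) for i in constant)
        raise ValueError(f"constant feature(s) in training set, cannot min–max scale: {names}")
    return NormalizationParams(minimum=mn, maximum=mx, feature_names=feature_names)
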