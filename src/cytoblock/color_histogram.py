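"""Color histograms, their statistical moments, and nuclear-interval ratios.

Every channel plane is histogrammed on a common 256-level scale (intensity
values in [0,1] are mapped ×255 and rounded; gray and R-channel values are
rounded directly) so that the cross-channel averages of the S feature group
compare like with like.  Six moments are taken per histogram — mean,
variance, skewness, kurtosis, energy, entropy (base-2 log) — of which
variance, skewness, energy and entropy are emitted as features.

The R feature group is built from fixed stain-chemistry intervals: on the
intensity plane, [0, 0.2) holds white-cell (leukocyte) nuclei and
[0.2, 0.4) epithelial nuclei; on the gray plane the corresponding intervals
are [0, 50) and [50, 100).  R1 = mass[0,0.2)/mass[0,0.5) and
R2 = mass[0.2,0.4)/mass[0.2,0.5) on intensity; R3 = mass[0,50)/mass[0,125)
and R4 = mass[50,100)/mass[50,125) on gray.  R2 and R4 — the epithelial
nuclear ratios — are the selected features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_prep import ColorPlanes

N_LEVELS = 256


@dataclass
class ColorHistogram:
    proportions: np.ndarray       # 256 values summing to 1
    channel: str
    scale: float                  # native value of the top level (1.0 or 255.0)


@dataclass
class HistogramStats:
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    energy: float
    entropy: float


@dataclass
class IntervalRatios:
    r1: float
    r2: float
    r3: float
    r4: float


def histogram(plane: np.ndarray, channel: str = "", value_range: tuple[float, float] = (0.0, 255.0)) -> ColorHistogram:
    """Proportion histogram of a plane over the common 256-level scale."""
    lo, hi = value_range
    levels = np.rint((np.asarray(plane, dtype=float) - lo) / (hi - lo) * (N_LEVELS - 1))
    levels = np.clip(levels.astype(np.int64), 0, N_LEVELS - 1)
    props = np.bincount(levels.ravel(), minlength=N_LEVELS) / levels.size
    return ColorHistogram(proportions=props, channel=channel, scale=hi)


def histogram_stats(h: ColorHistogram) -> HistogramStats:
    """The six moment statistics of a proportion histogram.

    Entropy uses log base 2 (0·log 0 ≡ 0); for a degenerate histogram
    (σ = 0) skewness and kurtosis are 0 by convention.
    """
    p = h.proportions
    i = np.arange(N_LEVELS, dtype=float)
    mu = float((i * p).sum())
    var = float(((i - mu) ** 2 * p).sum())
    sigma = np.sqrt(var)
    if sigma > 0:
        skew = float(((i - mu) ** 3 * p).sum() / sigma**3)
        kurt = float(((i - mu) ** 4 * p).sum() / sigma**4 - 3.0)
    else:
        skew = kurt = 0.0
    energy = float((p**2).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return HistogramStats(mean=mu, variance=var, skewness=skew, kurtosis=kurt, energy=energy, entropy=entropy)


def _interval_mass(h: ColorHistogram, lo: float, hi: float) -> float:
    """Histogram mass on [lo, hi) in native channel units ([lo, hi] when hi
    reaches the top of the scale)."""
    values = np.arange(N_LEVELS, dtype=float) / (N_LEVELS - 1) * h.scale
    if hi >= h.scale:
        sel = (values >= lo) & (values <= hi)
    else:
        sel = (values >= lo) & (values < hi)
    return float(h.proportions[sel].sum())


def _ratio(h: ColorHistogram, num: tuple[float, float], den: tuple[float, float]) -> float:
    d = _interval_mass(h, *den)
    return _interval_mass(h, *num) / d if d > 0 else 0.0


def interval_ratios(planes: ColorPlanes) -> IntervalRatios:
    """The four nuclear-interval ratios (zero denominator → ratio 0)."""
    hi_ = histogram(planes.intensity, "intensity", (0.0, 1.0))
    hg = histogram(planes.gray, "gray", (0.0, 255.0))
    return IntervalRatios(
        r1=_ratio(hi_, (0.0, 0.2), (0.0, 0.5)),
        r2=_ratio(hi_, (0.2, 0.4), (0.2, 0.5)),
        r3=_ratio(hg, (0.0, 50.0), (0.0, 125.0)),
        r4=_ratio(hg, (50.0, 100.0), (50.0, 125.0)),
    )


def s_features(planes: ColorPlanes) -> tuple[float, float, float, float]:
    """The S feature group (variance, skewness, energy, entropy), each
    averaged over the three channels on the common 256-level scale."""
    stats = [
        histogram_stats(histogram(plane, name, value_range))
        for name, plane, value_range in planes.channels()
    ]
    return (
        float(np.mean([s.variance for s in stats])),
        float(np.mean([s.skewness for s in stats])),
        float(np.mean([s.energy for s in stats])),
        float(np.mean([s.entropy for s in stats])),
    )
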