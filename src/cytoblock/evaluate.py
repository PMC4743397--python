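"""Screening metrics from predicted vs. true block labels.

The positive class of the screen is *abnormal* (suspicious, label −1):
TP counts true abnormal blocks found, FP normal blocks flagged abnormal,
FN abnormal blocks missed, TN true normals.  Accuracy, sensitivity,
specificity, PPV and NPV are reported as percentages to two decimals; a
rate with a zero denominator is undefined (None), never 0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .features import LABEL_SUSPICIOUS


@dataclass
class ConfusionMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    @property
    def n_blocks(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _rate(num: int, den: int) -> float | None:
    return 100.0 * num / den if den > 0 else None


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> ConfusionMetrics:
    """Build the five screening rates from raw confusion counts."""
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("no blocks to evaluate")
    return ConfusionMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=_rate(tp + tn, total),
        sensitivity=_rate(tp, tp + fn),
        specificity=_rate(tn, tn + fp),
        ppv=_rate(tp, tp + fp),
        npv=_rate(tn, tn + fn),
    )


def confusion(pred, truth) -> ConfusionMetrics:
    """Confusion counts and rates from aligned label sequences in {+1, −1}."""
    pred = np.asarray(pred, dtype=int).ravel()
    truth = np.asarray(truth, dtype=int).ravel()
    if pred.size == 0:
        raise ValueError("empty prediction list")
    if pred.size != truth.size:
        raise ValueError(f"length mismatch: {pred.size} predictions vs {truth.size} truths")
    pos_p, pos_t = pred == LABEL_SUSPICIOUS, truth == LABEL_SUSPICIOUS
    return metrics_from_counts(
        tp=int(np.sum(pos_p & pos_t)),
        tn=int(np.sum(~pos_p & ~pos_t)),
        fp=int(np.sum(pos_p & ~pos_t)),
        fn=int(np.sum(~pos_p & pos_t)),
    )


def _fmt(rate: float | None) -> str:
    return "undefined" if rate is None else f"{rate:.2f} %"


def report(
    metrics: ConfusionMetrics,
    background: dict | None = None,
    seed: int | None = None,
) -> tuple[str, str]:
    """Render a results document: (human-readable text, CSV).

    ``background`` optionally summarizes the background-removal stage, e.g.
    ``{"total_blocks": 960, "background_blocks": 469, "accuracy_pct": 99.9}``.
    The generator/run seed is echoed so any number is reproducible.
    """
    rows: list[tuple[str, str]] = []
    if background:
        if "total_blocks" in background:
            rows.append(("Total blocks", str(background["total_blocks"])))
        if "background_blocks" in background:
            rows.append(("Background blocks", str(background["background_blocks"])))
        if "accuracy_pct" in background:
            rows.append(("Background removal accuracy", f"{background['accuracy_pct']:.1f} %"))
    rows += [
        ("Non-background blocks evaluated", str(metrics.n_blocks)),
        ("TP (abnormal found)", str(metrics.tp)),
        ("TN (normal kept)", str(metrics.tn)),
        ("FP (normal flagged)", str(metrics.fp)),
        ("FN (abnormal missed)", str(metrics.fn)),
        ("Accuracy", _fmt(metrics.accuracy)),
        ("Sensitivity", _fmt(metrics.sensitivity)),
        ("Specificity", _fmt(metrics.specificity)),
        ("PPV", _fmt(metrics.ppv)),
        ("NPV", _fmt(metrics.npv)),
    ]
    if seed is not None:
        rows.append(("Seed", str(seed)))

    width = max(len(k) for k, _ in rows)
    text = "\n".join(f"{k:<{width}}  {v}" for k, v in rows) + "\n"

    buf = io.StringIO()
    buf.write("quantity,value\n")
    for k, v in rows:
        buf.write(f"{k},{v.replace(' %', '%')}\n")
    return text, buf.getvalue()
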