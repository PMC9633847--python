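"""Per-image, per-class segmentation metrics.

Four pixel-level metrics summarise segmentation quality: mean intersection
over union (mIoU), mean precision, mean recall and mean specificity.  Each
is the *mean of per-cell ratios* over every (image, class) cell,

    mIoU = 1/(I*C) * sum_i sum_c TP_ic / (TP_ic + FP_ic + FN_ic)

and analogously for the others — not the ratio of pooled counts.  Per-class
columns average over images only; the overall column averages over images
and classes, mirroring the usual per-class / overall report layout.

Cells whose ratio has a zero denominator (e.g. a class absent from both the
truth and the prediction of an image) default to a score of 1: perfect
agreement on absence.  The ``zero_division="skip"`` policy drops such cells
from the mean instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = ["ConfusionTally", "MetricsReport", "tally", "compute_metrics", "METRIC_NAMES"]

METRIC_NAMES = ("miou", "mprecision", "mrecall", "mspecificity")


@dataclass(frozen=True)
class ConfusionTally:
    """Pixel confusion counts for one image and one class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Mean metrics per class and overall.

    ``per_class`` maps class name -> {metric name -> value}; ``overall``
    maps metric name -> value averaged over all (image, class) cells.
    """

    per_class: Mapping[str, Mapping[str, float]]
    overall: Mapping[str, float]
    n_images: int
    n_classes: int


def tally(pred: np.ndarray, truth: np.ndarray) -> ConfusionTally:
    """Exact pixel confusion counts between a predicted and a truth mask."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionTally(tp=tp, fp=fp, fn=fn, tn=tn)


def _cell_ratios(t: ConfusionTally, zero_division: str) -> dict[str, float | None]:
    """The four per-cell ratios; ``None`` marks a skipped zero-denominator cell."""

    def ratio(num: int, den: int) -> float | None:
        if den == 0:
            return 1.0 if zero_division == "one" else None
        return num / den

    return {
        "miou": ratio(t.tp, t.tp + t.fp + t.fn),
        "mprecision": ratio(t.tp, t.tp + t.fp),
        "mrecall": ratio(t.tp, t.tp + t.fn),
        "mspecificity": ratio(t.tn, t.tn + t.fp),
    }


def compute_metrics(
    tallies: Mapping[tuple[object, str], ConfusionTally],
    *,
    zero_division: str = "one",
) -> MetricsReport:
    """Aggregate per-(image, class) tallies into a :class:`MetricsReport`.

    Parameters
    ----------
    tallies:
        Mapping from ``(image_id, class_name)`` to a :class:`ConfusionTally`.
        Every image must carry a tally for every class (a complete grid).
    zero_division:
        ``"one"`` (default) scores zero-denominator cells as 1;
        ``"skip"`` excludes them from the averages.
    """
    if zero_division not in ("one", "skip"):
        raise ValueError("zero_division must be 'one' or 'skip'")
    if not tallies:
        raise ValueError("at least one tally is required")
    images = sorted({k[0] for k in tallies}, key=repr)
    classes = sorted({k[1] for k in tallies})
    missing = [(i, c) for i in images for c in classes if (i, c) not in tallies]
    if missing:
        raise ValueError(f"incomplete (image, class) grid; missing cells: {missing[:5]}")

    cell = {
        (i, c): _cell_ratios(tallies[(i, c)], zero_division)
        for i in images
        for c in classes
    }

    def mean_over(keys: list[tuple[object, str]], metric: str) -> float:
        vals = [cell[k][metric] for k in keys if cell[k][metric] is not None]
        return float(np.mean(vals)) if vals else float("nan")

    per_class = {
        c: {m: mean_over([(i, c) for i in images], m) for m in METRIC_NAMES}
        for c in classes
    }
    all_keys = [(i, c) for i in images for c in classes]
    overall = {m: mean_over(all_keys, m) for m in METRIC_NAMES}
    return MetricsReport(
        per_class=per_class,
        overall=overall,
        n_images=len(images),
        n_classes=len(classes),
    )
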