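"""Confusion matrices and accuracy/sensitivity/specificity/precision.

The confusion matrix is oriented rows = labelled (video-observed)
behaviour, columns = model prediction, over the classes sit, stand, walk.
For each class a one-vs-rest decomposition gives TP, FN, FP, TN and the
four metrics

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)        (true positive rate)
    specificity = TN / (TN + FP)        (true negative rate)
    precision   = TP / (TP + FP)

*Overall* metrics micro-aggregate: the class-wise TP/TN/FP/FN are summed
over the three decompositions before the formulas apply, which weights
each behaviour by its support (so the dominant sitting class carries the
most weight).  Two algebraic consequences hold for every 3-class matrix:
overall sensitivity = overall precision = trace/n, and overall accuracy
equals the unweighted mean of the three per-class accuracies.

Metrics are percentages; display rounding is half-up to integer, with
full precision retained on the objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import errors
from .names import BEHAVIOURS

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ConfusionMatrix3:
    """3x3 labelled-vs-predicted counts over (sit, stand, walk)."""

    counts: np.ndarray  # rows = labelled, columns = predicted

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3) or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative 3x3 matrix")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls: str) -> tuple[int, int, int, int]:
        """(TP, FN, FP, TN) for one class."""
        i = BEHAVIOURS.index(cls)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i, :].sum()) - tp
        fp = int(self.counts[:, i].sum()) - tp
        tn = self.n - tp - fn - fp
        return tp, fn, fp, tn


def confusion(true_labels, predicted_labels) -> ConfusionMatrix3:
    """Count labelled-vs-predicted pairs into a 3x3 matrix."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise errors.LengthMismatch("label sequences differ in length")
    if len(true_labels) == 0:
        raise errors.EmptyInput("no labels")
    counts = np.zeros((3, 3), dtype=np.int64)
    index = {b: i for i, b in enumerate(BEHAVIOURS)}
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise errors.UnknownClass(f"label outside {BEHAVIOURS}: {t!r}/{p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix3(counts)


@dataclass
class Metrics:
    """The four metrics (percent) with an undefined-denominator flag set."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    undefined: set[str] = field(default_factory=set)

    def as_display(self) -> dict[str, int | None]:
        """Half-up integer percents; None where the metric is undefined."""
        return {
            name: (None if name in self.undefined else _round_half_up(getattr(self, name)))
            for name in METRIC_NAMES
        }


def _metrics_from_counts(tp: int, fn: int, fp: int, tn: int) -> Metrics:
    undefined: set[str] = set()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.add(name)
            return float("nan")
        return 100.0 * num / den

    return Metrics(
        accuracy=ratio(tp + tn, tp + tn + fp + fn, "accuracy"),
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        precision=ratio(tp, tp + fp, "precision"),
        undefined=undefined,
    )


def class_metrics(cm: ConfusionMatrix3, cls: str) -> Metrics:
    """One-vs-rest metrics (percent) for one behaviour class."""
    if cls not in BEHAVIOURS:
        raise errors.UnknownClass(cls)
    return _metrics_from_counts(*cm.one_vs_rest(cls))


def overall_metrics(cm: ConfusionMatrix3) -> Metrics:
    """Micro-aggregated overall metrics: class-wise TP/FN/FP/TN are summed
    over the three one-vs-rest decompositions before the formulas apply."""
    sums = [0, 0, 0, 0]
    for cls in BEHAVIOURS:
        for j, v in enumerate(cm.one_vs_rest(cls)):
            sums[j] += v
    return _metrics_from_counts(*sums)


def metrics_report(cm: ConfusionMatrix3) -> dict[str, Metrics]:
    """Per-class metrics plus the micro-aggregated overall row."""
    report = {cls: class_metrics(cm, cls) for cls in BEHAVIOURS}
    report["overall"] = overall_metrics(cm)
    return report


def _shade(value: int | None) -> str:
    # display shading mirrors the reporting convention:
    # plain >= 80, light grey 60-79, dark grey <= 59
    if value is None:
        return "n/a  "
    mark = " " if value >= 80 else ("+" if value >= 60 else "*")
    return f"{value:>3d}{mark}"


def format_report(cm: ConfusionMatrix3) -> str:
    """Plain-text confusion matrix and metric table.

    Metric cells are flagged '+' when 60-79 % and '*' when <= 59 %.
    """
    lines = ["labelled \\ predicted   sit  stand   walk"]
    for i, cls in enumerate(BEHAVIOURS):
        row = "  ".join(f"{int(v):>5d}" for v in cm.counts[i])
        lines.append(f"{cls:<20} {row}")
    lines.append("")
    lines.append(f"{'':<10} {'acc':>5} {'sens':>5} {'spec':>5} {'prec':>5}")
    report = metrics_report(cm)
    for name in (*BEHAVIOURS, "overall"):
        disp = report[name].as_display()
        cells = " ".join(_shade(disp[m]) for m in METRIC_NAMES)
        lines.append(f"{name:<10} {cells}")
    lines.append("('+' 60-79 %, '*' <= 59 %)")
    return "\n".join(lines)
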