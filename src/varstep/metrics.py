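"""Classification evaluation: normalization, thresholded assignment, and
per-class precision / recall / F1 from confusion counts.

The classifier under evaluation emits softmax probabilities over the
target species; a prediction is accepted only when the maximum class
probability reaches a confidence threshold (0.95 by default), otherwise
the sample is assigned to the catch-all interference label ``"other"``.
That label participates in the confusion matrix as a first-class class.

Per class c over single-label predictions:

    TP = #(true = c and pred = c)
    FP = #(true != c and pred = c)
    FN = #(true = c and pred != c)

    P = TP / (TP + FP),  R = TP / (TP + FN),  F1 = 2PR / (P + R)

with any 0/0 defined as 0 for stable reporting of absent classes.
Overall accuracy is sum(TP) / total.  For comparison against published
tables, values are rounded half-up (3 decimals for metrics, 2 for percent
accuracies), matching display precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "round_half_up",
    "MinMaxRange",
    "minmax_normalize",
    "apply_threshold",
    "ConfusionCounts",
    "confusion_from_predictions",
    "ClassMetrics",
    "precision_recall_f1",
    "overall_accuracy",
    "metrics_report",
    "OTHER_LABEL",
]

#: Catch-all interference label for low-confidence predictions.
OTHER_LABEL = "other"


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (93.125 -> 93.13 at 2 digits)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MinMaxRange:
    """Closed range used for min-max feature scaling."""

    min: float
    max: float

    def __post_init__(self) -> None:
        if self.max < self.min:
            raise ValueError(f"max < min: {self.max} < {self.min}")

    def transform(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        span = self.max - self.min
        if span == 0:
            return np.zeros_like(values)
        return (values - self.min) / span


def minmax_normalize(values: Sequence[float]) -> np.ndarray:
    """Map values to [0, 1] via (x - min) / (max - min).

    Constant input (max == min) maps every element to 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("minmax_normalize requires a nonempty input")
    return MinMaxRange(float(values.min()), float(values.max())).transform(values)


def apply_threshold(
    class_probabilities: Sequence[float],
    threshold: float = 0.95,
    class_labels: Optional[Sequence[str]] = None,
    other_label: str = OTHER_LABEL,
):
    """Thresholded argmax assignment.

    Returns the argmax class when its probability reaches ``threshold``,
    else ``other_label``.  Argmax ties break toward the earlier class.
    """
    probs = np.asarray(class_probabilities, dtype=float)
    if probs.size == 0:
        raise ValueError("empty probability vector")
    if (probs < 0).any():
        raise ValueError("probabilities must be nonnegative")
    idx = int(np.argmax(probs))  # first maximum wins
    if probs[idx] < threshold:
        return other_label
    return class_labels[idx] if class_labels is not None else idx


@dataclass
class ConfusionCounts:
    """Per-class TP/FP/FN counts plus the total sample count."""

    classes: List[str]
    tp: Dict[str, int]
    fp: Dict[str, int]
    fn: Dict[str, int]
    total: int

    def __post_init__(self) -> None:
        for name, mapping in (("tp", self.tp), ("fp", self.fp), ("fn", self.fn)):
            for c in self.classes:
                v = mapping.get(c)
                if v is None or v < 0 or int(v) != v:
                    raise ValueError(f"{name}[{c!r}] must be a nonnegative integer, got {v!r}")
        if self.total <= 0:
            raise ValueError(f"total must be positive, got {self.total}")
        if sum(self.tp.values()) > self.total:
            raise ValueError("sum of TP exceeds total sample count")

    @classmethod
    def from_table(
        cls,
        rows: Mapping[str, Sequence[int]],
        total: Optional[int] = None,
    ) -> "ConfusionCounts":
        """Build from ``{class: (tp, fp, fn)}``.

        ``total`` defaults to ``sum(TP + FN)``, exact for a complete
        single-label matrix.
        """
        classes = list(rows)
        tp = {c: int(rows[c][0]) for c in classes}
        fp = {c: int(rows[c][1]) for c in classes}
        fn = {c: int(rows[c][2]) for c in classes}
        if total is None:
            total = sum(tp[c] + fn[c] for c in classes)
        return cls(classes=classes, tp=tp, fp=fp, fn=fn, total=total)

    @classmethod
    def from_csv(cls, path, total: Optional[int] = None) -> "ConfusionCounts":
        df = pd.read_csv(path)
        required = {"class", "tp", "fp", "fn"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        for i, row in df.iterrows():
            for col in ("tp", "fp", "fn"):
                if pd.isna(row[col]):
                    raise ValueError(f"{path}: row {i + 1}: missing {col}")
        rows = {str(r["class"]): (r["tp"], r["fp"], r["fn"]) for _, r in df.iterrows()}
        return cls.from_table(rows, total=total)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "class": self.classes,
                "tp": [self.tp[c] for c in self.classes],
                "fp": [self.fp[c] for c in self.classes],
                "fn": [self.fn[c] for c in self.classes],
            }
        ).to_csv(path, index=False)


def confusion_from_predictions(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str],
) -> ConfusionCounts:
    """Tally per-class TP/FP/FN from parallel single-label lists."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label lists differ in length")
    classes = list(class_order)
    known = set(classes)
    tp = {c: 0 for c in classes}
    fp = {c: 0 for c in classes}
    fn = {c: 0 for c in classes}
    for t, p in zip(true_labels, predicted_labels):
        if t not in known:
            raise ValueError(f"true label {t!r} outside class order {classes}")
        if p not in known:
            raise ValueError(f"predicted label {p!r} outside class order {classes}")
        if t == p:
            tp[t] += 1
        else:
            fn[t] += 1
            fp[p] += 1
    return ConfusionCounts(classes=classes, tp=tp, fp=fp, fn=fn, total=len(true_labels))


@dataclass(frozen=True)
class ClassMetrics:
    """Precision, recall, and their harmonic mean for one class."""

    precision: float
    recall: float
    f1: float

    def rounded(self, ndigits: int = 3) -> "ClassMetrics":
        return ClassMetrics(
            precision=round_half_up(self.precision, ndigits),
            recall=round_half_up(self.recall, ndigits),
            f1=round_half_up(self.f1, ndigits),
        )


def _ratio(num: int, den: int) -> float:
    return num / den if den else 0.0


def precision_recall_f1(counts: ConfusionCounts) -> Dict[str, ClassMetrics]:
    """Per-class P, R, F1 from confusion counts (0/0 cases -> 0)."""
    out: Dict[str, ClassMetrics] = {}
    for c in counts.classes:
        p = _ratio(counts.tp[c], counts.tp[c] + counts.fp[c])
        r = _ratio(counts.tp[c], counts.tp[c] + counts.fn[c])
        f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        out[c] = ClassMetrics(precision=p, recall=r, f1=f1)
    return out


def overall_accuracy(counts: ConfusionCounts) -> float:
    """Fraction of all samples correctly classified: sum(TP) / total."""
    return sum(counts.tp.values()) / counts.total


def metrics_report(counts: ConfusionCounts, ndigits: int = 3) -> pd.DataFrame:
    """Per-class metric table rounded for display, one row per class."""
    per_class = precision_recall_f1(counts)
    rows = []
    for c in counts.classes:
        m = per_class[c].rounded(ndigits)
        rows.append({"class": c, "precision": m.precision, "recall": m.recall, "f1": m.f1})
    return pd.DataFrame(rows, columns=["class", "precision", "recall", "f1"])


def write_metrics_report(
    counts: ConfusionCounts,
    csv_path: Optional[str | Path] = None,
    json_path: Optional[str | Path] = None,
) -> dict:
    """Emit the per-class report plus overall accuracy as CSV and/or JSON."""
    table = metrics_report(counts)
    acc_pct = round_half_up(overall_accuracy(counts) * 100, 2)
    payload = {
        "per_class": table.to_dict(orient="records"),
        "overall_accuracy_pct": acc_pct,
        "total": counts.total,
    }
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
    return payload
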