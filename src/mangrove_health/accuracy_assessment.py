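"""Confusion-matrix accuracy assessment for categorical classifications.

Orientation is fixed: rows are reference labels, columns are predicted
labels.  Producer accuracy (PA) of a class is the diagonal count over its
row total (omission-error complement), user accuracy (UA) the diagonal over
the column total (commission-error complement), and overall accuracy (OA)
the trace over the grand total.  Reports round to the nearest integer
percent (half up); unrounded values are kept in machine output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "AccuracyReport",
    "confusion_matrix",
    "producer_accuracy",
    "user_accuracy",
    "overall_accuracy",
    "accuracy_report",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows = reference classes, columns = predicted."""

    counts: np.ndarray
    class_order: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"counts must be square, got {self.counts.shape}")
        if len(self.class_order) != self.counts.shape[0]:
            raise ValueError("class_order length must match matrix size")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("confusion counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)
        self.class_order = tuple(self.class_order)
        self._index = {c: i for i, c in enumerate(self.class_order)}

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_total(self, cls) -> int:
        return int(self.counts[self._index[cls]].sum())

    def col_total(self, cls) -> int:
        return int(self.counts[:, self._index[cls]].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.class_order), columns=list(self.class_order)
        )


@dataclass
class AccuracyReport:
    """Per-class PA/UA and OA, in percent, with printed (rounded) forms."""

    class_order: tuple
    pa: dict
    ua: dict
    oa: float

    @property
    def pa_rounded(self) -> dict:
        return {c: _round_half_up(v) for c, v in self.pa.items() if not np.isnan(v)}

    @property
    def ua_rounded(self) -> dict:
        return {c: _round_half_up(v) for c, v in self.ua.items() if not np.isnan(v)}

    @property
    def oa_rounded(self) -> int:
        return _round_half_up(self.oa)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "PA_percent": [self.pa[c] for c in self.class_order],
                "UA_percent": [self.ua[c] for c in self.class_order],
            },
            index=list(self.class_order),
        )


def confusion_matrix(pairs, class_order) -> ConfusionMatrix:
    """Tabulate (reference, predicted) pairs into a count matrix.

    Labels outside *class_order* raise ``ValueError``.
    """
    class_order = tuple(class_order)
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for ref, pred in pairs:
        if ref not in index:
            raise ValueError(f"reference label {ref!r} not in class order")
        if pred not in index:
            raise ValueError(f"predicted label {pred!r} not in class order")
        counts[index[ref], index[pred]] += 1
    return ConfusionMatrix(counts=counts, class_order=class_order)


def producer_accuracy(cm: ConfusionMatrix, cls) -> float:
    """Percent of reference samples of *cls* classified correctly (NaN if the
    class has no reference samples)."""
    i = cm._index[cls]
    row = cm.counts[i].sum()
    if row == 0:
        return float("nan")
    return 100.0 * cm.counts[i, i] / row


def user_accuracy(cm: ConfusionMatrix, cls) -> float:
    """Percent of predictions of *cls* that are correct (NaN if never
    predicted)."""
    i = cm._index[cls]
    col = cm.counts[:, i].sum()
    if col == 0:
        return float("nan")
    return 100.0 * cm.counts[i, i] / col


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Percent of all samples on the diagonal: 100 × trace / total."""
    if cm.total == 0:
        raise ValueError("cannot compute overall accuracy of an empty matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def accuracy_report(cm: ConfusionMatrix) -> AccuracyReport:
    return AccuracyReport(
        class_order=cm.class_order,
        pa={c: producer_accuracy(cm, c) for c in cm.class_order},
        ua={c: user_accuracy(cm, c) for c in cm.class_order},
        oa=overall_accuracy(cm),
    )
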