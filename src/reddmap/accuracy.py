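"""Thematic accuracy assessment: confusion matrix, producer's/user's/overall
accuracy and the kappa coefficient.

The confusion matrix is oriented the way thematic-mapping error matrices
are printed: columns are the true (ground-truth ROI) classes, rows are the
classifier's predictions, with an extra top row for pixels the
post-classification chain left unclassified (label 0). Derived metrics:

* producer's accuracy (PA), per class: diagonal / column total — the
  probability a true pixel of the class is mapped correctly (omission
  complement);
* user's accuracy (UA), per class: diagonal / row total — the probability
  a pixel mapped as the class truly is it (commission complement);
* overall accuracy (OA): trace / grand total, the unclassified row
  counting in the total but contributing nothing to the trace;
* kappa: chance-corrected agreement, kappa = (p_o - p_e) / (1 - p_e) with
  p_o = OA and p_e = sum over named classes of row_total * col_total / N^2.
  The unclassified row has no matching column and therefore no term in
  p_e, but its pixels count in N and in row totals. Kappa can in principle
  be negative (agreement below chance), although thematic maps in practice
  score well above 0; negatives are reported as-is.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import ClassMap, ClassScheme, ROISet

log = logging.getLogger(__name__)


def _round_half_up(x: float, places: int = 2) -> float:
    x = float(x)
    if not np.isfinite(x):
        return x
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -places,
                                           rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """(K+1) x K pixel counts: row 0 = unclassified predictions, rows 1..K
    = predicted classes, columns 1..K = true classes."""

    counts: np.ndarray
    scheme: ClassScheme

    def __post_init__(self):
        counts = np.asarray(self.counts)
        k = len(self.scheme)
        if counts.shape != (k + 1, k):
            raise ValueError(
                f"expected shape {(k + 1, k)} for {k} classes, got "
                f"{counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)

    @property
    def n_classes(self) -> int:
        return len(self.scheme)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def diagonal(self) -> np.ndarray:
        """Correctly classified counts per class (prediction row c, truth col c)."""
        return np.array([self.counts[c, c - 1]
                         for c in range(1, self.n_classes + 1)])

    def row_total(self, class_id: int) -> int:
        return int(self.counts[class_id].sum())

    def col_total(self, class_id: int) -> int:
        return int(self.counts[:, class_id - 1].sum())

    def to_dataframe(self) -> pd.DataFrame:
        names = self.scheme.names
        return pd.DataFrame(self.counts, index=["Unclassified"] + names,
                            columns=names)

    def save_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="Predicted \\ True")


def build_confusion_matrix(predicted: ClassMap,
                           ground_truth: ROISet,
                           training: ROISet | None = None) -> ConfusionMatrix:
    """Count predictions against ground-truth ROI pixels.

    ``counts[r][c]`` is the number of ground-truth pixels of class c the
    map labels r (r = 0 collects unclassified predictions). If the training
    ROISet is supplied, any overlap with the ground truth is an error —
    scoring on training pixels inflates the assessment.
    """
    if training is not None and not ground_truth.is_disjoint_from(training):
        raise ValueError("ground-truth ROIs overlap the training ROIs")
    k = len(predicted.scheme)
    counts = np.zeros((k + 1, k), dtype=np.int64)
    for cid in range(1, k + 1):
        if ground_truth.count(cid) == 0:
            raise ValueError(
                f"ground truth has no pixels for class {cid} "
                f"({predicted.scheme.name_of(cid)})")
    for cid, coords in ground_truth.pixels.items():
        preds = predicted.labels[coords[:, 0], coords[:, 1]]
        counts[:, cid - 1] = np.bincount(preds, minlength=k + 1)
    return ConfusionMatrix(counts, predicted.scheme)


def producer_accuracy(cm: ConfusionMatrix, class_id: int) -> float:
    """Diagonal count over column total for one class."""
    col = cm.col_total(class_id)
    if col == 0:
        warnings.warn(f"class {class_id}: no ground-truth pixels, "
                      "producer's accuracy undefined", stacklevel=2)
        return float("nan")
    return cm.counts[class_id, class_id - 1] / col


def user_accuracy(cm: ConfusionMatrix, class_id: int) -> float:
    """Diagonal count over row total for one class."""
    row = cm.row_total(class_id)
    if row == 0:
        warnings.warn(f"class {class_id}: never predicted, "
                      "user's accuracy undefined", stacklevel=2)
        return float("nan")
    return cm.counts[class_id, class_id - 1] / row


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of ground-truth pixels classified correctly."""
    total = cm.grand_total
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(cm.diagonal().sum()) / total


def kappa_coefficient(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement between map and ground truth."""
    n = cm.grand_total
    if n == 0:
        raise ValueError("empty confusion matrix")
    p_o = overall_accuracy(cm)
    p_e = sum(cm.row_total(c) * cm.col_total(c)
              for c in range(1, cm.n_classes + 1)) / n ** 2
    if p_e >= 1.0:
        raise ValueError("degenerate matrix: expected agreement is 1")
    return (p_o - p_e) / (1 - p_e)


@dataclass
class AccuracyReport:
    """All assessment metrics for one classified map."""

    overall_accuracy: float
    kappa: float
    producer_accuracy: dict[int, float]
    user_accuracy: dict[int, float]
    scheme: ClassScheme
    grand_total: int

    def to_dataframe(self) -> pd.DataFrame:
        """Per-class table with PA/UA in percent, rounded half-up at 2 dp."""
        rows = []
        for c in self.scheme:
            rows.append({
                "class": c.name,
                "PA (%)": _round_half_up(100 * self.producer_accuracy[c.id]),
                "UA (%)": _round_half_up(100 * self.user_accuracy[c.id]),
            })
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        head = (f"overall accuracy: "
                f"{_round_half_up(100 * self.overall_accuracy):.2f}%   "
                f"kappa: {_round_half_up(self.kappa):.2f}   "
                f"(n = {self.grand_total} ground-truth pixels)")
        return head + "\n" + self.to_dataframe().to_string(index=False)

    def save_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df["OA (%)"] = _round_half_up(100 * self.overall_accuracy)
        df["kappa"] = _round_half_up(self.kappa)
        df.to_csv(path, index=False)


def accuracy_report(cm: ConfusionMatrix) -> AccuracyReport:
    """Assemble OA, kappa and per-class PA/UA from a confusion matrix."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pa = {c: producer_accuracy(cm, c) for c in range(1, cm.n_classes + 1)}
        ua = {c: user_accuracy(cm, c) for c in range(1, cm.n_classes + 1)}
    return AccuracyReport(
        overall_accuracy=overall_accuracy(cm),
        kappa=kappa_coefficient(cm),
        producer_accuracy=pa,
        user_accuracy=ua,
        scheme=cm.scheme,
        grand_total=cm.grand_total,
    )
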