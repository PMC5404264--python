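"""Confusion matrices, accuracy, Cohen's kappa and detection agreement.

Accuracy is reported as a percentage rounded half-up to one decimal and
kappa to two decimals, matching the convention of the benchmark tables
this layer reproduces.  The 4 -> 2 class collapse merges Normal/UDH into
Benign and LG/HG-DCIS into DCIS by quadrant sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import BENIGN_DCIS_MAP, BINARY_CLASSES, CLASSES, DataError


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (schoolbook), e.g. 0.345 -> 0.35 at 2."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows = actual classes, columns = predicted."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        k = len(self.classes)
        if c.shape != (k, k):
            raise DataError("counts must be K x K for K class names")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            c = c.astype(np.int64)
            if np.any(c < 0):
                raise DataError("counts must be non-negative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion(
    actual: Sequence[str],
    predicted: Sequence[str],
    classes: tuple[str, ...] = CLASSES,
) -> ConfusionMatrix:
    """Tally a confusion matrix over paired labels."""
    actual = list(actual)
    predicted = list(predicted)
    if len(actual) != len(predicted):
        raise DataError("actual and predicted lengths differ")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for a, p in zip(actual, predicted):
        if a not in index or p not in index:
            raise DataError(f"unknown label {a if a not in index else p!r}")
        counts[index[a], index[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def accuracy(cm: ConfusionMatrix, decimals: int | None = 1) -> float:
    """Overall accuracy in percent (trace / total x 100)."""
    if cm.total == 0:
        raise DataError("empty confusion matrix")
    value = 100.0 * float(np.trace(cm.counts)) / cm.total
    return value if decimals is None else round_half_up(value, decimals)


def cohen_kappa(cm: ConfusionMatrix, decimals: int | None = 2) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e), p_e from the marginals."""
    n = cm.total
    if n == 0:
        raise DataError("empty confusion matrix")
    po = float(np.trace(cm.counts)) / n
    pe = float((cm.counts.sum(axis=0) * cm.counts.sum(axis=1)).sum()) / n**2
    if pe >= 1.0:
        raise DataError("degenerate marginals: p_e = 1")
    value = (po - pe) / (1.0 - pe)
    return value if decimals is None else round_half_up(value, decimals)


def collapse_classes(
    cm: ConfusionMatrix,
    mapping: Mapping[str, str] = BENIGN_DCIS_MAP,
    order: tuple[str, ...] | None = None,
) -> ConfusionMatrix:
    """Merge classes by a label mapping (quadrant sums, totals preserved)."""
    missing = set(cm.classes) - set(mapping)
    if missing:
        raise DataError(f"mapping does not cover {sorted(missing)}")
    if order is None:
        order = tuple(dict.fromkeys(mapping[c] for c in cm.classes))
    index = {c: i for i, c in enumerate(order)}
    out = np.zeros((len(order), len(order)), dtype=np.int64)
    for i, a in enumerate(cm.classes):
        for j, p in enumerate(cm.classes):
            out[index[mapping[a]], index[mapping[p]]] += cm.counts[i, j]
    return ConfusionMatrix(out, tuple(order))


def detection_agreement(detected: Sequence[float], reference: Sequence[float]) -> float:
    """Mean per-ROI count agreement in percent.

    Per ROI: 100 x (1 - |detected - reference| / reference), clipped at 0;
    the result is the mean over ROIs.  A reconstruction of a count-based
    segmentation-accuracy measure; reference counts must be positive.
    """
    d = np.asarray(detected, dtype=float)
    r = np.asarray(reference, dtype=float)
    if d.shape != r.shape or d.size == 0:
        raise DataError("detected/reference must be equal-length, non-empty")
    if np.any(r <= 0):
        raise DataError("reference counts must be positive")
    if np.any(d < 0):
        raise DataError("detected counts must be non-negative")
    per_roi = np.clip(100.0 * (1.0 - np.abs(d - r) / r), 0.0, None)
    return float(per_roi.mean())


def metrics_pair(cm: ConfusionMatrix) -> dict:
    """Accuracy/kappa for a 4-class matrix and its Benign-vs-DCIS collapse."""
    out = {
        "accuracy_4class": accuracy(cm),
        "kappa_4class": cohen_kappa(cm),
    }
    if tuple(cm.classes) == CLASSES:
        two = collapse_classes(cm, BENIGN_DCIS_MAP, BINARY_CLASSES)
        out["accuracy_2class"] = accuracy(two)
        out["kappa_2class"] = cohen_kappa(two)
    return out
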