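"""Cell -> duct -> patient aggregation of classifier decisions.

Myoepithelial cells within a lesion are heterogeneous, so single-cell
predictions are aggregated: per-duct and per-patient class proportions are
computed from the cell-level labels, and each group is assigned a label by
a weighted majority decision (argmax of proportion x class weight).  The
default weights are the reciprocal training-set class frequencies, which
counteract the imbalanced nucleus counts across histotypes; uniform
weights are available as an alternative.  Ties resolve to the more severe
class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon as _draw_polygon

from .core import CLASS_COLORS, CLASSES, DataError, NucleusContour


@dataclass
class GroupSummary:
    """Class proportions and decision of one duct or patient."""

    group_id: str
    case_id: str
    n_cells: int
    proportions: np.ndarray  # aligned with `classes`
    classes: tuple[str, ...] = CLASSES
    decided: str | None = None
    decision_score: float = float("nan")

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (len(self.classes),) or np.any(p < 0):
            raise DataError("proportions must be non-negative, one per class")
        if abs(p.sum() - 1.0) > 1e-9:
            raise DataError("proportions must sum to 1")
        if self.n_cells < 1:
            raise DataError("a group needs at least one cell")
        self.proportions = p


def group_proportions(
    predictions: pd.DataFrame,
    group_col: str,
    label_col: str = "predicted",
    case_col: str = "case_id",
    classes: tuple[str, ...] = CLASSES,
) -> list[GroupSummary]:
    """Per-group normalized class histograms of cell-level predictions."""
    if group_col not in predictions.columns:
        raise DataError(f"missing group column {group_col!r}")
    out = []
    for gid, grp in predictions.groupby(group_col, sort=True):
        n = len(grp)
        if n == 0:  # defensive: groupby never yields empty groups
            warnings.warn(f"group {gid!r} has no cells; skipped", stacklevel=2)
            continue
        counts = np.array([(grp[label_col] == c).sum() for c in classes], dtype=float)
        case = str(grp[case_col].iloc[0]) if case_col in grp.columns else ""
        out.append(
            GroupSummary(
                group_id=str(gid),
                case_id=case,
                n_cells=n,
                proportions=counts / n,
                classes=classes,
            )
        )
    return out


def weighted_majority(summary: GroupSummary, weights) -> str:
    """Weighted majority decision: argmax of proportion x weight.

    Ties go to the more severe class (Normal < UDH < LG-DCIS < HG-DCIS).
    The decision and its winning score are recorded on the summary.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(summary.classes),) or np.any(w < 0):
        raise DataError("weights must be non-negative, one per class")
    if not np.any(w > 0):
        raise DataError("weights must not all be zero")
    scores = summary.proportions * w
    best = scores.max()
    # Last argmax = most severe among ties (classes are in severity order).
    winner = int(np.flatnonzero(scores >= best - 1e-12)[-1])
    summary.decided = summary.classes[winner]
    summary.decision_score = float(best)
    return summary.decided


def inverse_frequency_weights(labels, classes: tuple[str, ...] = CLASSES) -> np.ndarray:
    """Reciprocal class-frequency weights, normalized to sum 1."""
    labels = np.asarray(labels)
    counts = np.array([(labels == c).sum() for c in classes], dtype=float)
    if not np.any(counts > 0):
        raise DataError("no cells of any known class")
    if np.any(counts == 0):
        # A class absent from training can never be predicted; its weight
        # is irrelevant and pinned to 0.
        warnings.warn(
            f"classes absent from training get zero weight: "
            f"{[c for c, n in zip(classes, counts) if n == 0]}",
            stacklevel=2,
        )
    w = np.where(counts > 0, 1.0 / np.where(counts > 0, counts, 1.0), 0.0)
    return w / w.sum()


def uniform_weights(classes: tuple[str, ...] = CLASSES) -> np.ndarray:
    return np.full(len(classes), 1.0 / len(classes))


def decide_all(summaries, weights) -> list[str]:
    return [weighted_majority(s, weights) for s in summaries]


def summaries_table(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "group_id": s.group_id,
            "case_id": s.case_id,
            "n_cells": s.n_cells,
            "decided": s.decided,
            "decision_score": s.decision_score,
        }
        row.update({f"prop_{c}": p for c, p in zip(s.classes, s.proportions)})
        rows.append(row)
    return pd.DataFrame(rows)


def heterogeneity_overlay(
    image: np.ndarray,
    contours: list[NucleusContour],
    labels: list[str],
) -> np.ndarray:
    """Paint predicted-class colors over the nuclei of a tile.

    Returns a copy of the RGB image with each contour filled with the
    fixed class color (dark blue Normal, light blue UDH, light red
    LG-DCIS, dark red HG-DCIS).
    """
    if len(contours) != len(labels):
        raise DataError("contours and labels differ in length")
    out = np.asarray(image).copy()
    for contour, lab in zip(contours, labels):
        if lab not in CLASS_COLORS:
            raise DataError(f"unknown class label {lab!r}")
        rr, cc = _draw_polygon(
            contour.vertices[:, 0], contour.vertices[:, 1], out.shape[:2]
        )
        out[rr, cc] = CLASS_COLORS[lab]
    return out
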