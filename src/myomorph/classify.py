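"""Nucleus classification: normalization, F-score ranking, RBF-SVM.

Features are mean-centered and variance-scaled using training-set
statistics only; hyper-parameters (C, gamma) of the RBF kernel are chosen
by stratified cross-validated grid search over the canonical exponential
grid; multi-class handling is one-vs-one voting.  Two split protocols are
provided: the 70/30 random cell split (5 repetitions) and the
leave-one-case-out 21/1 protocol (10 repetitions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .core import DataError
from .morphometry import FEATURE_MANIFEST

#: Canonical exponential grid: C in 2^-5..2^15, gamma in 2^-15..2^3,
#: powers of 4.
DEFAULT_GRID: dict[str, tuple[float, ...]] = {
    "C": tuple(2.0**e for e in range(-5, 16, 2)),
    "gamma": tuple(2.0**e for e in range(-15, 4, 2)),
}


@dataclass
class NormalizationStats:
    feature_names: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray  # training SD, 1 where SD == 0

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in table.columns]
        if missing:
            raise DataError(f"missing feature column {missing[0]!r}")
        x = table[list(self.feature_names)].to_numpy(dtype=float)
        return (x - self.mean) / self.scale


def normalize(
    train: pd.DataFrame,
    test: pd.DataFrame | None = None,
    feature_names=FEATURE_MANIFEST,
) -> tuple[np.ndarray, np.ndarray | None, NormalizationStats]:
    """Z-score features with training statistics only.

    Zero-variance features pass through unscaled (scale 1) so constant
    columns stay finite.
    """
    if len(train) == 0:
        raise DataError("training table is empty")
    names = tuple(feature_names)
    x = train[list(names)].to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    stats = NormalizationStats(names, mean, scale)
    return stats.transform(train), (None if test is None else stats.transform(test)), stats


@dataclass
class FeatureRanking:
    """Per-feature multi-class F-scores, descending order."""

    feature_names: tuple[str, ...]
    scores: np.ndarray
    order: tuple[str, ...]  # names sorted by descending score

    def top(self, k: int) -> tuple[str, ...]:
        return self.order[:k]


def fscore_rank(
    table: pd.DataFrame, labels, feature_names=FEATURE_MANIFEST
) -> FeatureRanking:
    """Rank features by the multi-class F-score discrimination measure.

    F = sum_c (mean_c - mean)^2 / sum_c var_c, with the within-class
    variances computed with n_c - 1 denominators.  Perfect separation with
    zero within-class variance yields +inf; identical class means yield 0.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise DataError("F-score needs at least two classes")
    names = tuple(feature_names)
    x = table[list(names)].to_numpy(dtype=float)
    grand = x.mean(axis=0)
    num = np.zeros(len(names))
    den = np.zeros(len(names))
    for c in classes:
        xc = x[labels == c]
        num += (xc.mean(axis=0) - grand) ** 2
        if len(xc) > 1:
            den += xc.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(den > 0, num / den, np.where(num > 0, np.inf, 0.0))
    order = tuple(np.asarray(names)[np.argsort(-scores, kind="stable")])
    return FeatureRanking(names, scores, order)


@dataclass
class TrainedClassifier:
    """A fitted RBF-SVM with its training-set normalization statistics."""

    stats: NormalizationStats
    model: SVC
    C: float
    gamma: float
    cv_accuracy: float
    classes: tuple[str, ...]

    @property
    def selected_features(self) -> tuple[str, ...]:
        return self.stats.feature_names


def tune_and_train(
    train: pd.DataFrame,
    labels,
    grid: dict | None = None,
    folds: int = 5,
    seed: int = 0,
    feature_names=FEATURE_MANIFEST,
) -> TrainedClassifier:
    """Grid-search (C, gamma) by stratified CV and refit on all rows.

    Ties in CV accuracy resolve to the smallest C, then the smallest
    gamma.  Classes with fewer members than ``folds`` reduce the fold
    count with a warning.
    """
    grid = grid or DEFAULT_GRID
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise DataError("training needs at least two classes")
    if not grid.get("C") or not grid.get("gamma"):
        raise DataError("grid must provide C and gamma values")
    x, _, stats = normalize(train, feature_names=feature_names)
    n_folds = int(min(folds, counts.min()))
    if n_folds < folds:
        warnings.warn(
            f"reducing CV folds from {folds} to {n_folds}: smallest class has "
            f"{counts.min()} members",
            stacklevel=2,
        )
    n_folds = max(n_folds, 2)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, labels))
    best = (-1.0, None, None)
    for C in sorted(grid["C"]):
        for gamma in sorted(grid["gamma"]):
            accs = []
            for tr, te in splits:
                svc = SVC(kernel="rbf", C=C, gamma=gamma)
                svc.fit(x[tr], labels[tr])
                accs.append(float((svc.predict(x[te]) == labels[te]).mean()))
            acc = float(np.mean(accs))
            if acc > best[0]:  # strict: ties keep the earlier (smaller) pair
                best = (acc, C, gamma)
    cv_acc, C, gamma = best
    model = SVC(kernel="rbf", C=C, gamma=gamma)
    model.fit(x, labels)
    return TrainedClassifier(
        stats=stats,
        model=model,
        C=float(C),
        gamma=float(gamma),
        cv_accuracy=cv_acc,
        classes=tuple(model.classes_),
    )


def predict(model: TrainedClassifier, rows: pd.DataFrame) -> np.ndarray:
    """Predict histotype labels for feature rows."""
    x = model.stats.transform(rows)
    return model.model.predict(x)


@dataclass(frozen=True)
class SplitSpec:
    """Protocol of repeated train/test splits."""

    mode: str = "random_cell_70_30"  # or "leave_one_case_out_21_1"
    repetitions: int = 5
    seed: int = 0
    label_col: str = "histotype"
    case_col: str = "case_id"

    def __post_init__(self) -> None:
        if self.mode not in ("random_cell_70_30", "leave_one_case_out_21_1"):
            raise DataError(f"unknown split mode {self.mode!r}")
        if self.repetitions < 1:
            raise DataError("repetitions must be >= 1")


def make_splits(
    table: pd.DataFrame, spec: SplitSpec
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate (train_index, test_index) pairs of positional indices.

    Cell mode: stratified 70/30 row splits, one per repetition.  Case
    mode: one whole case per repetition goes to test, cases sampled
    without replacement across repetitions when possible.
    """
    if len(table) == 0:
        raise DataError("dataset is empty")
    idx = np.arange(len(table))
    out = []
    if spec.mode == "random_cell_70_30":
        y = table[spec.label_col].to_numpy()
        for rep in range(spec.repetitions):
            rep_seed = int(
                np.random.SeedSequence([spec.seed, rep]).generate_state(1)[0] % (2**31)
            )
            tr, te = train_test_split(
                idx, test_size=0.3, stratify=y, random_state=rep_seed
            )
            out.append((np.sort(tr), np.sort(te)))
    else:
        cases = np.array(sorted(table[spec.case_col].unique()))
        if len(cases) < 2:
            raise DataError("case mode needs at least two cases")
        rng = np.random.default_rng(spec.seed)
        replace = spec.repetitions > len(cases)
        chosen = rng.choice(cases, size=spec.repetitions, replace=replace)
        case_col = table[spec.case_col].to_numpy()
        for test_case in chosen:
            te = idx[case_col == test_case]
            tr = idx[case_col != test_case]
            out.append((tr, te))
    return out
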