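"""Per-nucleus morphometry: the 32-feature shape/texture/intensity vector.

The feature manifest is fixed at 13 shape descriptors (moment-ellipse axes,
rotating-calipers Feret diameters, solidity, form factor, ...), 13 Haralick
texture features computed from a masked grey-level co-occurrence matrix
(GLCM), and 6 first-order intensity statistics of the nuclear stain
channel.  Quantization for the GLCM is per-nucleus min-max, which makes the
texture features invariant to affine intensity rescaling of the patch.

The size-trim rule drops the 10% largest and 10% smallest nuclei per ROI
before analysis, absorbing contour noise such as touching nuclei merged
into one contour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from skimage.measure import regionprops

from .core import DataError, NucleusContour

SHAPE_FEATURES = (
    "Area",
    "Perimeter",
    "MajorAxisLength",
    "MinorAxisLength",
    "MinorMajorRatio",
    "MinFeretDiameter",
    "MaxFeretDiameter",
    "Eccentricity",
    "Solidity",
    "Extent",
    "FormFactor",
    "Compactness",
    "EquivalentDiameter",
)

HARALICK_FEATURES = (
    "AngularSecondMoment",
    "Contrast",
    "Correlation",
    "SumOfSquaresVariance",
    "InverseDifferenceMoment",
    "SumAverage",
    "SumVariance",
    "SumEntropy",
    "Entropy",
    "DifferenceVariance",
    "DifferenceEntropy",
    "InfoMeasureCorrelation1",
    "InfoMeasureCorrelation2",
)

INTENSITY_FEATURES = (
    "IntensityMean",
    "IntensitySD",
    "IntensityMin",
    "IntensityMax",
    "IntensityMedian",
    "IntensityMAD",
)

#: The canonical 32-feature manifest, in table column order.
FEATURE_MANIFEST: tuple[str, ...] = SHAPE_FEATURES + HARALICK_FEATURES + INTENSITY_FEATURES
assert len(FEATURE_MANIFEST) == 32

ID_COLUMNS = ("cell_id", "roi_id", "duct_id", "case_id", "histotype")

#: Default GLCM quantization and offsets: 8 grey levels, the 4 distance-1
#: directions, averaged.
DEFAULT_GLCM_LEVELS = 8
DEFAULT_GLCM_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class FeatureRecord:
    """The 32-value morphometric vector of one nucleus, with identity."""

    cell_id: str
    roi_id: str
    duct_id: str
    case_id: str
    histotype: str
    features: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(FEATURE_MANIFEST) - set(self.features)
        if missing:
            raise DataError(f"feature record missing {sorted(missing)}")

    def vector(self) -> np.ndarray:
        return np.array([self.features[name] for name in FEATURE_MANIFEST])

    def to_row(self) -> dict:
        row = {
            "cell_id": self.cell_id,
            "roi_id": self.roi_id,
            "duct_id": self.duct_id,
            "case_id": self.case_id,
            "histotype": self.histotype,
        }
        row.update({name: self.features[name] for name in FEATURE_MANIFEST})
        return row


def features_table(records) -> pd.DataFrame:
    """Stack feature records into the canonical per-nucleus table."""
    return pd.DataFrame(
        [r.to_row() for r in records], columns=list(ID_COLUMNS) + list(FEATURE_MANIFEST)
    )


def _feret_diameters(mask: np.ndarray) -> tuple[float, float]:
    """Min and max caliper width via rotating calipers on pixel corners."""
    pts = np.argwhere(mask)
    corners = np.concatenate(
        [pts + np.array(d) for d in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
    )
    if len(np.unique(corners, axis=0)) < 3:
        return 1.0, 1.0
    try:
        hull = ConvexHull(corners)
    except Exception:  # degenerate (collinear) point sets
        d = np.linalg.norm(corners.max(0) - corners.min(0))
        return 0.0, float(d)
    hp = corners[hull.vertices]
    # Max Feret: largest pairwise distance between hull vertices.
    diff = hp[:, None, :] - hp[None, :, :]
    max_feret = float(np.sqrt((diff**2).sum(-1)).max())
    # Min Feret: for every hull edge, the farthest vertex distance to the
    # edge's supporting line; the minimum over edges is the caliper width.
    widths = []
    n = len(hp)
    for i in range(n):
        a, b = hp[i], hp[(i + 1) % n]
        e = b - a
        norm = np.linalg.norm(e)
        if norm == 0:
            continue
        normal = np.array([-e[1], e[0]]) / norm
        widths.append(np.abs((hp - a) @ normal).max())
    min_feret = float(min(widths)) if widths else max_feret
    return min_feret, max_feret


def shape_features(mask: np.ndarray) -> dict[str, float]:
    """Shape descriptors of a binary nucleus mask."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise DataError("empty mask")
    rp = regionprops(mask.astype(np.uint8))[0]
    area = float(rp.area)
    perimeter = float(rp.perimeter)
    major = float(rp.axis_major_length)
    minor = float(rp.axis_minor_length)
    ratio = min(minor / major, 1.0) if major > 0 else 1.0
    min_feret, max_feret = _feret_diameters(mask)
    if perimeter > 0:
        form_factor = 4 * math.pi * area / perimeter**2
        compactness = perimeter**2 / (4 * math.pi * area)
    else:  # single-pixel masks: define the dimensionless ratios as circular
        form_factor = 1.0
        compactness = 1.0
    return {
        "Area": area,
        "Perimeter": perimeter,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "MinorMajorRatio": ratio,
        "MinFeretDiameter": min_feret,
        "MaxFeretDiameter": max_feret,
        "Eccentricity": float(rp.eccentricity),
        "Solidity": float(rp.solidity),
        "Extent": float(rp.extent),
        "FormFactor": form_factor,
        "Compactness": compactness,
        "EquivalentDiameter": 2.0 * math.sqrt(area / math.pi),
    }


def glcm(
    patch: np.ndarray,
    mask: np.ndarray,
    levels: int = DEFAULT_GLCM_LEVELS,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_GLCM_OFFSETS,
) -> np.ndarray:
    """Masked, symmetric, normalized grey-level co-occurrence matrix.

    The patch is quantized per nucleus (min-max over mask pixels) to
    ``levels`` grey values; co-occurrences are accumulated only over pixel
    pairs that both lie inside the mask, per offset, symmetrized, and the
    per-offset matrices averaged.
    """
    patch = np.asarray(patch, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if patch.shape != mask.shape:
        raise DataError("patch and mask shapes differ")
    if not mask.any():
        raise DataError("empty mask")
    vals = patch[mask]
    vmin, vmax = float(vals.min()), float(vals.max())
    q = np.zeros(patch.shape, dtype=np.intp)
    if vmax > vmin:
        q[mask] = np.minimum(
            ((patch[mask] - vmin) / (vmax - vmin) * levels).astype(np.intp), levels - 1
        )
    mats = []
    for dr, dc in offsets:
        p = np.zeros((levels, levels))
        h, w = patch.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a_idx = (slice(r0, r1), slice(c0, c1))
        b_idx = (slice(r0 + dr, r1 + dr), slice(c0 + dc, c1 + dc))
        valid = mask[a_idx] & mask[b_idx]
        if not valid.any():
            continue
        i = q[a_idx][valid]
        j = q[b_idx][valid]
        np.add.at(p, (i, j), 1.0)
        p = p + p.T  # symmetric
        mats.append(p / p.sum())
    if not mats:  # isolated pixels: all mass at the single quantized level
        p = np.zeros((levels, levels))
        p[0, 0] = 1.0
        return p
    return np.mean(mats, axis=0)


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def haralick_features(p: np.ndarray) -> dict[str, float]:
    """The 13 Haralick texture features of a normalized symmetric GLCM.

    Natural logarithms throughout.  Degenerate single-level matrices give
    Contrast 0, InverseDifferenceMoment 1, entropies 0 and Correlation 0
    (the correlation is undefined at zero variance and pinned to 0).
    """
    g = p.shape[0]
    i, j = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    px = p.sum(axis=1)
    mu = float((np.arange(g) * px).sum())
    var = float(((np.arange(g) - mu) ** 2 * px).sum())

    asm = float((p**2).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())
    entropy = _entropy(p)

    correlation = 0.0
    if var > 0:
        correlation = float(((i - mu) * (j - mu) * p).sum() / var)

    # p_{x+y}(k), k = 0..2G-2 and p_{|x-y|}(k), k = 0..G-1
    psum = np.zeros(2 * g - 1)
    np.add.at(psum, (i + j).ravel(), p.ravel())
    pdiff = np.zeros(g)
    np.add.at(pdiff, np.abs(i - j).ravel(), p.ravel())

    ks = np.arange(2 * g - 1)
    sum_average = float((ks * psum).sum())
    sum_entropy = _entropy(psum)
    sum_variance = float(((ks - sum_average) ** 2 * psum).sum())
    kd = np.arange(g)
    diff_entropy = _entropy(pdiff)
    diff_mean = float((kd * pdiff).sum())
    diff_variance = float(((kd - diff_mean) ** 2 * pdiff).sum())

    hx = _entropy(px)
    hxy = entropy
    outer = px[:, None] * px[None, :]
    nz = (p > 0) & (outer > 0)
    hxy1 = float(-(p[nz] * np.log(outer[nz])).sum())
    nz2 = outer > 0
    hxy2 = float(-(outer[nz2] * np.log(outer[nz2])).sum())
    imc1 = (hxy - hxy1) / max(hx, 1e-12) if hx > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    return {
        "AngularSecondMoment": asm,
        "Contrast": contrast,
        "Correlation": correlation,
        "SumOfSquaresVariance": var,
        "InverseDifferenceMoment": idm,
        "SumAverage": sum_average,
        "SumVariance": sum_variance,
        "SumEntropy": sum_entropy,
        "Entropy": entropy,
        "DifferenceVariance": diff_variance,
        "DifferenceEntropy": diff_entropy,
        "InfoMeasureCorrelation1": imc1,
        "InfoMeasureCorrelation2": imc2,
    }


def glcm_features(
    patch: np.ndarray,
    mask: np.ndarray,
    levels: int = DEFAULT_GLCM_LEVELS,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_GLCM_OFFSETS,
) -> dict[str, float]:
    """Haralick sub-vector of a masked patch."""
    return haralick_features(glcm(patch, mask, levels, offsets))


def intensity_features(patch: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """First-order statistics of the nuclear channel inside the mask."""
    vals = np.asarray(patch, dtype=float)[np.asarray(mask).astype(bool)]
    if vals.size == 0:
        raise DataError("empty mask")
    med = float(np.median(vals))
    return {
        "IntensityMean": float(vals.mean()),
        "IntensitySD": float(vals.std()),
        "IntensityMin": float(vals.min()),
        "IntensityMax": float(vals.max()),
        "IntensityMedian": med,
        "IntensityMAD": float(np.median(np.abs(vals - med))),
    }


def feature_vector(
    contour: NucleusContour,
    channel: np.ndarray,
    cell_id: str = "",
    roi_id: str = "",
    duct_id: str = "",
    case_id: str = "",
    histotype: str = "",
) -> FeatureRecord:
    """Measure the full 32-feature vector of one nucleus.

    ``channel`` is the grey-level nuclear stain map of the source tile
    (hematoxylin projection for HE, DAB projection for p63).
    """
    channel = np.asarray(channel, dtype=float)
    mask = contour.mask(channel.shape)
    if not mask.any():
        raise DataError("contour rasterizes to an empty mask")
    # Work on the bounding box for speed.
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    sub_mask = mask[sl]
    sub_patch = channel[sl]
    feats = {}
    feats.update(shape_features(sub_mask))
    feats.update(glcm_features(sub_patch, sub_mask))
    feats.update(intensity_features(sub_patch, sub_mask))
    return FeatureRecord(cell_id, roi_id, duct_id, case_id, histotype, feats)


def trim_by_size(
    table: pd.DataFrame,
    fraction: float = 0.10,
    size_feature: str = "Area",
    group_col: str = "roi_id",
) -> pd.DataFrame:
    """Drop the largest and smallest ``fraction`` of nuclei per ROI.

    Within each group, floor(fraction * n) rows are removed from each end
    of the ``size_feature`` ranking (stable ties); surviving rows keep
    their original order.  ``fraction`` must lie in [0, 0.5).
    """
    if not (0.0 <= fraction < 0.5):
        raise DataError("fraction must be in [0, 0.5)")
    if size_feature not in table.columns:
        raise DataError(f"missing size feature column {size_feature!r}")
    if fraction == 0.0 or table.empty:
        return table.copy()
    keep_masks = []
    for _, grp in table.groupby(group_col, sort=False):
        n = len(grp)
        k = int(np.floor(fraction * n))
        order = np.argsort(grp[size_feature].to_numpy(), kind="stable")
        kept = np.ones(n, dtype=bool)
        if k > 0:
            kept[order[:k]] = False
            kept[order[-k:]] = False
        keep_masks.append(pd.Series(kept, index=grp.index))
    keep = pd.concat(keep_masks).reindex(table.index)
    return table[keep.to_numpy()].copy()
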