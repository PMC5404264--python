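"""p63 nucleus segmentation: trainable random-forest pixel classifier.

p63 is a nuclear myoepithelial marker developed with DAB (brown) over a
hematoxylin counterstain, so myoepithelial nuclei are the only brown
objects in the tile.  A random-forest classifier over per-pixel color and
multi-scale derivative features (an Ilastik-style recipe) is trained once
on a labeled DCIS ROI and applied to all remaining ROIs; morphological
post-processing turns the probability map into nucleus contours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import (
    binary_fill_holes,
    gaussian_filter,
    gaussian_gradient_magnitude,
    gaussian_laplace,
)
from skimage.measure import find_contours, label as cc_label, regionprops
from sklearn.ensemble import RandomForestClassifier

from .core import DataError, NucleusContour, RoiImage

#: Default feature scales in pixels.
DEFAULT_SCALES: tuple[float, ...] = (1.0, 2.5, 5.0)

#: Per-scale derivative features: smoothed value, gradient magnitude,
#: Laplacian of Gaussian.
_DERIVATIVES_PER_SCALE = 3


def pixel_features(
    image: np.ndarray | RoiImage, scales: tuple[float, ...] = DEFAULT_SCALES
) -> np.ndarray:
    """Per-pixel feature stack: raw RGB plus, per scale and channel, the
    Gaussian-smoothed value, gradient magnitude and Laplacian.

    Stack depth is ``channels * (1 + 3 * len(scales))``.
    """
    if len(scales) == 0:
        raise DataError("scales must be non-empty")
    pixels = image.pixels if isinstance(image, RoiImage) else np.asarray(image)
    img = pixels.astype(np.float32) / 255.0
    if img.ndim == 2:
        img = img[..., None]
    layers = [img[..., ch] for ch in range(img.shape[2])]
    for s in scales:
        for ch in range(img.shape[2]):
            band = img[..., ch]
            layers.append(gaussian_filter(band, s))
            layers.append(gaussian_gradient_magnitude(band, s))
            layers.append(gaussian_laplace(band, s))
    return np.stack(layers, axis=-1).astype(np.float32)


@dataclass
class PixelClassifier:
    """Trained per-pixel nucleus/background classifier.

    Maps a pixel-feature vector to a nucleus probability in [0, 1];
    deterministic for a fixed training seed.
    """

    scales: tuple[float, ...]
    model: RandomForestClassifier
    train_accuracy: float
    training_roi: str = ""

    def probability_map(self, image: np.ndarray | RoiImage) -> np.ndarray:
        feats = pixel_features(image, self.scales)
        flat = feats.reshape(-1, feats.shape[-1])
        proba = self.model.predict_proba(flat)[:, self.model.classes_.tolist().index(1)]
        return proba.reshape(feats.shape[:2])


def train_pixel_classifier(
    image: np.ndarray | RoiImage,
    label_mask: np.ndarray,
    seed: int = 0,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    n_estimators: int = 100,
    max_samples_per_class: int = 20000,
    training_roi: str = "",
) -> PixelClassifier:
    """Train the pixel classifier on sparsely labeled pixels.

    ``label_mask``: 0 = unlabeled, 1 = nucleus, 2 = background.  Only
    labeled pixels are used (subsampled per class for speed); both classes
    must be present.
    """
    label_mask = np.asarray(label_mask)
    feats = pixel_features(image, scales)
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for cls, target in ((1, 1), (2, 0)):
        idx = np.flatnonzero(label_mask.ravel() == cls)
        if len(idx) > max_samples_per_class:
            idx = rng.choice(idx, size=max_samples_per_class, replace=False)
        xs.append(feats.reshape(-1, feats.shape[-1])[idx])
        ys.append(np.full(len(idx), target))
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(np.unique(y)) < 2 or len(y) == 0:
        raise DataError("label mask must contain both nucleus and background")
    model = RandomForestClassifier(
        n_estimators=n_estimators,
        random_state=seed,
        n_jobs=1,
        min_samples_leaf=2,
    )
    model.fit(X, y)
    acc = float(model.score(X, y))
    return PixelClassifier(
        scales=tuple(scales), model=model, train_accuracy=acc, training_roi=training_roi
    )


def label_mask_from_truth(truth_labels: np.ndarray, margin: int = 3) -> np.ndarray:
    """Build a sparse training label mask from a ground-truth label image.

    Nucleus pixels (1) are the eroded truth nuclei; background pixels (2)
    are everything outside the dilated nuclei; a ``margin`` band around
    each nucleus stays unlabeled (0), mimicking sparse interactive brush
    labels that avoid ambiguous boundaries.
    """
    from scipy.ndimage import binary_dilation, binary_erosion

    fg = np.asarray(truth_labels) > 0
    core = binary_erosion(fg, iterations=1)
    far = ~binary_dilation(fg, iterations=margin)
    out = np.zeros(fg.shape, dtype=np.uint8)
    out[core] = 1
    out[far] = 2
    return out


@dataclass(frozen=True)
class P63SegmentationParams:
    prob_threshold: float = 0.5
    min_area_px: float = 30.0


def segment_p63_roi(
    image: np.ndarray | RoiImage,
    classifier: PixelClassifier,
    exclusion_mask: np.ndarray | None = None,
    params: P63SegmentationParams | None = None,
) -> list[NucleusContour]:
    """Segment myoepithelial nuclei on a p63 tile.

    probability map -> threshold -> hole fill -> connected components ->
    drop components below ``min_area_px`` or with centroid inside the
    exclusion mask -> boundary polygon per component.
    """
    params = params or P63SegmentationParams()
    prob = classifier.probability_map(image)
    binary = prob >= params.prob_threshold
    if binary.any():
        binary = binary_fill_holes(binary)
    labels = cc_label(binary, connectivity=2)
    contours: list[NucleusContour] = []
    for region in regionprops(labels):
        if region.area < params.min_area_px:
            continue
        cy, cx = region.centroid
        if exclusion_mask is not None and exclusion_mask[int(round(cy)), int(round(cx))]:
            continue
        rmin, cmin, rmax, cmax = region.bbox
        patch = np.pad(region.image, 1)
        paths = find_contours(patch.astype(float), 0.5)
        if not paths:
            continue
        boundary = max(paths, key=len)
        verts = boundary[:-1] + np.array([rmin - 1, cmin - 1])
        if len(verts) < 3:
            continue
        contours.append(
            NucleusContour(vertices=verts, label=len(contours) + 1)
        )
    return contours
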