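"""Color-to-stain transformation shared by both segmentation paths.

Histological stains mix multiplicatively in transmitted light, so analysis
happens in optical-density (OD) space where Beer-Lambert mixing becomes
linear: each pixel's OD vector is a non-negative combination of per-stain
unit "color" vectors (hematoxylin, eosin, DAB).  The module converts RGB
tiles to OD, estimates the two dominant stain vectors of a tile from the
principal plane of its high-OD pixels, and projects OD maps onto a stain
vector to obtain a grey-level map (e.g. the hematoxylin map driving nucleus
detection in HE images).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DataError


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


#: Reference OD color vectors (Ruifrok-Johnston values), unit norm.
HEMATOXYLIN_RGB_OD = _unit([0.650, 0.704, 0.286])
EOSIN_RGB_OD = _unit([0.092, 0.954, 0.283])
DAB_RGB_OD = _unit([0.268, 0.570, 0.776])

#: Achromatic (grey) OD axis; a lone "stain" this close to grey is rejected.
_GREY_AXIS = _unit([1.0, 1.0, 1.0])

#: Second-vector confidence below this value marks a one-stain image.
LOW_CONFIDENCE = 0.5


class StainEstimationError(DataError):
    """Raised when stain vectors cannot be estimated from an image."""


@dataclass(frozen=True)
class StainVector:
    """Unit RGB optical-density direction of one stain."""

    rgb_od: np.ndarray
    stain_name: str = ""
    confidence: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.rgb_od, dtype=float)
        if v.shape != (3,):
            raise DataError("stain vector must have 3 components")
        n = np.linalg.norm(v)
        if not np.isfinite(n) or n == 0:
            raise DataError("stain vector must be non-zero")
        if abs(n - 1.0) > 1e-9:
            v = v / n
        if v.max() <= 0:
            raise DataError("stain vector needs a positive component")
        object.__setattr__(self, "rgb_od", v)

    def angle_to(self, other) -> float:
        """Angle in degrees to another stain vector / 3-vector."""
        o = other.rgb_od if isinstance(other, StainVector) else _unit(other)
        cos = float(np.clip(np.dot(self.rgb_od, o), -1.0, 1.0))
        return float(np.degrees(np.arccos(abs(cos))))

    def to_dict(self) -> dict:
        return {
            "stain_name": self.stain_name,
            "rgb_od": self.rgb_od.tolist(),
            "confidence": self.confidence,
        }


def rgb_to_od(image: np.ndarray, background_intensity=255.0) -> np.ndarray:
    """Convert an RGB 8-bit image to optical density per channel.

    OD = -log10((I + 1) / (I0 + 1)) with I0 the per-channel background
    intensity; values are clipped at 0 so saturated pixels stay valid.
    """
    bg = np.asarray(background_intensity, dtype=float)
    if np.any(bg <= 0):
        raise DataError("background intensity must be positive")
    img = np.asarray(image, dtype=float)
    od = -np.log10((img + 1.0) / (bg + 1.0))
    return np.clip(od, 0.0, None)


def estimate_stain_vectors(
    od_map: np.ndarray,
    n_stains: int = 2,
    od_floor: float = 0.08,
    min_foreground: int = 1000,
    angle_percentile: float = 1.0,
) -> list[StainVector]:
    """Estimate the dominant stain OD vectors of a tile.

    High-OD pixels are reduced to their principal plane through the origin;
    the two stain vectors are taken at the extreme angular percentiles of
    the pixel directions within that plane (a deterministic plane-fit
    replacement for a trained per-tile color predictor).  The first vector
    returned is the hematoxylin-like one: largest blue OD component, ties
    broken by the larger red component.

    For a one-stain image the principal direction is returned first and an
    in-plane orthogonal complement second with ``confidence`` < 0.5.
    """
    if n_stains != 2:
        raise DataError("only two-stain estimation is supported")
    px = np.asarray(od_map, dtype=float).reshape(-1, 3)
    fg = px[np.linalg.norm(px, axis=1) > od_floor]
    if len(fg) < min_foreground:
        raise StainEstimationError(
            f"only {len(fg)} foreground pixels (need >= {min_foreground})"
        )
    # Principal directions through the origin (uncentered SVD).
    _, s, vt = np.linalg.svd(fg, full_matrices=False)
    ratio = float(s[1] / s[0]) if s[0] > 0 else 0.0
    e1, e2 = vt[0], vt[1]
    if e1.sum() < 0:
        e1 = -e1
    if ratio < 0.05:
        # Essentially one stain.  Reject achromatic (grey) images: grey has
        # no stain plane at all.
        mean_dir = _unit(fg.mean(axis=0))
        grey_angle = np.degrees(np.arccos(np.clip(np.dot(mean_dir, _GREY_AXIS), -1, 1)))
        if grey_angle < 3.0:
            raise StainEstimationError("no stain plane: image is achromatic")
        primary = StainVector(np.clip(mean_dir, 0, None), confidence=1.0)
        # Orthogonal complement within the plane spanned with the grey axis.
        residual = _GREY_AXIS - np.dot(_GREY_AXIS, primary.rgb_od) * primary.rgb_od
        secondary = StainVector(
            np.clip(_unit(residual), 1e-6, None),
            confidence=min(1.0, ratio / 0.05) * LOW_CONFIDENCE,
        )
        # The real stain stays first; the complement is only a placeholder,
        # so the hematoxylin-first ordering rule is not applied here.
        return [
            StainVector(primary.rgb_od, "hematoxylin_like", primary.confidence),
            StainVector(secondary.rgb_od, "counterstain_like", secondary.confidence),
        ]
    else:
        proj = fg @ np.stack([e1, e2]).T  # (n, 2) plane coordinates
        phi = np.arctan2(proj[:, 1], proj[:, 0])
        lo, hi = np.percentile(phi, [angle_percentile, 100.0 - angle_percentile])
        v_lo = np.cos(lo) * e1 + np.sin(lo) * e2
        v_hi = np.cos(hi) * e1 + np.sin(hi) * e2
        conf = min(1.0, ratio / 0.1)
        vectors = [
            StainVector(np.clip(v, 1e-6, None), confidence=conf)
            for v in (v_lo, v_hi)
        ]
    # Hematoxylin first: largest blue OD; near-ties (within 0.05) broken by
    # the larger red component, which separates hematoxylin from eosin.
    vectors.sort(
        key=lambda v: (round(v.rgb_od[2] / 0.05), v.rgb_od[0]), reverse=True
    )
    named = [
        StainVector(vectors[0].rgb_od, "hematoxylin_like", vectors[0].confidence),
        StainVector(vectors[1].rgb_od, "counterstain_like", vectors[1].confidence),
    ]
    return named


def project_stain(od_map: np.ndarray, vector: StainVector) -> np.ndarray:
    """Project an OD map onto a stain vector (grey-level stain map).

    The result is the per-pixel dot product with the unit stain vector,
    clipped at 0; higher values mean more of that stain.
    """
    od = np.asarray(od_map, dtype=float)
    return np.clip(od @ vector.rgb_od, 0.0, None)
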