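"""Shared vocabulary of the package: histotype labels, colors, contours.

The four histological classes are ordered by increasing severity
(Normal < UDH < LG-DCIS < HG-DCIS); several tie-breaking rules downstream
rely on this order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.draw import polygon as _draw_polygon

#: Histotype labels in severity order.
CLASSES: tuple[str, ...] = ("Normal", "UDH", "LG_DCIS", "HG_DCIS")

#: Mapping used for the two-class (Benign vs DCIS) collapse.
BENIGN_DCIS_MAP: dict[str, str] = {
    "Normal": "Benign",
    "UDH": "Benign",
    "LG_DCIS": "DCIS",
    "HG_DCIS": "DCIS",
}

#: Two-class label order (benign first).
BINARY_CLASSES: tuple[str, ...] = ("Benign", "DCIS")

#: Fixed RGB colors of the heterogeneity maps: dark blue = Normal,
#: light blue = UDH, light red = LG-DCIS, dark red = HG-DCIS.
CLASS_COLORS: dict[str, tuple[int, int, int]] = {
    "Normal": (0, 0, 139),
    "UDH": (102, 178, 255),
    "LG_DCIS": (255, 128, 128),
    "HG_DCIS": (139, 0, 0),
}


class DataError(Exception):
    """Malformed or infeasible data (CLI exit code 3)."""


class ConfigError(Exception):
    """Invalid configuration (CLI exit code 2)."""


class SchemaError(DataError):
    """A table does not match the expected schema."""


def severity(label: str) -> int:
    """Rank of a histotype in the severity order."""
    return CLASSES.index(label)


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


@dataclass
class RoiImage:
    """An RGB histology tile with its identity and physical scale."""

    pixels: np.ndarray  # (H, W, 3) uint8
    stain: str  # "HE" or "P63"
    case_id: str = ""
    roi_id: str = ""
    um_per_px: float = 0.46

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise DataError("RoiImage expects an (H, W, 3) array")
        if self.stain not in ("HE", "P63"):
            raise DataError(f"unknown stain kind {self.stain!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class NucleusContour:
    """Closed polygon outlining one segmented nucleus.

    Vertices are (row, col) pixel coordinates, 0-based; the polygon is
    closed implicitly (the last vertex is not a repeat of the first).
    """

    vertices: np.ndarray  # (n, 2) float
    source_roi: str = ""
    label: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise DataError("contour vertices must be an (n, 2) array")
        if len(self.vertices) < 3:
            raise DataError("a contour needs at least 3 vertices")

    @property
    def centroid(self) -> tuple[float, float]:
        r, c = self.vertices[:, 0], self.vertices[:, 1]
        return float(r.mean()), float(c.mean())

    @property
    def area(self) -> float:
        """Shoelace area of the polygon."""
        r, c = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize the filled polygon into a boolean mask."""
        rr, cc = _draw_polygon(self.vertices[:, 0], self.vertices[:, 1], shape)
        out = np.zeros(shape, dtype=bool)
        out[rr, cc] = True
        return out


def contours_to_json(contours: Sequence[NucleusContour]) -> list[dict]:
    return [
        {
            "label": c.label,
            "source_roi": c.source_roi,
            "vertices": np.round(c.vertices, 3).tolist(),
        }
        for c in contours
    ]


def contours_from_json(items: Sequence[dict]) -> list[NucleusContour]:
    return [
        NucleusContour(
            vertices=np.asarray(d["vertices"], dtype=float),
            source_roi=d.get("source_roi", ""),
            label=int(d.get("label", 0)),
        )
        for d in items
    ]


def contours_to_labels(
    contours: Sequence[NucleusContour], shape: tuple[int, int]
) -> np.ndarray:
    """Paint contours into a label image (1-based, later contours on top)."""
    out = np.zeros(shape, dtype=np.int32)
    for i, c in enumerate(contours, start=1):
        rr, cc = _draw_polygon(c.vertices[:, 0], c.vertices[:, 1], shape)
        out[rr, cc] = i
    return out
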