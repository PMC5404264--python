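"""HE nucleus segmentation: multi-scale center detection on the hematoxylin
map, non-maxima suppression, polar sampling and snake-style contour tracing.

Detection runs three blob filters on the grey-level hematoxylin map — two
difference-of-Gaussian filters for small and mid-sized dense nuclei and a
circular Hough transform for large nuclei — rescales each response to
[0, 1] and aggregates them by pixelwise maximum.  Surviving peaks seed a
polar resampling of the map around each candidate center, on which the
nucleus boundary is traced as a circular minimum-cost path over the rays
(a deterministic dynamic-programming formulation of snake tracking: the
per-ray cost is the negative radial gradient magnitude, with an elasticity
penalty on radius changes between neighboring rays).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.feature import canny, peak_local_max
from skimage.transform import hough_circle

from .core import DataError, NucleusContour, RoiImage
from .stains import estimate_stain_vectors, project_stain, rgb_to_od


class ContourError(DataError):
    """Raised when a contour cannot be traced from the polar sample."""


@dataclass(frozen=True)
class DetectionCandidate:
    """One putative nucleus center with its filter response."""

    center: tuple[int, int]  # (row, col)
    scale_source: str  # dog_small | dog_mid | hough_large
    response: float


@dataclass
class PolarSample:
    """Polar resampling of the hematoxylin map around one center.

    ``values[k, r]`` is the map sampled at angle 2*pi*k/n_rays and radius r
    (bilinear interpolation, edge values extended outside the image).
    """

    values: np.ndarray  # (n_rays, r_max)
    center: tuple[float, float]

    def __post_init__(self) -> None:
        if self.values.shape[0] < 16 or self.values.shape[1] < 4:
            raise DataError("polar sample needs >= 16 rays and r_max >= 4")

    @property
    def n_rays(self) -> int:
        return self.values.shape[0]

    @property
    def r_max(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class HeSegmentationParams:
    """Tunable knobs of the HE path.

    Defaults assume nucleus diameters of roughly 5-15 um at 0.46 um/px:
    DoG scales 2.5/5 px, Hough radii 8-20 px, 72 polar rays to 30 px.
    """

    sigma_small: float = 2.5
    sigma_mid: float = 5.0
    hough_radii: tuple[int, ...] = tuple(range(8, 21, 2))
    response_floor: float = 0.25
    nms_separation_px: float = 8.0
    n_rays: int = 72
    r_max: int = 30
    smoothness_lambda: float = 0.12
    min_area_px: float = 20.0

    def __post_init__(self) -> None:
        if not (0 < self.sigma_small < self.sigma_mid):
            raise DataError("need 0 < sigma_small < sigma_mid")
        if len(self.hough_radii) == 0:
            raise DataError("hough_radii must not be empty")


#: Center response of DoG(sigma, 1.6 sigma) to a matched unit disc; the
#: maximum over disc radii of exp(-x/5.12) - exp(-x/2) at x = r^2/sigma^2.
_DOG_MATCHED = 0.3336


def _rescale01(m: np.ndarray) -> np.ndarray:
    lo, hi = float(m.min()), float(m.max())
    if hi - lo < 1e-12:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def detect_centers(
    hem_map: np.ndarray, params: HeSegmentationParams | None = None
) -> list[DetectionCandidate]:
    """Locate candidate nucleus centers on the hematoxylin map."""
    params = params or HeSegmentationParams()
    h = np.asarray(hem_map, dtype=float)

    dog_small = gaussian_filter(h, params.sigma_small) - gaussian_filter(
        h, 1.6 * params.sigma_small
    )
    dog_mid = gaussian_filter(h, params.sigma_mid) - gaussian_filter(
        h, 1.6 * params.sigma_mid
    )
    hnorm = _rescale01(h)
    edges = canny(hnorm, sigma=1.5)
    if edges.any():
        acc = hough_circle(edges, np.asarray(params.hough_radii))
        hough_map = np.clip(acc.max(axis=0), 0.0, 1.0)
    else:
        hough_map = np.zeros_like(h)

    # Each map is expressed on a [0, 1] scale where 1 means an ideal
    # detection: the DoG responses are divided by the center response of a
    # DoG(sigma, 1.6 sigma) to a perfectly matched unit-amplitude disc
    # (0.3336, independent of sigma); the Hough accumulator is already
    # normalized so a full circle of edge votes scores 1.  A min-max
    # stretch would instead amplify off-scale edge-band noise to 1.
    maps = {
        "dog_small": np.clip(np.clip(dog_small, 0, None) / _DOG_MATCHED, 0, 1),
        "dog_mid": np.clip(np.clip(dog_mid, 0, None) / _DOG_MATCHED, 0, 1),
        "hough_large": hough_map,
    }
    stack = np.stack(list(maps.values()))
    agg = stack.max(axis=0)
    source_idx = stack.argmax(axis=0)
    names = list(maps.keys())

    peaks = peak_local_max(
        agg, min_distance=2, threshold_abs=params.response_floor, exclude_border=False
    )
    out = [
        DetectionCandidate(
            center=(int(r), int(c)),
            scale_source=names[source_idx[r, c]],
            response=float(agg[r, c]),
        )
        for r, c in peaks
    ]
    out.sort(key=lambda d: (-d.response, d.center))
    return out


def nonmax_suppress(
    candidates: list[DetectionCandidate], min_separation_px: float
) -> list[DetectionCandidate]:
    """Greedy keep-highest-response suppression within a separation radius."""
    if min_separation_px <= 0:
        raise DataError("min_separation_px must be > 0")
    ordered = sorted(candidates, key=lambda d: (-d.response, d.center))
    kept: list[DetectionCandidate] = []
    centers: list[tuple[int, int]] = []
    for cand in ordered:
        r, c = cand.center
        if all(
            (r - kr) ** 2 + (c - kc) ** 2 >= min_separation_px**2
            for kr, kc in centers
        ):
            kept.append(cand)
            centers.append(cand.center)
    return kept


def extract_polar(
    hem_map: np.ndarray,
    center: tuple[float, float],
    n_rays: int = 72,
    r_max: int = 30,
) -> PolarSample:
    """Sample the map along ``n_rays`` equally spaced rays from a center."""
    h = np.asarray(hem_map, dtype=float)
    angles = 2 * np.pi * np.arange(n_rays) / n_rays
    radii = np.arange(r_max, dtype=float)
    rows = center[0] + radii[None, :] * np.sin(angles)[:, None]
    cols = center[1] + radii[None, :] * np.cos(angles)[:, None]
    values = map_coordinates(
        h, np.stack([rows, cols]), order=1, mode="nearest"
    )
    return PolarSample(values=values, center=(float(center[0]), float(center[1])))


def trace_contour(
    polar: PolarSample, smoothness_lambda: float = 0.12, min_radius: int = 2
) -> NucleusContour:
    """Trace the nucleus boundary as a circular minimum-cost path.

    Cost per (ray, radius) is the negative magnitude of the radial gradient
    of the polar profile (normalized to [-1, 0]); transitions between
    neighboring rays are limited to |delta r| <= 2 px and penalized by
    ``smoothness_lambda * |delta r|``.  The path is closed exactly (first
    and last radii agree), enforced by solving the DP once per admissible
    start radius, vectorized over start states.
    """
    prof = polar.values
    n_rays, r_max = prof.shape
    grad = np.gradient(prof, axis=1)
    mag = np.abs(grad)
    peak = mag.max()
    if peak < 1e-12:
        raise ContourError("no boundary evidence in polar sample")
    cost = -(mag / peak)  # in [-1, 0]
    r_lo, r_hi = min_radius, r_max - 2
    if r_hi <= r_lo:
        raise ContourError("polar sample too small to trace")
    states = np.arange(r_lo, r_hi)
    n_states = len(states)
    lam = float(smoothness_lambda)
    deltas = np.arange(-2, 3)

    big = 1e18
    # D[s0, s]: best cost of a path starting at state s0 (ray 0) ending at
    # state s on the current ray.  Parents store the chosen delta.
    D = np.full((n_states, n_states), big)
    D[np.arange(n_states), np.arange(n_states)] = cost[0, states]
    parents = np.zeros((n_rays, n_states, n_states), dtype=np.int8)
    for t in range(1, n_rays):
        best = np.full_like(D, big)
        best_d = np.zeros((n_states, n_states), dtype=np.int8)
        for d in deltas:
            # previous state = current - d
            shifted = np.full_like(D, big)
            if d == 0:
                shifted = D + lam * abs(d)
            elif d > 0:
                shifted[:, d:] = D[:, :-d] + lam * d
            else:
                shifted[:, :d] = D[:, -d:] + lam * (-d)
            take = shifted < best
            best[take] = shifted[take]
            best_d[take] = d
        D = best + cost[t, states][None, :]
        parents[t] = best_d
    # Close the loop: end state must equal the start state.
    closed = D[np.arange(n_states), np.arange(n_states)]
    s0 = int(np.argmin(closed))
    # Backtrack.
    path = np.empty(n_rays, dtype=int)
    s = s0
    for t in range(n_rays - 1, 0, -1):
        path[t] = s
        s -= parents[t, s0, s]
    path[0] = s0
    radii = states[path].astype(float)
    angles = 2 * np.pi * np.arange(n_rays) / n_rays
    rows = polar.center[0] + radii * np.sin(angles)
    cols = polar.center[1] + radii * np.cos(angles)
    return NucleusContour(vertices=np.stack([rows, cols], axis=1))


def segment_he_roi(
    image: RoiImage | np.ndarray,
    exclusion_mask: np.ndarray | None = None,
    params: HeSegmentationParams | None = None,
) -> list[NucleusContour]:
    """Full HE path: stain projection, detection, NMS, per-candidate snake.

    Contours whose centroid lies in the exclusion mask, falls outside the
    image, or whose area is below ``min_area_px`` are dropped.  The whole
    chain is deterministic.
    """
    params = params or HeSegmentationParams()
    pixels = image.pixels if isinstance(image, RoiImage) else np.asarray(image)
    od = rgb_to_od(pixels)
    vectors = estimate_stain_vectors(od)
    hem = project_stain(od, vectors[0])
    # Normalize so the detection floor is comparable across tiles.
    scale = np.percentile(hem, 99.5)
    if scale > 0:
        hem = hem / scale

    candidates = nonmax_suppress(
        detect_centers(hem, params), params.nms_separation_px
    )
    shape = hem.shape
    contours: list[NucleusContour] = []
    for k, cand in enumerate(candidates):
        polar = extract_polar(hem, cand.center, params.n_rays, params.r_max)
        try:
            contour = trace_contour(polar, params.smoothness_lambda)
        except ContourError:
            continue
        cy, cx = contour.centroid
        if not (0 <= cy < shape[0] and 0 <= cx < shape[1]):
            continue
        if exclusion_mask is not None and exclusion_mask[int(round(cy)), int(round(cx))]:
            continue
        if contour.area < params.min_area_px:
            continue
        contour.label = len(contours) + 1
        contours.append(contour)
    return contours
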