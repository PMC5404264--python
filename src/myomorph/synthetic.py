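"""Synthetic breast-duct cohort generator with pixel-level ground truth.

Each ROI emulates an H&E / p63 pair of serial-section tiles: ducts ringed by
myoepithelial nuclei (ellipses tangentially oriented on the duct boundary),
luminal nuclei filling the duct for proliferative histotypes, and elongated
fibroblast nuclei scattered in the stroma.  Nuclear minor-axis length,
minor/major axis ratio and intra-nuclear texture contrast shift with the
histological class (Normal, UDH, LG-DCIS, HG-DCIS): lesional myoepithelial
nuclei become flatter and more spindle-like with higher staining contrast.

One geometric scene is rendered into both stains (perfect serial sections),
so ground-truth identity carries across stains exactly.  Rendering composes
stain concentration maps in optical-density space (Beer-Lambert mixing of
unit stain color vectors) and adds Gaussian pixel noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, binary_dilation
from skimage.draw import ellipse as _draw_ellipse

from . import __version__
from .core import CLASSES, DataError, RoiImage, config_hash
from .stains import DAB_RGB_OD, EOSIN_RGB_OD, HEMATOXYLIN_RGB_OD

#: Physical scale of the tiles: 2174 px correspond to 1 mm.
UM_PER_PX = 1000.0 / 2174.0  # ~0.46 um/px


class PackingError(DataError):
    """Raised when the requested ducts cannot be placed in the ROI."""


@dataclass(frozen=True)
class ClassMorphologyParams:
    """Per-histotype morphology of myoepithelial nuclei.

    ``minor_axis_mean_px``/``sd`` parameterize the full minor-axis length of
    the nuclear ellipse in pixels; ``minor_major_ratio_mean``/``ratio_sd``
    its elongation; ``texture_contrast_level`` the amplitude of the
    intra-nuclear stain speckle (relative concentration units) and
    ``stain_intensity`` the peak stain concentration in (0, 1].
    """

    histotype: str
    minor_axis_mean_px: float
    minor_axis_sd_px: float
    minor_major_ratio_mean: float
    ratio_sd: float
    texture_contrast_level: float
    stain_intensity: float = 0.9

    def __post_init__(self) -> None:
        if self.histotype not in CLASSES:
            raise DataError(f"unknown histotype {self.histotype!r}")
        if self.minor_axis_mean_px <= 0:
            raise DataError("minor axis mean must be > 0")
        if self.minor_axis_sd_px < 0 or self.ratio_sd < 0:
            raise DataError("standard deviations must be >= 0")
        r, s = self.minor_major_ratio_mean, self.ratio_sd
        if not (0.0 < r <= 1.0):
            raise DataError("ratio mean must be in (0, 1]")
        if r - 3 * s <= 0.0 or r + 3 * s > 1.0:
            raise DataError("ratio mean +- 3 sd must stay in (0, 1]")
        if not (0.0 < self.stain_intensity <= 1.0):
            raise DataError("stain intensity must be in (0, 1]")
        if self.texture_contrast_level < 0:
            raise DataError("texture contrast must be >= 0")


#: Default per-class morphology: elongation and texture contrast change
#: monotonically from Normal to HG-DCIS (flatter, more contrasted nuclei).
DEFAULT_CLASS_PARAMS: dict[str, ClassMorphologyParams] = {
    "Normal": ClassMorphologyParams("Normal", 14.0, 1.2, 0.75, 0.05, 0.05),
    "UDH": ClassMorphologyParams("UDH", 13.0, 1.2, 0.70, 0.05, 0.10),
    "LG_DCIS": ClassMorphologyParams("LG_DCIS", 11.5, 1.1, 0.60, 0.05, 0.18),
    "HG_DCIS": ClassMorphologyParams("HG_DCIS", 10.0, 1.0, 0.52, 0.05, 0.25),
}


@dataclass(frozen=True)
class CohortSpec:
    """Size and layout of a synthetic cohort.

    Defaults reproduce the reference study conditions: 22 cases (7 Normal,
    5 UDH, 5 LG-DCIS, 5 HG-DCIS), ~70 ROIs of 2174 px (~1 mm^2) and on the
    order of 11,000 myoepithelial nuclei.
    """

    cases_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"Normal": 7, "UDH": 5, "LG_DCIS": 5, "HG_DCIS": 5}
    )
    rois_per_case: int = 3
    ducts_per_roi: int = 3
    nuclei_per_duct: tuple[int, int] = (40, 70)
    roi_size_px: int = 2174
    seed: int = 0
    # Secondary scene content and noise.
    fibroblasts_per_roi: int = 40
    luminal_fill: bool = True
    duct_radius_frac: tuple[float, float] = (0.13, 0.17)
    noise_sd: float = 2.0
    # Between-case variation of the class morphology means.
    case_minor_sd_px: float = 0.6
    case_ratio_sd: float = 0.03
    case_contrast_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.roi_size_px < 256:
            raise DataError("roi_size_px must be >= 256")
        if self.rois_per_case < 1 or any(
            n < 1 for n in self.cases_per_class.values()
        ):
            raise DataError("case and ROI counts must be >= 1")
        if self.ducts_per_roi < 0 or self.fibroblasts_per_roi < 0:
            raise DataError("ducts/fibroblasts per ROI must be >= 0")
        lo, hi = self.nuclei_per_duct
        if lo < 1 or hi < lo:
            raise DataError("nuclei_per_duct must be a non-empty range")
        if set(self.cases_per_class) - set(CLASSES):
            raise DataError("cases_per_class has unknown histotypes")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cases_per_class"] = dict(self.cases_per_class)
        return d


@dataclass(frozen=True)
class NucleusSpec:
    """Geometry of one generated nucleus (ellipse parameters in pixels)."""

    nucleus_id: int
    kind: str  # myoepithelial | luminal | fibroblast
    histotype: str
    duct_id: int  # -1 for stromal nuclei
    row: float
    col: float
    semi_minor: float
    semi_major: float
    orientation: float  # radians, rotation passed to the rasterizer
    contrast: float
    intensity: float


@dataclass
class Scene:
    """Geometric content of one ROI before rendering."""

    roi_size: int
    histotype: str
    ducts: list[tuple[float, float, float]]  # (row, col, radius)
    nuclei: list[NucleusSpec]
    seed: int
    noise_sd: float = 2.0

    def nuclei_of_kind(self, kind: str) -> list[NucleusSpec]:
        return [n for n in self.nuclei if n.kind == kind]


@dataclass
class GroundTruth:
    """Pixel-level truth for one ROI.

    ``labels`` indexes myoepithelial nuclei only (value = nucleus_id);
    ``exclusion_mask`` covers all stromal fibroblast nuclei (the synthetic
    analogue of manually masking fibroblasts/necrosis).
    """

    labels: np.ndarray  # (H, W) int32
    exclusion_mask: np.ndarray  # (H, W) bool
    nuclei: list[NucleusSpec]

    def myoepithelial(self) -> list[NucleusSpec]:
        return [n for n in self.nuclei if n.kind == "myoepithelial"]

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(n) for n in self.nuclei]
        return pd.DataFrame(rows)


def _ellipse_coords(n: NucleusSpec, shape):
    return _draw_ellipse(
        n.row, n.col, n.semi_minor, n.semi_major, shape=shape, rotation=n.orientation
    )


def generate_roi(
    spec: CohortSpec,
    params: Mapping[str, ClassMorphologyParams],
    histotype: str,
    seed: int,
) -> tuple[Scene, GroundTruth]:
    """Generate one ROI scene plus its ground truth, deterministically.

    Ducts are placed without overlap (rejection sampling; infeasible packing
    raises :class:`PackingError`).  Myoepithelial nuclei sit on the duct
    boundary with their major axis tangential; luminal nuclei fill the duct
    for proliferative histotypes; fibroblasts land in the stroma and are
    covered by the exclusion mask.
    """
    if histotype not in CLASSES:
        raise DataError(f"unknown histotype {histotype!r}")
    p = params[histotype]
    rng = np.random.default_rng(seed)
    size = spec.roi_size_px

    # Worst-case semi-major axis, used as a safety margin everywhere.
    max_major = (p.minor_axis_mean_px + 3 * p.minor_axis_sd_px) / (
        2 * max(p.minor_major_ratio_mean - 3 * p.ratio_sd, 0.2)
    )
    margin = max_major + 4.0

    ducts: list[tuple[float, float, float]] = []
    r_lo, r_hi = spec.duct_radius_frac
    # Retry the whole layout when a partial placement paints itself into a
    # corner (e.g. a central first duct blocking all later ones).
    for _restart in range(50):
        ducts = []
        ok = True
        for _ in range(spec.ducts_per_roi):
            placed = False
            for _attempt in range(200):
                radius = rng.uniform(r_lo, r_hi) * size
                lo, hi = radius + margin, size - radius - margin
                if hi <= lo:
                    continue
                cy, cx = rng.uniform(lo, hi, size=2)
                if all(
                    np.hypot(cy - dy, cx - dx) > radius + dr + 2 * margin
                    for dy, dx, dr in ducts
                ):
                    ducts.append((cy, cx, radius))
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise PackingError(
            f"cannot place {spec.ducts_per_roi} ducts in a {size} px ROI"
        )

    nuclei: list[NucleusSpec] = []
    next_id = 1

    def sample_ellipse(pp: ClassMorphologyParams):
        minor = float(np.clip(rng.normal(pp.minor_axis_mean_px, pp.minor_axis_sd_px), 4.0, None))
        ratio = float(np.clip(rng.normal(pp.minor_major_ratio_mean, pp.ratio_sd), 0.2, 1.0))
        return minor / 2.0, minor / (2.0 * ratio)

    for duct_id, (cy, cx, radius) in enumerate(ducts):
        # Cap the ring count so tangential neighbors cannot overlap.
        cap = max(1, int(2 * np.pi * radius / (2 * max_major + 2.0)))
        n_ring = min(int(rng.integers(spec.nuclei_per_duct[0], spec.nuclei_per_duct[1] + 1)), cap)
        phase = rng.uniform(0, 2 * np.pi)
        for k in range(n_ring):
            angle = phase + 2 * np.pi * k / n_ring + rng.normal(0, 0.1 / n_ring)
            semi_minor, semi_major = sample_ellipse(p)
            row = cy + radius * np.sin(angle)
            col = cx + radius * np.cos(angle)
            # Major axis along the duct tangent.  skimage's ellipse rotation
            # is applied clockwise in (row, col); the tangent direction at
            # `angle` has slope angle+90 degrees.
            orientation = -(angle + np.pi / 2)
            nuclei.append(
                NucleusSpec(
                    next_id, "myoepithelial", histotype, duct_id,
                    float(row), float(col), semi_minor, semi_major,
                    float(orientation), p.texture_contrast_level, p.stain_intensity,
                )
            )
            next_id += 1
        if spec.luminal_fill and histotype != "Normal":
            inner = radius - p.minor_axis_mean_px - 6.0
            if inner > 12.0:
                target = int(0.35 * (inner / 5.0) ** 2)
                placed_pts: list[tuple[float, float]] = []
                attempts = 0
                while len(placed_pts) < target and attempts < target * 30:
                    attempts += 1
                    rr = inner * np.sqrt(rng.uniform())
                    aa = rng.uniform(0, 2 * np.pi)
                    py, px_ = cy + rr * np.sin(aa), cx + rr * np.cos(aa)
                    if all(np.hypot(py - q, px_ - w) > 11.0 for q, w in placed_pts):
                        placed_pts.append((py, px_))
                for py, px_ in placed_pts:
                    a = rng.uniform(3.5, 5.0)
                    nuclei.append(
                        NucleusSpec(
                            next_id, "luminal", histotype, duct_id,
                            float(py), float(px_), a, a / rng.uniform(0.8, 0.95),
                            float(rng.uniform(0, np.pi)), 0.08, 0.8,
                        )
                    )
                    next_id += 1

    # Fibroblasts: elongated nuclei in the stroma, outside every duct.
    for _ in range(spec.fibroblasts_per_roi):
        for _attempt in range(100):
            py, px_ = rng.uniform(10, size - 10, size=2)
            if all(
                np.hypot(py - dy, px_ - dx) > dr + margin + 8.0
                for dy, dx, dr in ducts
            ):
                nuclei.append(
                    NucleusSpec(
                        next_id, "fibroblast", histotype, -1,
                        float(py), float(px_), 2.2, 7.5,
                        float(rng.uniform(0, np.pi)), 0.05, 0.85,
                    )
                )
                next_id += 1
                break

    scene = Scene(size, histotype, ducts, nuclei, seed=seed, noise_sd=spec.noise_sd)

    labels = np.zeros((size, size), dtype=np.int32)
    exclusion = np.zeros((size, size), dtype=bool)
    for n in nuclei:
        rr, cc = _ellipse_coords(n, labels.shape)
        if n.kind == "myoepithelial":
            labels[rr, cc] = n.nucleus_id
        elif n.kind == "fibroblast":
            exclusion[rr, cc] = True
    if exclusion.any():
        exclusion = binary_dilation(exclusion, iterations=3)
    truth = GroundTruth(labels=labels, exclusion_mask=exclusion, nuclei=nuclei)
    return scene, truth


#: Background eosin concentration of the HE rendering (stroma tint).
_HE_EOSIN_BACKGROUND = 0.25
#: Hematoxylin counterstain level of the p63 rendering.
_P63_COUNTERSTAIN = 0.06

_STAIN_CODE = {"HE": 1, "P63": 2}


def render_stain(scene: Scene, stain: str, background: float = 255.0) -> RoiImage:
    """Render a scene into an 8-bit RGB tile for one stain.

    Stain concentration maps are composed per nucleus (with multiplicative
    intra-nuclear speckle of amplitude ``texture_contrast_level``), mixed in
    OD space with the reference stain color vectors, exponentiated back to
    intensities and degraded with Gaussian pixel noise of SD
    ``scene.noise_sd``.
    """
    if stain not in _STAIN_CODE:
        raise DataError(f"unknown stain kind {stain!r}")
    size = scene.roi_size
    rng = np.random.default_rng(
        np.random.SeedSequence([scene.seed, _STAIN_CODE[stain], 7919])
    )
    # One smooth unit-variance speckle field shared by all nuclei.
    field_ = rng.standard_normal((size, size))
    field_ = gaussian_filter(field_, 1.2)
    sd = field_.std()
    if sd > 0:
        field_ /= sd

    c_h = np.zeros((size, size))
    c_e = np.zeros((size, size))
    c_d = np.zeros((size, size))

    for n in scene.nuclei:
        rr, cc = _ellipse_coords(n, (size, size))
        mult = np.clip(1.0 + n.contrast * field_[rr, cc], 0.1, None)
        conc = n.intensity * mult
        if stain == "HE":
            np.maximum.at(c_h, (rr, cc), conc)
        elif n.kind == "myoepithelial":
            np.maximum.at(c_d, (rr, cc), conc)
        else:
            np.maximum.at(c_h, (rr, cc), conc)

    # Background stain is displaced where nuclear chromatin dominates, so
    # strongly stained nuclei contribute near-pure stain pixels.
    occupancy = np.clip(1.0 - (c_h + c_d), 0.0, 1.0)
    if stain == "HE":
        c_e += _HE_EOSIN_BACKGROUND * occupancy
    else:
        c_h += _P63_COUNTERSTAIN * occupancy

    od = (
        c_h[..., None] * HEMATOXYLIN_RGB_OD
        + c_e[..., None] * EOSIN_RGB_OD
        + c_d[..., None] * DAB_RGB_OD
    )
    img = (background + 1.0) * np.power(10.0, -od) - 1.0
    if scene.noise_sd > 0:
        img = img + rng.normal(0.0, scene.noise_sd, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return RoiImage(pixels=pixels, stain=stain, um_per_px=UM_PER_PX)


def perturb_params(
    params: Mapping[str, ClassMorphologyParams],
    histotype: str,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> ClassMorphologyParams:
    """Case-level biological variation: jitter the class morphology means."""
    p = params[histotype]
    ratio = p.minor_major_ratio_mean + rng.normal(0, spec.case_ratio_sd)
    ratio = float(np.clip(ratio, 3 * p.ratio_sd + 0.01, 1.0 - 3 * p.ratio_sd))
    return dataclasses.replace(
        p,
        minor_axis_mean_px=max(
            5.0, p.minor_axis_mean_px + rng.normal(0, spec.case_minor_sd_px)
        ),
        minor_major_ratio_mean=ratio,
        texture_contrast_level=max(
            0.01, p.texture_contrast_level + rng.normal(0, spec.case_contrast_sd)
        ),
    )


def iter_cohort(
    spec: CohortSpec,
    params: Mapping[str, ClassMorphologyParams] | None = None,
) -> Iterator[tuple[str, str, str, Scene, GroundTruth]]:
    """Yield (case_id, roi_id, histotype, scene, truth) for a whole cohort.

    Case order is severity order; everything derives deterministically from
    ``spec.seed``.
    """
    params = dict(params or DEFAULT_CLASS_PARAMS)
    case_index = 0
    for histotype in CLASSES:
        for k in range(spec.cases_per_class.get(histotype, 0)):
            case_id = f"{histotype}_{k + 1:02d}"
            case_rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, 104729, case_index])
            )
            case_params = {**params, histotype: perturb_params(params, histotype, spec, case_rng)}
            for r in range(spec.rois_per_case):
                roi_id = f"{case_id}_roi{r + 1}"
                roi_seed = int(
                    np.random.SeedSequence(
                        [spec.seed, 224737, case_index, r]
                    ).generate_state(1)[0] % (2**31)
                )
                scene, truth = generate_roi(spec, case_params, histotype, roi_seed)
                yield case_id, roi_id, histotype, scene, truth
            case_index += 1


TRUTH_COLUMNS = [
    "cell_id", "case_id", "roi_id", "duct_id", "histotype", "kind",
    "row", "col", "semi_minor_px", "semi_major_px", "orientation_rad",
    "minor_axis_px", "minor_major_ratio",
]


@dataclass
class CohortSummary:
    out_dir: Path
    n_cases: int
    n_rois: int
    n_myoepithelial: int
    n_nuclei: int


def make_cohort(
    spec: CohortSpec,
    params: Mapping[str, ClassMorphologyParams] | None = None,
    out_dir: str | Path = "cohort",
) -> CohortSummary:
    """Write a full cohort to disk: paired HE/p63 TIFFs, exclusion-mask PNGs,
    a truth CSV and the generating spec as JSON."""
    import imageio.v3 as iio
    import tifffile

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    rows = []
    n_rois = 0
    cases = set()
    for case_id, roi_id, histotype, scene, truth in iter_cohort(spec, params):
        n_rois += 1
        cases.add(case_id)
        for stain in ("HE", "P63"):
            img = render_stain(scene, stain)
            tifffile.imwrite(out / "images" / f"{roi_id}_{stain}.tiff", img.pixels)
        iio.imwrite(
            out / "masks" / f"{roi_id}_exclusion.png",
            (truth.exclusion_mask * np.uint8(255)),
        )
        np.save(out / "masks" / f"{roi_id}_labels.npy", truth.labels)
        for n in truth.nuclei:
            rows.append(
                {
                    "cell_id": f"{roi_id}:c{n.nucleus_id}",
                    "case_id": case_id,
                    "roi_id": roi_id,
                    "duct_id": f"{roi_id}:d{n.duct_id}",
                    "histotype": histotype,
                    "kind": n.kind,
                    "row": round(n.row, 3),
                    "col": round(n.col, 3),
                    "semi_minor_px": round(n.semi_minor, 4),
                    "semi_major_px": round(n.semi_major, 4),
                    "orientation_rad": round(n.orientation, 5),
                    "minor_axis_px": round(2 * n.semi_minor, 4),
                    "minor_major_ratio": round(n.semi_minor / n.semi_major, 5),
                }
            )
    truth_df = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    meta = {
        "version": __version__,
        "seed": spec.seed,
        "config_hash": config_hash(spec.to_dict()),
    }
    header = "# " + json.dumps(meta, sort_keys=True) + "\n"
    with open(out / "truth.csv", "w") as fh:
        fh.write(header)
        truth_df.to_csv(fh, index=False)
    with open(out / "spec.json", "w") as fh:
        json.dump({**meta, "spec": spec.to_dict()}, fh, indent=2, sort_keys=True, default=str)
    myo = (truth_df["kind"] == "myoepithelial").sum()
    return CohortSummary(out, len(cases), n_rois, int(myo), len(truth_df))
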