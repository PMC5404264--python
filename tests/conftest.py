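"""Shared fixtures: small synthetic scenes reused across test modules."""

import numpy as np
import pytest

from myomorph.segment_p63 import label_mask_from_truth, train_pixel_classifier
from myomorph.synthetic import (
    DEFAULT_CLASS_PARAMS,
    CohortSpec,
    generate_roi,
    render_stain,
)


def small_spec(**overrides) -> CohortSpec:
    """A 384 px ROI spec sized for fast tests."""
    base = dict(
        cases_per_class={"Normal": 1, "UDH": 1, "LG_DCIS": 1, "HG_DCIS": 1},
        rois_per_case=1,
        ducts_per_roi=2,
        nuclei_per_duct=(9, 14),
        roi_size_px=384,
        fibroblasts_per_roi=10,
        duct_radius_frac=(0.15, 0.18),
        seed=0,
    )
    base.update(overrides)
    return CohortSpec(**base)


@pytest.fixture(scope="session")
def spec():
    return small_spec()


@pytest.fixture(scope="session")
def clean_spec():
    """Zero-noise variant for segmentation-accuracy checks."""
    return small_spec(noise_sd=0.0)


@pytest.fixture(scope="session")
def normal_roi(clean_spec):
    return generate_roi(clean_spec, DEFAULT_CLASS_PARAMS, "Normal", seed=3)


@pytest.fixture(scope="session")
def hg_roi(spec):
    return generate_roi(spec, DEFAULT_CLASS_PARAMS, "HG_DCIS", seed=11)


@pytest.fixture(scope="session")
def hg_p63_image(hg_roi):
    scene, _ = hg_roi
    return render_stain(scene, "P63")


@pytest.fixture(scope="session")
def pixel_classifier(hg_roi, hg_p63_image):
    _, truth = hg_roi
    return train_pixel_classifier(
        hg_p63_image, label_mask_from_truth(truth.labels), seed=0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
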