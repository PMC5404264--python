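"""Morphometry oracles: shape features against brute-force computations,
GLCM against hand-enumerated co-occurrences, and the size-trim rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk, ellipse

from myomorph.core import DataError, NucleusContour
from myomorph.morphometry import (
    FEATURE_MANIFEST,
    feature_vector,
    glcm,
    glcm_features,
    shape_features,
    trim_by_size,
)


def brute_force_caliper(mask, n_angles=720):
    """Min/max width by projecting pixel corners over many directions."""
    pts = np.argwhere(mask)
    corners = np.concatenate(
        [pts + np.array(d) for d in ((-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5))]
    )
    widths = []
    for theta in np.linspace(0, np.pi, n_angles, endpoint=False):
        u = np.array([np.cos(theta), np.sin(theta)])
        proj = corners @ u
        widths.append(proj.max() - proj.min())
    return min(widths), max(widths)


def brute_force_moment_axes(mask):
    """Axis lengths from raw second central moments of pixel centers."""
    pts = np.argwhere(mask).astype(float)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts) + np.eye(2) / 12.0
    eig = np.sort(np.linalg.eigvalsh(cov))
    return 4 * np.sqrt(eig[0]), 4 * np.sqrt(eig[1])  # minor, major


class TestShapeFeatures:
    def test_disc_is_round(self):
        m = np.zeros((41, 41), bool)
        rr, cc = disk((20, 20), 10)
        m[rr, cc] = True
        f = shape_features(m)
        assert abs(f["MinorMajorRatio"] - 1.0) < 0.02
        assert abs(f["FormFactor"] - 1.0) < 0.05

    def test_ellipse_axes_match_brute_force(self):
        m = np.zeros((61, 101), bool)
        rr, cc = ellipse(30, 50, 10, 20)
        m[rr, cc] = True
        f = shape_features(m)
        bf_minor, bf_major = brute_force_moment_axes(m)
        assert abs(f["MinorAxisLength"] - bf_minor) < 0.05
        assert abs(f["MajorAxisLength"] - bf_major) < 0.05
        assert abs(f["MinorAxisLength"] - 20.0) < 0.5
        bf_min_feret, bf_max_feret = brute_force_caliper(m)
        assert abs(f["MinFeretDiameter"] - bf_min_feret) < 0.05
        assert abs(f["MaxFeretDiameter"] - bf_max_feret) < 0.05
        assert abs(f["MinFeretDiameter"] - 20.0) <= 1.0

    def test_square_is_convex_and_fills_bbox(self):
        m = np.zeros((15, 15), bool)
        m[2:13, 2:13] = True
        f = shape_features(m)
        assert f["Extent"] == 1.0
        assert f["Solidity"] == 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(DataError):
            shape_features(np.zeros((5, 5), bool))

    def test_translation_invariance(self):
        m = np.zeros((61, 61), bool)
        rr, cc = ellipse(25, 25, 8, 14)
        m[rr, cc] = True
        shifted = np.roll(np.roll(m, 7, axis=0), 5, axis=1)
        a, b = shape_features(m), shape_features(shifted)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9)

    def test_axis_lengths_invariant_to_quarter_rotation(self):
        m = np.zeros((61, 61), bool)
        rr, cc = ellipse(30, 30, 8, 14)
        m[rr, cc] = True
        a, b = shape_features(m), shape_features(np.rot90(m))
        for k in ("MinorAxisLength", "MajorAxisLength"):
            assert abs(a[k] - b[k]) / a[k] < 0.01


class TestGlcm:
    def test_constant_patch_degenerate_values(self):
        h = glcm_features(np.full((10, 10), 5.0), np.ones((10, 10), bool))
        assert h["Contrast"] == 0.0
        assert h["InverseDifferenceMoment"] == 1.0
        assert h["Entropy"] == 0.0
        assert h["AngularSecondMoment"] == 1.0

    def test_stripes_contrast_matches_hand_enumeration(self):
        # vertical 1-px stripes of {0, 1}, horizontal offset, G=2: every
        # horizontal pair differs by one level -> Contrast = 1.0 exactly
        patch = np.tile(np.array([0.0, 1.0]), (8, 4))
        h = glcm_features(patch, np.ones(patch.shape, bool), levels=2, offsets=((0, 1),))
        assert h["Contrast"] == pytest.approx(1.0)
        assert h["InverseDifferenceMoment"] == pytest.approx(0.5)

    def test_affine_intensity_invariance(self, rng):
        patch = rng.uniform(0, 1, (15, 15))
        mask = np.ones((15, 15), bool)
        a = glcm_features(patch, mask)
        b = glcm_features(4.2 * patch + 17.0, mask)
        for k in a:
            assert a[k] == pytest.approx(b[k], abs=1e-9)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_glcm_symmetric_normalized(self, seed):
        rng = np.random.default_rng(seed)
        patch = rng.uniform(0, 1, (12, 12))
        mask = rng.uniform(0, 1, (12, 12)) > 0.3
        if mask.sum() < 2:
            return
        p = glcm(patch, mask)
        assert p.min() >= 0
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(p, p.T)

    def test_masked_pairs_only(self):
        # mask out one stripe: no horizontal pair crosses the gap
        patch = np.array([[0.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
        mask = np.array([[True, False, True]] * 2)
        p = glcm(patch, mask, levels=2, offsets=((0, 1),))
        # no valid horizontal pairs at distance 1 -> degenerate fallback
        assert p[0, 0] == 1.0


class TestFeatureVector:
    def test_vector_has_exactly_32_features(self, rng):
        assert len(FEATURE_MANIFEST) == 32
        theta = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        contour = NucleusContour(
            np.stack([20 + 8 * np.sin(theta), 20 + 12 * np.cos(theta)], axis=1)
        )
        channel = rng.uniform(0, 1, (41, 41))
        rec = feature_vector(contour, channel, cell_id="c1")
        assert rec.vector().shape == (32,)
        assert np.all(np.isfinite(rec.vector()))

    def test_duplicate_contour_identical_vector(self, rng):
        theta = np.linspace(0, 2 * np.pi, 48, endpoint=False)
        contour = NucleusContour(
            np.stack([20 + 8 * np.sin(theta), 20 + 12 * np.cos(theta)], axis=1)
        )
        channel = rng.uniform(0, 1, (41, 41))
        a = feature_vector(contour, channel).vector()
        b = feature_vector(contour, channel).vector()
        assert np.array_equal(a, b)


class TestTrimBySize:
    def test_ten_areas_trims_one_each_end(self):
        df = pd.DataFrame({"roi_id": ["r"] * 10, "Area": range(1, 11)})
        assert trim_by_size(df)["Area"].tolist() == list(range(2, 10))

    def test_small_group_fully_retained(self):
        df = pd.DataFrame({"roi_id": ["r"] * 5, "Area": range(5)})
        assert len(trim_by_size(df)) == 5

    def test_retained_count_closed_form(self, rng):
        for n in range(1, 101):
            df = pd.DataFrame({"roi_id": ["r"] * n, "Area": rng.permutation(n)})
            assert len(trim_by_size(df)) == n - 2 * (n // 10)

    def test_trim_is_per_roi(self, rng):
        df = pd.DataFrame(
            {
                "roi_id": ["a"] * 10 + ["b"] * 10,
                "Area": list(range(10)) + list(range(100, 110)),
            }
        )
        out = trim_by_size(df)
        assert (out["roi_id"] == "a").sum() == 8
        assert (out["roi_id"] == "b").sum() == 8

    def test_zero_fraction_identity_and_monotone(self, rng):
        df = pd.DataFrame({"roi_id": ["r"] * 37, "Area": rng.uniform(0, 1, 37)})
        assert trim_by_size(df, fraction=0.0).equals(df)
        kept = [set(trim_by_size(df, fraction=f)["Area"]) for f in (0.0, 0.1, 0.2, 0.3)]
        for a, b in zip(kept, kept[1:]):
            assert b <= a

    def test_invalid_fraction_rejected(self):
        df = pd.DataFrame({"roi_id": ["r"], "Area": [1.0]})
        with pytest.raises(DataError):
            trim_by_size(df, fraction=0.5)
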