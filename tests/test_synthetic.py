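"""Cohort generator: geometry, determinism, effect sizes, rendering."""

import numpy as np
import pandas as pd
import pytest
from skimage.measure import regionprops

from myomorph.core import DataError
from myomorph.stains import DAB_RGB_OD, StainVector, project_stain, rgb_to_od
from myomorph.synthetic import (
    DEFAULT_CLASS_PARAMS,
    ClassMorphologyParams,
    CohortSpec,
    PackingError,
    generate_roi,
    iter_cohort,
    make_cohort,
    render_stain,
)

from conftest import small_spec


class TestParams:
    def test_ratio_band_must_stay_in_unit_interval(self):
        with pytest.raises(DataError):
            ClassMorphologyParams("Normal", 14, 1.2, 0.95, 0.05, 0.1)

    def test_negative_sd_rejected(self):
        with pytest.raises(DataError):
            ClassMorphologyParams("Normal", 14, -1.0, 0.7, 0.05, 0.1)

    def test_default_spec_matches_study_design(self):
        spec = CohortSpec()
        assert spec.cases_per_class == {
            "Normal": 7, "UDH": 5, "LG_DCIS": 5, "HG_DCIS": 5,
        }
        assert spec.roi_size_px == 2174

    def test_small_roi_rejected(self):
        with pytest.raises(DataError):
            small_spec(roi_size_px=128)


class TestGenerateRoi:
    def test_no_ducts_gives_stroma_only(self):
        spec = small_spec(ducts_per_roi=0, fibroblasts_per_roi=5)
        scene, truth = generate_roi(spec, DEFAULT_CLASS_PARAMS, "Normal", 1)
        assert scene.ducts == []
        assert truth.labels.max() == 0
        assert len(truth.myoepithelial()) == 0

    def test_same_seed_identical_truth(self, spec):
        _, a = generate_roi(spec, DEFAULT_CLASS_PARAMS, "UDH", 7)
        _, b = generate_roi(spec, DEFAULT_CLASS_PARAMS, "UDH", 7)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.exclusion_mask, b.exclusion_mask)
        assert a.to_frame().equals(b.to_frame())

    def test_infeasible_packing_raises(self):
        spec = small_spec(ducts_per_roi=8, duct_radius_frac=(0.3, 0.35))
        with pytest.raises(PackingError):
            generate_roi(spec, DEFAULT_CLASS_PARAMS, "Normal", 1)

    def test_minor_axis_mean_recovered_from_truth_masks(self):
        # ~200 Normal nuclei at minor-axis mean 14 px: raster moment minor
        # axes must average within 0.5 px of 14.
        spec = small_spec(
            roi_size_px=1536,
            ducts_per_roi=6,
            nuclei_per_duct=(40, 40),
            fibroblasts_per_roi=0,
            duct_radius_frac=(0.10, 0.13),
        )
        _, truth = generate_roi(spec, DEFAULT_CLASS_PARAMS, "Normal", 9)
        minors = [p.axis_minor_length for p in regionprops(truth.labels)]
        assert len(minors) >= 200
        assert abs(np.mean(minors) - 14.0) < 0.5

    def test_class_effect_sizes_match_params(self):
        # Per-class empirical minor axis and ratio within 2 SE of params.
        spec = small_spec(
            roi_size_px=1792,
            ducts_per_roi=7,
            nuclei_per_duct=(40, 40),
            fibroblasts_per_roi=0,
            duct_radius_frac=(0.10, 0.12),
        )
        for hist, p in DEFAULT_CLASS_PARAMS.items():
            _, truth = generate_roi(spec, DEFAULT_CLASS_PARAMS, hist, 13)
            myo = truth.myoepithelial()
            minor = np.array([2 * n.semi_minor for n in myo])
            ratio = np.array([n.semi_minor / n.semi_major for n in myo])
            n = len(myo)
            assert n >= 200
            assert abs(minor.mean() - p.minor_axis_mean_px) < 2 * minor.std() / np.sqrt(n) + 0.1
            assert abs(ratio.mean() - p.minor_major_ratio_mean) < 2 * ratio.std() / np.sqrt(n) + 0.01

    def test_fibroblasts_covered_by_exclusion_mask(self, hg_roi):
        _, truth = hg_roi
        for n in truth.nuclei:
            if n.kind == "fibroblast":
                assert truth.exclusion_mask[int(round(n.row)), int(round(n.col))]


class TestRenderStain:
    def test_unknown_stain_rejected(self, normal_roi):
        with pytest.raises(DataError):
            render_stain(normal_roi[0], "PAS")

    def test_empty_scene_near_uniform_background(self):
        spec = small_spec(ducts_per_roi=0, fibroblasts_per_roi=0, noise_sd=2.0)
        scene, _ = generate_roi(spec, DEFAULT_CLASS_PARAMS, "Normal", 2)
        img = render_stain(scene, "HE").pixels.astype(float)
        assert img.std(axis=(0, 1)).max() < 1.5 * spec.noise_sd

    def test_zero_noise_zero_contrast_nucleus_is_constant(self):
        params = {
            k: ClassMorphologyParams(k, 14.0, 0.0, 0.75, 0.0, 0.0)
            for k in DEFAULT_CLASS_PARAMS
        }
        spec = small_spec(
            ducts_per_roi=1, nuclei_per_duct=(1, 1), fibroblasts_per_roi=0,
            noise_sd=0.0,
        )
        scene, truth = generate_roi(spec, params, "Normal", 4)
        img = render_stain(scene, "P63").pixels
        inner = truth.labels > 0
        # erode one pixel to avoid rasterization boundary pixels
        from scipy.ndimage import binary_erosion

        inner = binary_erosion(inner)
        for ch in range(3):
            assert len(np.unique(img[..., ch][inner])) == 1

    def test_render_deterministic(self, normal_roi):
        scene, _ = normal_roi
        a = render_stain(scene, "HE").pixels
        b = render_stain(scene, "HE").pixels
        assert np.array_equal(a, b)

    def test_mask_aligns_with_stain_channel_at_zero_noise(self, normal_roi):
        # Stain projections are not unmixing: hematoxylin-stained nuclei
        # (fibroblasts) also project onto the DAB vector, so the comparison
        # is restricted to the exclusion-free region.
        scene, truth = normal_roi
        img = render_stain(scene, "P63")
        dab = project_stain(rgb_to_od(img.pixels), StainVector(DAB_RGB_OD))
        keep = ~truth.exclusion_mask
        myo = (truth.labels > 0) & keep
        thresholded = (dab > 0.3) & keep
        iou = (myo & thresholded).sum() / (myo | thresholded).sum()
        assert iou >= 0.9


class TestMakeCohort:
    def test_default_cohort_has_22_cases(self):
        spec = CohortSpec()
        counts = spec.cases_per_class
        assert sum(counts.values()) == 22
        assert [counts[c] for c in ("Normal", "UDH", "LG_DCIS", "HG_DCIS")] == [7, 5, 5, 5]

    def test_truth_row_count_arithmetic(self, tmp_path):
        spec = small_spec(
            ducts_per_roi=1, nuclei_per_duct=(10, 10), fibroblasts_per_roi=0,
            luminal_fill=False,
        )
        summary = make_cohort(spec, out_dir=tmp_path / "cohort")
        truth = pd.read_csv(tmp_path / "cohort" / "truth.csv", comment="#")
        myo = truth[truth["kind"] == "myoepithelial"]
        assert len(myo) == 40  # 4 cases x 1 ROI x 1 duct x 10 nuclei
        assert summary.n_myoepithelial == 40

    def test_same_seed_byte_identical_truth_csv(self, tmp_path):
        spec = small_spec(ducts_per_roi=1, nuclei_per_duct=(5, 8))
        make_cohort(spec, out_dir=tmp_path / "a")
        make_cohort(spec, out_dir=tmp_path / "b")
        assert (tmp_path / "a" / "truth.csv").read_bytes() == (
            tmp_path / "b" / "truth.csv"
        ).read_bytes()

    def test_iter_cohort_case_layout(self):
        spec = small_spec(rois_per_case=2)
        entries = list(iter_cohort(spec))
        assert len(entries) == 8  # 4 cases x 2 ROIs
        cases = {e[0] for e in entries}
        assert len(cases) == 4
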