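"""End-to-end pipeline: simulate -> segment -> measure -> classify ->
aggregate -> evaluate, plus the table readers/writers shared by the CLI.

The default configuration runs a scaled benchmark cohort that preserves
the study design (22 cases, 7/5/5/5 per class, paired HE/p63 tiles) at a
tile size and nucleus count chosen so a full run completes in minutes on
one CPU; every size is configurable up to the full-scale cohort.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import (
    decide_all,
    group_proportions,
    inverse_frequency_weights,
    summaries_table,
    uniform_weights,
)
from .classify import SplitSpec, make_splits, predict, tune_and_train
from .core import CLASSES, DataError, NucleusContour, SchemaError, config_hash
from .evaluate import confusion, detection_agreement, metrics_pair
from .morphometry import FEATURE_MANIFEST, feature_vector, features_table, trim_by_size
from .segment_he import HeSegmentationParams, segment_he_roi
from .segment_p63 import (
    P63SegmentationParams,
    label_mask_from_truth,
    segment_p63_roi,
    train_pixel_classifier,
)
from .stains import DAB_RGB_OD, StainVector, estimate_stain_vectors, project_stain, rgb_to_od
from .synthetic import (
    DEFAULT_CLASS_PARAMS,
    ClassMorphologyParams,
    CohortSpec,
    GroundTruth,
    iter_cohort,
    render_stain,
)

#: Grid used by the pipeline's repeated grid searches: a coarser sweep of
#: the canonical exponential grid (full grid available via classify).
PIPELINE_GRID = {
    "C": tuple(2.0**e for e in range(-3, 10, 3)),
    "gamma": tuple(2.0**e for e in range(-9, 2, 2)),
}


def benchmark_cohort_spec(seed: int = 0) -> CohortSpec:
    """The scaled benchmark cohort: same design, ~1/10 the nuclei."""
    return CohortSpec(
        rois_per_case=2,
        ducts_per_roi=2,
        nuclei_per_duct=(9, 14),
        roi_size_px=384,
        fibroblasts_per_roi=10,
        duct_radius_frac=(0.15, 0.18),
        seed=seed,
    )


@dataclass
class PipelineConfig:
    """All knobs of one end-to-end run."""

    output_dir: str = "results"
    seed: int = 0
    cohort: CohortSpec | None = None  # default: benchmark_cohort_spec(seed)
    class_params: Mapping[str, ClassMorphologyParams] | None = None
    stains: tuple[str, ...] = ("P63", "HE")
    he_params: HeSegmentationParams = field(default_factory=HeSegmentationParams)
    p63_params: P63SegmentationParams = field(default_factory=P63SegmentationParams)
    trim_fraction: float = 0.10
    split_mode: str = "random_cell_70_30"
    repetitions: int = 5
    cv_folds: int = 5
    grid: dict = field(default_factory=lambda: dict(PIPELINE_GRID))
    pooling: str = "pooled"  # or "mean": average per-repetition metrics
    weights_mode: str = "inverse"  # or "uniform"
    save_tables: bool = True

    def __post_init__(self) -> None:
        if self.pooling not in ("pooled", "mean"):
            raise DataError(f"unknown pooling mode {self.pooling!r}")
        if self.weights_mode not in ("inverse", "uniform"):
            raise DataError(f"unknown weights mode {self.weights_mode!r}")
        if self.cohort is None:
            self.cohort = benchmark_cohort_spec(self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        if self.class_params:
            d["class_params"] = {
                k: dataclasses.asdict(v) for k, v in self.class_params.items()
            }
        return d


# ---------------------------------------------------------------------------
# Table IO: CSVs carry a single '#' metadata line (version, config hash,
# seed) and round-trip losslessly through pandas.

def write_table(df: pd.DataFrame, path: str | Path, meta: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{Path(path).name}: missing column {col!r}")
    return df


def _dab_map(pixels: np.ndarray) -> np.ndarray:
    """DAB (brown) stain projection used as the p63 nuclear channel."""
    return project_stain(rgb_to_od(pixels), StainVector(DAB_RGB_OD, "dab"))


def _hem_map(pixels: np.ndarray) -> np.ndarray:
    """Estimated hematoxylin projection used as the HE nuclear channel."""
    od = rgb_to_od(pixels)
    vectors = estimate_stain_vectors(od)
    return project_stain(od, vectors[0])


def _match_contours_to_truth(
    contours: list[NucleusContour], truth: GroundTruth
) -> dict[int, NucleusContour]:
    """Assign contours to ground-truth myoepithelial nuclei by centroid.

    The synthetic stand-in for manually picking myoepithelial nuclei off
    the paired p63 image: a contour claims the truth nucleus its centroid
    falls in; first (largest-overlap-free) match wins, unmatched contours
    (luminal/stromal nuclei, spurious detections) are discarded.
    """
    shape = truth.labels.shape
    matched: dict[int, NucleusContour] = {}
    for contour in contours:
        cy, cx = contour.centroid
        r, c = int(round(cy)), int(round(cx))
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            continue
        lab = int(truth.labels[r, c])
        if lab > 0 and lab not in matched:
            matched[lab] = contour
    return matched


def _contour_truth_iou(contour: NucleusContour, truth: GroundTruth, lab: int) -> float:
    m = contour.mask(truth.labels.shape)
    t = truth.labels == lab
    union = (m | t).sum()
    return float((m & t).sum() / union) if union else 0.0


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return (and write) the metrics report.

    Deterministic given ``config.seed``: the cohort, the pixel-classifier
    training, the split repetitions and the SVM grid search all derive
    their randomness from it.
    """
    spec = config.cohort
    params = dict(config.class_params or DEFAULT_CLASS_PARAMS)
    out_dir = Path(config.output_dir)
    meta = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config.to_dict()),
    }

    rois = list(iter_cohort(spec, params))
    if not rois:
        raise DataError("empty cohort")

    # Train the p63 pixel classifier on one DCIS ROI, then apply it to all.
    pixel_classifier = None
    if "P63" in config.stains:
        training_roi = next(
            (r for r in rois if r[2] == "HG_DCIS"), rois[-1]
        )
        _, troi_id, _, tscene, ttruth = training_roi
        timg = render_stain(tscene, "P63")
        pixel_classifier = train_pixel_classifier(
            timg,
            label_mask_from_truth(ttruth.labels),
            seed=config.seed,
            training_roi=troi_id,
        )

    records: dict[str, list] = {s: [] for s in config.stains}
    det_counts: dict[str, list] = {s: [] for s in config.stains}
    ref_counts: list[int] = []
    ious: dict[str, list] = {s: [] for s in config.stains}

    for case_id, roi_id, histotype, scene, truth in rois:
        myo = truth.myoepithelial()
        ref_counts.append(len(myo))
        by_id = {n.nucleus_id: n for n in myo}
        for stain in config.stains:
            img = render_stain(scene, stain)
            if stain == "P63":
                contours = segment_p63_roi(
                    img, pixel_classifier, truth.exclusion_mask, config.p63_params
                )
                channel = _dab_map(img.pixels)
            else:
                contours = segment_he_roi(img, truth.exclusion_mask, config.he_params)
                channel = _hem_map(img.pixels)
            matched = _match_contours_to_truth(contours, truth)
            det_counts[stain].append(len(matched))
            for lab, contour in matched.items():
                ious[stain].append(_contour_truth_iou(contour, truth, lab))
                n = by_id[lab]
                records[stain].append(
                    feature_vector(
                        contour,
                        channel,
                        cell_id=f"{roi_id}:c{lab}",
                        roi_id=roi_id,
                        duct_id=f"{roi_id}:d{n.duct_id}",
                        case_id=case_id,
                        histotype=histotype,
                    )
                )

    report: dict = {**meta, "stains": {}, "counts": {"rois": len(rois)}}
    for stain in config.stains:
        table = features_table(records[stain])
        table = trim_by_size(table, fraction=config.trim_fraction)
        if config.save_tables:
            write_table(table, out_dir / f"features_{stain}.csv", meta)

        split_spec = SplitSpec(
            mode=config.split_mode, repetitions=config.repetitions, seed=config.seed
        )
        splits = make_splits(table, split_spec)

        pred_frames = []
        rep_results = []
        for rep, (tr, te) in enumerate(splits):
            train_rows = table.iloc[tr]
            test_rows = table.iloc[te]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = tune_and_train(
                    train_rows,
                    train_rows["histotype"],
                    grid=config.grid,
                    folds=config.cv_folds,
                    seed=config.seed,
                )
            pred = predict(model, test_rows)
            frame = test_rows[
                ["cell_id", "roi_id", "duct_id", "case_id", "histotype"]
            ].copy()
            frame["predicted"] = pred
            frame["repetition"] = rep
            pred_frames.append(frame)
            if config.weights_mode == "inverse":
                weights = inverse_frequency_weights(train_rows["histotype"])
            else:
                weights = uniform_weights()
            rep_results.append((frame, weights, model))

        predictions = pd.concat(pred_frames, ignore_index=True)
        if config.save_tables:
            write_table(predictions, out_dir / f"predictions_{stain}.csv", meta)

        # Aggregate each repetition separately, then pool or average.
        level_pairs: dict[str, list[tuple[str, str]]] = {
            "cell": [],
            "duct": [],
            "patient": [],
        }
        rep_metrics: dict[str, list[dict]] = {"cell": [], "duct": [], "patient": []}
        all_summaries = {"duct": [], "patient": []}
        for frame, weights, model in rep_results:
            pairs = list(zip(frame["histotype"], frame["predicted"]))
            level_pairs["cell"].extend(pairs)
            rep_level = {"cell": pairs}
            for level, key in (("duct", "duct_id"), ("patient", "case_id")):
                summaries = group_proportions(frame, key)
                decide_all(summaries, weights)
                truth_by_group = frame.groupby(key)["histotype"].first()
                pairs = [
                    (truth_by_group[s.group_id], s.decided) for s in summaries
                ]
                level_pairs[level].extend(pairs)
                rep_level[level] = pairs
                all_summaries[level].extend(summaries)
            for level, pairs in rep_level.items():
                cm = confusion(*zip(*pairs))
                rep_metrics[level].append(metrics_pair(cm))

        stain_key = stain.lower()
        stain_report: dict = {"n_cells": int(len(table))}
        for level in ("cell", "duct", "patient"):
            cm = confusion(*zip(*level_pairs[level]))
            if config.pooling == "pooled":
                m = metrics_pair(cm)
            else:
                keys = rep_metrics[level][0].keys()
                m = {
                    k: round(float(np.mean([r[k] for r in rep_metrics[level]])), 3)
                    for k in keys
                }
            stain_report[level] = {
                "n": cm.total,
                "confusion": cm.counts.tolist(),
                **m,
            }
        stain_report["detection_agreement_pct"] = round(
            detection_agreement(det_counts[stain], ref_counts), 2
        )
        stain_report["mean_contour_iou"] = round(float(np.mean(ious[stain])), 4)
        report["stains"][stain_key] = stain_report

        if config.save_tables:
            for level in ("duct", "patient"):
                write_table(
                    summaries_table(all_summaries[level]),
                    out_dir / f"summaries_{level}_{stain}.csv",
                    meta,
                )

    report["counts"]["myoepithelial_truth"] = int(sum(ref_counts))
    if config.save_tables:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
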