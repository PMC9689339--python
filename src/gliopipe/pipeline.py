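"""Three-stage tumor analysis of a volume.

Stage 1 classifies every slice as tumorous or not; stage 2 segments the
tumor on the slices called tumorous (neighboring-FCM pipeline); stage 3
classifies the segmented tumor crop into the four glioma sub-compartments.
Non-tumorous slices skip stages 2 and 3.  With ground truth available the
report carries per-stage evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cnn.data import prepare_input
from .cnn.net import Network, predict
from .fcm import FCMParams
from .metrics import (
    ConfusionCounts,
    confusion_metrics,
    dice,
    multiclass_report,
)
from .phantom import CLASS_NAMES, MRVolume, region_masks
from .segmentation import (
    MorphParams,
    RegionGrowParams,
    SegmentationResult,
    enhance_stack,
    segment_slice,
)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "tumor_size_location"]


@dataclass
class PipelineConfig:
    #: trained binary slice classifier, or the string "oracle" to inject
    #: the volume's ground-truth slice labels
    stage1_model: Network | str | None = None
    #: trained four-class subregion classifier; ``None`` skips stage 3
    stage3_model: Network | None = None
    fcm_params: FCMParams = field(default_factory=FCMParams)
    morph_params: MorphParams = field(default_factory=MorphParams)
    rg_params: RegionGrowParams = field(default_factory=RegionGrowParams)
    evaluate: bool = True
    seed: int = 0


@dataclass
class PipelineReport:
    slice_predictions: np.ndarray
    segmentations: dict[int, SegmentationResult]
    crop_classes: dict[int, int]  # slice index -> BraTS label 1..4
    crop_class_names: dict[int, str]
    tumor_stats: dict[int, dict]
    evaluation: dict = field(default_factory=dict)


def tumor_size_location(final_mask: np.ndarray) -> dict:
    """Area, centroid and inclusive bounding box of a nonempty tumor mask."""
    mask = np.asarray(final_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty tumor mask has no size or location")
    rows, cols = np.nonzero(mask)
    return {
        "area_px": int(mask.sum()),
        "centroid": (float(rows.mean()), float(cols.mean())),
        "bounding_box": (
            int(rows.min()),
            int(rows.max()),
            int(cols.min()),
            int(cols.max()),
        ),
    }


def _dominant_label(mask: np.ndarray, within: np.ndarray | None = None) -> int | None:
    """Most frequent nonzero class label, optionally restricted to a region."""
    vals = mask[within] if within is not None else mask.ravel()
    counts = np.bincount(vals.ravel(), minlength=5)[1:]
    if counts.sum() == 0:
        return None
    return int(np.argmax(counts) + 1)


def run_pipeline(volume: MRVolume, config: PipelineConfig) -> PipelineReport:
    """Run the full multistage analysis on one volume."""
    if config.stage1_model is None:
        raise ValueError("stage-1 model missing; train or pass 'oracle'")
    slices = volume.slices

    # stage 1: per-slice tumorous / non-tumorous call
    if isinstance(config.stage1_model, str):
        if config.stage1_model != "oracle":
            raise ValueError(f"unknown stage-1 model '{config.stage1_model}'")
        pred_tumorous = volume.slice_labels.copy()
    else:
        x1 = np.stack([prepare_input(s, "binary") for s in slices])
        labels, _ = predict(config.stage1_model, x1)
        pred_tumorous = labels.astype(bool)

    # stage 2: segmentation of the slices called tumorous
    enhanced = enhance_stack(slices)
    segmentations: dict[int, SegmentationResult] = {}
    for s in np.flatnonzero(pred_tumorous):
        segmentations[int(s)] = segment_slice(
            slices,
            int(s),
            config.fcm_params,
            config.morph_params,
            config.rg_params,
            enhanced,
        )

    # stage 3: subregion classification of nonempty tumor crops
    crop_classes: dict[int, int] = {}
    crop_class_names: dict[int, str] = {}
    tumor_stats: dict[int, dict] = {}
    for s, seg in segmentations.items():
        if not seg.final_tumor_mask.any():
            continue
        tumor_stats[s] = tumor_size_location(seg.final_tumor_mask)
        if config.stage3_model is None:
            continue
        crop = prepare_input(seg.enhanced_slice, "multiclass", mask=seg.final_tumor_mask)
        lab, _ = predict(config.stage3_model, crop[None])
        crop_classes[s] = int(lab[0]) + 1
        crop_class_names[s] = CLASS_NAMES[crop_classes[s]]

    report = PipelineReport(
        slice_predictions=pred_tumorous,
        segmentations=segmentations,
        crop_classes=crop_classes,
        crop_class_names=crop_class_names,
        tumor_stats=tumor_stats,
    )
    if config.evaluate:
        report.evaluation = _evaluate(volume, report)
    return report


def _evaluate(volume: MRVolume, report: PipelineReport) -> dict:
    truth = volume.slice_labels
    pred = report.slice_predictions
    stage1 = confusion_metrics(
        ConfusionCounts(
            tp=int(np.sum(pred & truth)),
            fp=int(np.sum(pred & ~truth)),
            tn=int(np.sum(~pred & ~truth)),
            fn=int(np.sum(~pred & truth)),
        )
    )
    dscs = []
    for s, seg in report.segmentations.items():
        if not truth[s]:
            continue
        gt = region_masks(volume.multiclass_masks[s])["region1"]
        dscs.append(dice(seg.final_tumor_mask, gt))
    evaluation = {
        "stage1": stage1.to_dict(),
        "stage2_mean_dsc": float(np.mean(dscs)) if dscs else None,
    }
    if report.crop_classes:
        pairs = [
            (report.crop_classes[s], _dominant_label(volume.multiclass_masks[s]))
            for s in report.crop_classes
            if truth[s]
        ]
        pairs = [(p, t) for p, t in pairs if t is not None]
        if pairs:
            pred_l, true_l = zip(*pairs)
            evaluation["stage3"] = multiclass_report(
                np.array(pred_l), np.array(true_l), classes=[1, 2, 3, 4]
            ).to_dict()
    return evaluation
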