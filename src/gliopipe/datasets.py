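"""Synthetic training sets and benchmark suites built from phantoms.

These generators define the package's default study conditions: the
two-class patch set for the binary slice classifiers, per-subregion tumor
crops for the four-class glioma classifier, and the 20-volume phantom
suite on which the neighboring-FCM pipeline is compared against the
standard-FCM baseline.
"""

from __future__ import annotations

import numpy as np

from .cnn.data import prepare_input
from .fcm import FCMParams
from .metrics import confusion_metrics, dice, mask_confusion
from .phantom import CLASS_NAMES, MRVolume, PhantomConfig, generate_volume, region_masks
from .segmentation import MorphParams, RegionGrowParams, enhance_stack, segment_slice

__all__ = [
    "separable_patches",
    "slice_dataset",
    "subregion_crop_dataset",
    "suite_configs",
    "segmentation_suite",
    "SUITE_SHAPE",
]

#: (slices, height, width) of the benchmark phantoms; small enough for a
#: single CPU while leaving the algorithms untouched (they are size-agnostic)
SUITE_SHAPE = (41, 96, 96)


def separable_patches(n_per_class: int = 300, seed: int = 42, size: int = 30):
    """Linearly separable bright-vs-dark patch set for binary training.

    Class 0: dark noisy background patches; class 1: the same background
    with a bright central disk, emulating a tumorous slice.  Returns
    ``(x, y)`` with x of shape (2n, size, size).
    """
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    x, y = [], []
    for _ in range(n_per_class):
        bg = np.clip(0.30 + rng.normal(0, 0.05, (size, size)), 0, 1)
        x.append(bg)
        y.append(0)
        cr = size / 2 + rng.uniform(-3, 3)
        cr_c = size / 2 + rng.uniform(-3, 3)
        rad = rng.uniform(size * 0.15, size * 0.3)
        disk = (rr - cr) ** 2 + (cc - cr_c) ** 2 <= rad**2
        img = bg.copy()
        img[disk] = np.clip(0.85 + rng.normal(0, 0.05, disk.sum()), 0, 1)
        x.append(img)
        y.append(1)
    order = rng.permutation(len(x))
    return np.stack(x)[order], np.asarray(y)[order]


def slice_dataset(volumes: list[MRVolume]):
    """Whole-slice binary dataset (prepared 30x30 inputs, tumorous labels)."""
    x = [prepare_input(s, "binary") for v in volumes for s in v.slices]
    y = [int(lbl) for v in volumes for lbl in v.slice_labels]
    return np.stack(x), np.asarray(y)


def subregion_crop_dataset(volumes: list[MRVolume]):
    """Per-subregion tumor crops with four-class labels.

    For every tumorous slice, each glioma sub-compartment present
    (necrosis, edema, non-enhancing, enhancing) yields one masked crop;
    the class index is the BraTS label minus 1.
    """
    x, y = [], []
    for vol in volumes:
        for s in vol.tumorous_indices():
            mask = vol.multiclass_masks[s]
            for lab in sorted(CLASS_NAMES):
                sel = mask == lab
                if sel.any():
                    x.append(prepare_input(vol.slices[s], "multiclass", mask=sel))
                    y.append(lab - 1)
    if not x:
        raise ValueError("no tumorous slices in the provided volumes")
    return np.stack(x), np.asarray(y)


def suite_configs(n_volumes: int = 20, seed: int = 0, shape=SUITE_SHAPE) -> list[PhantomConfig]:
    """Configs of the default benchmark suite: seeded variations of the
    standard phantom scaled to the suite slice size."""
    s, h, w = shape
    rng = np.random.default_rng(seed)
    base = PhantomConfig()
    configs = []
    for i in range(n_volumes):
        lo = int(rng.integers(4, 9))
        hi = int(rng.integers(shape[0] - 9, shape[0] - 4))
        cfg = base.scaled(
            h,
            w,
            slice_count=s,
            tumorous_slice_range=(lo, hi),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        configs.append(cfg)
    return configs


def _scaled_min_px(cfg: PhantomConfig, base_min_px: int = 256) -> int:
    # 256 px is calibrated to 240x240 slices; scale by pixel count
    return max(8, round(base_min_px * cfg.height * cfg.width / (240 * 240)))


def segmentation_suite(
    configs: list[PhantomConfig],
    window_halfwidth: int = 2,
    fcm_params: FCMParams | None = None,
) -> dict:
    """Run the slice-segmentation pipeline over a phantom suite.

    Returns per-volume mean Dice of the final tumor mask against the
    complete-tumor ground truth, plus the fraction of non-tumorous slices
    on which the pipeline (correctly) produced an empty final mask.
    """
    if fcm_params is None:
        fcm_params = FCMParams(window_halfwidth=window_halfwidth)
    else:
        fcm_params = FCMParams(
            c=fcm_params.c,
            q=fcm_params.q,
            tol=fcm_params.tol,
            max_iter=fcm_params.max_iter,
            window_halfwidth=window_halfwidth,
            edge_mode=fcm_params.edge_mode,
        )
    per_volume = []
    sens, spec = [], []
    empty_on_clean = 0
    clean_total = 0
    rg = RegionGrowParams()
    for cfg in configs:
        vol = generate_volume(cfg)
        morph = MorphParams(min_px=_scaled_min_px(cfg))
        enhanced = enhance_stack(vol.slices)
        dscs = []
        for s in vol.tumorous_indices():
            res = segment_slice(vol.slices, int(s), fcm_params, morph, rg, enhanced)
            truth = region_masks(vol.multiclass_masks[s])["region1"]
            dscs.append(dice(res.final_tumor_mask, truth))
            rep = confusion_metrics(mask_confusion(res.final_tumor_mask, truth))
            if rep.sensitivity is not None:
                sens.append(rep.sensitivity)
            if rep.specificity is not None:
                spec.append(rep.specificity)
        per_volume.append(float(np.mean(dscs)))
        for s in np.flatnonzero(~vol.slice_labels):
            res = segment_slice(vol.slices, int(s), fcm_params, morph, rg, enhanced)
            clean_total += 1
            empty_on_clean += int(not res.final_tumor_mask.any())
    return {
        "per_volume_dsc": per_volume,
        "mean_dsc": float(np.mean(per_volume)),
        "mean_sensitivity": float(np.mean(sens)) if sens else None,
        "mean_specificity": float(np.mean(spec)) if spec else None,
        "empty_fraction_on_clean_slices": (
            empty_on_clean / clean_total if clean_total else None
        ),
    }
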