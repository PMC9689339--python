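"""Tumor segmentation of a slice stack by neighboring fuzzy c-means.

The pipeline for one slice, in order:

1. percentile contrast stretch saturating the darkest and brightest 1% of
   pixels of each window slice;
2. fuzzy c-means on the window-averaged enhanced intensities (or on the
   single slice for the standard-FCM baseline);
3. binarization keeping the pixels whose strongest membership belongs to
   the brightest cluster (tumors appear bright in the modalities modelled);
4. removal of connected components smaller than a pixel-count threshold;
5. morphological gap filling with a 2x2 structuring element;
6. per-object roundness scoring (4*pi*A/P^2) and selection of the roundest
   object as the initial tumor segment;
7. seeded region growing from that segment with an intensity tolerance
   around the running region mean.

Every intermediate mask is retained in the returned result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from .fcm import FCMParams, FCMState, neighboring_fcm, standard_fcm, window_average

__all__ = [
    "MorphParams",
    "RegionGrowParams",
    "RegionObject",
    "SegmentationResult",
    "enhance_contrast",
    "enhance_stack",
    "binarize_from_fcm",
    "remove_small_regions",
    "fill_gaps",
    "score_objects",
    "select_tumor_object",
    "region_grow",
    "segment_slice",
]

_FOOTPRINTS = {4: ndi.generate_binary_structure(2, 1), 8: ndi.generate_binary_structure(2, 2)}


@dataclass(frozen=True)
class MorphParams:
    min_px: int = 256
    connectivity: int = 8
    se_size: int = 2
    #: "close" = dilate then erode (fills gaps); "open" = the literal
    #: erode-then-dilate order.
    fill_order: str = "close"

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.fill_order not in ("close", "open"):
            raise ValueError("fill_order must be 'close' or 'open'")


@dataclass(frozen=True)
class RegionGrowParams:
    #: absolute intensity tolerance; ``None`` selects 0.15 x the intensity
    #: standard deviation inside the brain (nonzero) area of the enhanced slice
    tau: float | None = None
    auto_scale: float = 0.15
    connectivity: int = 8


@dataclass(frozen=True)
class RegionObject:
    """One connected component of a binary mask with its shape descriptors."""

    mask: np.ndarray
    area: int
    perimeter: float
    roundness: float
    centroid: tuple[float, float]


@dataclass
class SegmentationResult:
    enhanced_slice: np.ndarray
    fcm_state: FCMState
    fcm_binary_mask: np.ndarray
    cleaned_mask: np.ndarray
    initial_tumor_mask: np.ndarray
    final_tumor_mask: np.ndarray
    selected_object: RegionObject | None
    metadata: dict = field(default_factory=dict)


def enhance_contrast(slice_: np.ndarray, low_frac: float = 0.01, high_frac: float = 0.01) -> np.ndarray:
    """Linear stretch saturating the extreme intensity fractions to 0 and 1.

    A constant slice cannot be stretched and is returned unchanged.
    """
    slice_ = np.asarray(slice_, dtype=np.float64)
    if not np.all(np.isfinite(slice_)):
        raise ValueError("slice intensities must be finite")
    lo = np.quantile(slice_, low_frac)
    hi = np.quantile(slice_, 1.0 - high_frac)
    if hi <= lo:
        return slice_.copy()
    return np.clip((slice_ - lo) / (hi - lo), 0.0, 1.0)


def enhance_stack(stack: np.ndarray) -> np.ndarray:
    """Contrast-stretch every slice of an (S, H, W) stack independently."""
    return np.stack([enhance_contrast(s) for s in np.asarray(stack, dtype=np.float64)])


def binarize_from_fcm(state: FCMState) -> np.ndarray:
    """Mask of pixels whose strongest membership is in the brightest cluster.

    Membership ties resolve toward the brighter cluster.
    """
    order = np.argsort(state.centroids, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    u = state.memberships[:, order]  # columns sorted dark -> bright
    lab = u.shape[1] - 1 - np.argmax(u[:, ::-1], axis=1)
    return (lab == u.shape[1] - 1).reshape(state.grid_shape)


def remove_small_regions(mask: np.ndarray, min_px: int = 256, connectivity: int = 8) -> np.ndarray:
    """Drop connected components with fewer than ``min_px`` pixels.

    Components of exactly ``min_px`` pixels survive.  Idempotent.
    """
    mask = np.asarray(mask, dtype=bool)
    lab, n = ndi.label(mask, structure=_FOOTPRINTS[connectivity])
    if n == 0:
        return mask.copy()
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[lab]


def fill_gaps(mask: np.ndarray, se_size: int = 2, order: str = "close") -> np.ndarray:
    """Morphological gap filling with a square structuring element.

    ``order='close'`` (default) dilates then erodes; ``order='open'``
    applies the literal erode-then-dilate sequence.
    """
    mask = np.asarray(mask, dtype=bool)
    se = np.ones((se_size, se_size), dtype=bool)
    if order not in ("close", "open"):
        raise ValueError("order must be 'close' or 'open'")
    # pad so the result equals the infinite-domain (background outside)
    # composition, independent of array borders
    padded = np.pad(mask, se_size, constant_values=False)
    if order == "close":
        out = ndi.binary_erosion(ndi.binary_dilation(padded, se), se)
    else:
        out = ndi.binary_dilation(ndi.binary_erosion(padded, se), se)
    return out[se_size:-se_size, se_size:-se_size]


def score_objects(mask: np.ndarray, connectivity: int = 8) -> list[RegionObject]:
    """One :class:`RegionObject` per connected component.

    Roundness is the circularity 4*pi*A/P^2 with the perimeter measured on
    the traced component outline; a component whose outline has zero length
    (a single pixel) gets roundness 0.
    """
    mask = np.asarray(mask, dtype=bool)
    lab = measure.label(mask, connectivity=2 if connectivity == 8 else 1)
    objects = []
    for prop in measure.regionprops(lab):
        perim = float(prop.perimeter)
        area = int(prop.area)
        roundness = 4.0 * np.pi * area / perim**2 if perim > 0 else 0.0
        objects.append(
            RegionObject(
                mask=lab == prop.label,
                area=area,
                perimeter=perim,
                roundness=roundness,
                centroid=tuple(prop.centroid),
            )
        )
    return objects


def select_tumor_object(objects: list[RegionObject]) -> RegionObject | None:
    """Most round object; ties broken by larger area, then smaller centroid.

    Returns ``None`` for an empty list (the slice is declared tumor-free at
    this stage).
    """
    if not objects:
        return None
    return max(
        objects,
        key=lambda o: (o.roundness, o.area, -o.centroid[0], -o.centroid[1]),
    )


def region_grow(
    enhanced_slice: np.ndarray,
    seed_mask: np.ndarray,
    tau: float,
    connectivity: int = 8,
) -> np.ndarray:
    """Grow a seed region by absorbing adjacent pixels near the region mean.

    Each sweep adds every pixel adjacent to the current region whose
    intensity lies within ``tau`` of the current region mean, then
    recomputes the mean; sweeps repeat until no pixel is added.  The output
    is always a superset of the seed.
    """
    img = np.asarray(enhanced_slice, dtype=np.float64)
    region = np.asarray(seed_mask, dtype=bool).copy()
    if region.shape != img.shape:
        raise ValueError("seed mask must match slice dimensions")
    if not region.any():
        raise ValueError("region growing requires a nonempty seed")
    footprint = _FOOTPRINTS[connectivity]
    while True:
        mean = img[region].mean()
        frontier = ndi.binary_dilation(region, structure=footprint) & ~region
        accept = frontier & (np.abs(img - mean) <= tau)
        if not accept.any():
            return region
        region |= accept


def _auto_tau(enhanced: np.ndarray, params: RegionGrowParams) -> float:
    if params.tau is not None:
        return params.tau
    brain = enhanced > 0.01  # background saturates to 0 after the stretch
    ref = enhanced[brain] if brain.any() else enhanced.ravel()
    return params.auto_scale * float(ref.std())


def segment_slice(
    stack: np.ndarray,
    slice_index: int,
    fcm_params: FCMParams = FCMParams(),
    morph_params: MorphParams = MorphParams(),
    rg_params: RegionGrowParams = RegionGrowParams(),
    enhanced_stack: np.ndarray | None = None,
) -> SegmentationResult:
    """Full segmentation of one slice of an (S, H, W) stack.

    With ``fcm_params.window_halfwidth == 0`` this is the standard-FCM
    baseline of the same pipeline.  If no object survives the cleaning
    stages the result carries an empty final mask rather than raising.
    ``enhanced_stack`` may carry the per-slice contrast-stretched stack
    precomputed by :func:`enhance_stack` when segmenting many slices of
    the same volume.
    """
    if hasattr(stack, "slices"):  # MRVolume passed directly
        stack = stack.slices
    stack = np.asarray(stack, dtype=np.float64)
    if enhanced_stack is None:
        enhanced_stack = enhance_stack(stack)
    enhanced = enhanced_stack[slice_index]
    constant = bool(np.ptp(stack[slice_index]) == 0)

    if fcm_params.window_halfwidth == 0:
        state = standard_fcm(enhanced, fcm_params)
    else:
        state = neighboring_fcm(enhanced_stack, slice_index, fcm_params)

    binary = binarize_from_fcm(state)
    cleaned = remove_small_regions(binary, morph_params.min_px, morph_params.connectivity)
    cleaned = fill_gaps(cleaned, morph_params.se_size, morph_params.fill_order)
    objects = score_objects(cleaned, morph_params.connectivity)
    selected = select_tumor_object(objects)

    if selected is None:
        empty = np.zeros_like(binary)
        initial, final = empty, empty.copy()
        tau = None
    else:
        initial = selected.mask
        tau = _auto_tau(enhanced, rg_params)
        final = region_grow(enhanced, initial, tau, rg_params.connectivity)

    return SegmentationResult(
        enhanced_slice=enhanced,
        fcm_state=state,
        fcm_binary_mask=binary,
        cleaned_mask=cleaned,
        initial_tumor_mask=initial,
        final_tumor_mask=final,
        selected_object=selected,
        metadata={
            "constant_slice": constant,
            "tau": tau,
            "roundness": [o.roundness for o in objects],
            "window_halfwidth": fcm_params.window_halfwidth,
        },
    )
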