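"""Deterministic preparation of slices and tumor crops for the CNNs.

The binary stage feeds the whole slice, min-max normalized and bilinearly
resized to 30x30.  The multiclass stage crops the tumor bounding box,
zeroes everything outside the tumor mask, pads the crop to a centered
square, and resizes the same way.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = ["bilinear_resize", "prepare_input", "split_dataset"]

TARGET = 30


def bilinear_resize(image: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resampling on the half-pixel-center grid (align_corners=False)."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    if (h, w) == (out_h, out_w):
        return image.copy()
    rows = (np.arange(out_h) + 0.5) * h / out_h - 0.5
    cols = (np.arange(out_w) + 0.5) * w / out_w - 0.5
    rr, cc = np.meshgrid(
        np.clip(rows, 0, h - 1), np.clip(cols, 0, w - 1), indexing="ij"
    )
    return ndi.map_coordinates(image, [rr, cc], order=1, mode="nearest")


def _normalize(image: np.ndarray) -> np.ndarray:
    lo, hi = image.min(), image.max()
    if hi <= lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def prepare_input(
    image: np.ndarray,
    stage: str = "binary",
    mask: np.ndarray | None = None,
    target: int = TARGET,
) -> np.ndarray:
    """Turn a slice (or mask-cropped tumor region) into a CNN input grid.

    ``stage='binary'`` normalizes and resizes the whole slice;
    ``stage='multiclass'`` requires a nonempty tumor ``mask``, crops its
    bounding box (masked outside the tumor), pads to a centered square and
    resizes.  Output is ``target x target`` in [0, 1].
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("expected a nonempty 2-D image")
    if stage == "binary":
        return bilinear_resize(_normalize(image), target, target)
    if stage != "multiclass":
        raise ValueError("stage must be 'binary' or 'multiclass'")
    if mask is None:
        raise ValueError("multiclass stage requires a tumor mask")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask must match image dimensions")
    if not mask.any():
        raise ValueError("empty tumor crop")
    rows, cols = np.nonzero(mask)
    crop = np.where(mask, image, 0.0)[
        rows.min() : rows.max() + 1, cols.min() : cols.max() + 1
    ]
    ch, cw = crop.shape
    side = max(ch, cw)
    padded = np.zeros((side, side))
    r0, c0 = (side - ch) // 2, (side - cw) // 2
    padded[r0 : r0 + ch, c0 : c0 + cw] = crop
    return bilinear_resize(_normalize(padded), target, target)


def split_dataset(
    x: np.ndarray,
    y: np.ndarray,
    fractions: tuple[float, ...] = (0.6, 0.2, 0.2),
    seed: int = 0,
):
    """Shuffle and split into consecutive subsets (e.g. train/val/test).

    ``fractions`` must sum to 1; returns one ``(x, y)`` pair per fraction.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(x)
    perm = np.random.default_rng(seed).permutation(n)
    cuts = np.cumsum([int(round(f * n)) for f in fractions[:-1]])
    parts = np.split(perm, cuts)
    return [(x[p], y[p]) for p in parts]
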