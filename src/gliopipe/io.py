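"""Reading and writing MR volumes as PNG slice stacks with a JSON manifest.

Each slice is stored as an 8- or 16-bit grayscale PNG named
``slice_####.png``; multiclass masks as ``mask_####.png`` holding the
literal label values 0-4; a ``manifest.json`` records dimensions, per-slice
labels and free-form metadata.  NIfTI export of the full volume is
available through nibabel.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .phantom import MRVolume

__all__ = ["save_volume", "load_volume", "save_nifti"]

_MANIFEST = "manifest.json"


def save_volume(
    volume: MRVolume,
    directory: str | Path,
    bit_depth: int = 16,
    metadata: dict | None = None,
) -> Path:
    """Write a volume as PNG slices + masks + JSON manifest; returns the dir."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vmax = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    for i, sl in enumerate(volume.slices):
        arr = np.round(np.clip(sl, 0.0, 1.0) * vmax).astype(dtype)
        Image.fromarray(arr).save(directory / f"slice_{i:04d}.png")
        Image.fromarray(volume.multiclass_masks[i]).save(directory / f"mask_{i:04d}.png")
    manifest = {
        "n_slices": volume.n_slices,
        "height": volume.shape[1],
        "width": volume.shape[2],
        "bit_depth": bit_depth,
        "modality_tag": volume.modality_tag,
        "slice_labels": [
            "tumorous" if t else "non-tumorous" for t in volume.slice_labels
        ],
        "metadata": metadata or {},
    }
    (directory / _MANIFEST).write_text(json.dumps(manifest, indent=2))
    return directory


def load_volume(directory: str | Path) -> MRVolume:
    """Read back a PNG stack written by :func:`save_volume`."""
    directory = Path(directory)
    manifest = json.loads((directory / _MANIFEST).read_text())
    n = manifest["n_slices"]
    vmax = 2 ** manifest["bit_depth"] - 1
    slices = np.stack(
        [
            np.asarray(Image.open(directory / f"slice_{i:04d}.png"), dtype=np.float64)
            / vmax
            for i in range(n)
        ]
    )
    masks = np.stack(
        [
            np.asarray(Image.open(directory / f"mask_{i:04d}.png"), dtype=np.uint8)
            for i in range(n)
        ]
    )
    labels = np.array([lbl == "tumorous" for lbl in manifest["slice_labels"]])
    return MRVolume(slices, labels, masks, modality_tag=manifest["modality_tag"])


def save_nifti(volume: MRVolume, path: str | Path) -> Path:
    """Export the intensity volume as a NIfTI-1 file (slices along axis 2)."""
    import nibabel as nib

    data = np.transpose(volume.slices, (1, 2, 0)).astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine=np.eye(4)), str(path))
    return Path(path)
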