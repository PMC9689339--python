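"""Synthetic brain-MR phantoms with ground-truth tumor annotations.

Generates T1-like axial slice stacks containing three healthy-tissue
intensity bands (CSF dark, grey matter intermediate, white matter bright),
a slow polynomial bias field, additive Gaussian noise, and a bright
quasi-circular glioma whose cross-section drifts and changes size smoothly
across consecutive slices.  Every slice carries a binary tumorous /
non-tumorous label and a per-pixel multiclass mask using the BraTS label
coding: 0 background/healthy, 1 necrosis, 2 edema, 3 non-enhancing tumor,
4 enhancing tumor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TumorConfig",
    "PhantomConfig",
    "MRVolume",
    "REGION_LABELS",
    "CLASS_NAMES",
    "generate_volume",
    "region_masks",
    "manifest_totals",
]

#: Tumor sub-compartments: region 1 = complete tumor, region 2 = tumor core,
#: region 3 = enhancing tumor.
REGION_LABELS = {
    "region1": frozenset({1, 2, 3, 4}),
    "region2": frozenset({1, 3, 4}),
    "region3": frozenset({4}),
}

CLASS_NAMES = {1: "necrosis", 2: "edema", 3: "non-enhancing", 4: "enhancing"}

# Radial order of the sub-compartments from tumor center outward: necrotic
# core, non-enhancing patches, enhancing rim, edema halo.
_RADIAL_ORDER = (1, 3, 4, 2)


@dataclass(frozen=True)
class TumorConfig:
    """Geometry and intensities of the simulated glioma.

    ``center`` is the (row, col) offset of the tumor center from the brain
    center on the middle tumorous slice; ``drift`` is the per-slice (row,
    col) displacement, giving a smoothly moving cross-section.  The radius
    on slice ``s`` is ``base_radius * (1 - modulation * cos(pi*t)**2)``
    with ``t`` the normalized position inside the tumorous slice range: an
    ellipsoid-like profile peaking mid-range and tapering smoothly toward
    both ends, so the area changes gradually between adjacent slices.

    ``subregion_fractions`` are radial extents (fractions of the tumor
    radius, summing to 1) occupied by labels 1, 3, 4 and 2 from the center
    outward; ``subregion_intensities`` are their noise-free means in [0, 1].
    """

    center: tuple[float, float] = (-18.0, 22.0)
    drift: tuple[float, float] = (0.6, 0.4)
    base_radius: float = 34.0
    modulation: float = 0.20
    subregion_fractions: dict[int, float] = field(
        default_factory=lambda: {1: 0.25, 3: 0.15, 4: 0.35, 2: 0.25}
    )
    #: FLAIR-like contrast: enhancing rim brightest, non-enhancing patches
    #: clearly hyperintense, the infiltrative edema halo intermediate
    #: (its fringe blends toward white matter), necrotic core dark
    subregion_intensities: dict[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.80, 3: 0.82, 4: 0.95}
    )


@dataclass(frozen=True)
class PhantomConfig:
    slice_count: int = 31
    height: int = 240
    width: int = 240
    tissue_intensities: dict[str, float] = field(
        default_factory=lambda: {"csf": 0.15, "gm": 0.45, "wm": 0.65}
    )
    tumor: TumorConfig = field(default_factory=TumorConfig)
    #: additive Gaussian noise inside the brain; 0.08 corresponds to a
    #: white-matter SNR of about 8, typical of clinical MR
    noise_sigma: float = 0.08
    bias_field_amplitude: float = 0.05
    #: inclusive (first, last) slice index containing tumor; ``None`` for a
    #: tumor-free volume.
    tumorous_slice_range: tuple[int, int] | None = (8, 22)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slice_count < 1 or self.height < 8 or self.width < 8:
            raise ValueError("phantom dimensions too small")
        fr = self.tumor.subregion_fractions
        if set(fr) != {1, 2, 3, 4}:
            raise ValueError("subregion_fractions must cover labels 1-4")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError("subregion fractions must sum to 1")
        for name, v in {
            **self.tissue_intensities,
            **{CLASS_NAMES[k]: v for k, v in self.tumor.subregion_intensities.items()},
        }.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"mean intensity {name}={v} outside [0, 1]")
        if self.tumorous_slice_range is not None:
            lo, hi = self.tumorous_slice_range
            if not (0 <= lo <= hi < self.slice_count):
                raise ValueError("tumorous_slice_range outside the volume")

    def scaled(self, height: int, width: int, **kwargs) -> "PhantomConfig":
        """Copy of the config with geometry scaled to a new slice size."""
        f = min(height / self.height, width / self.width)
        t = self.tumor
        tumor = replace(
            t,
            center=(t.center[0] * f, t.center[1] * f),
            drift=(t.drift[0] * f, t.drift[1] * f),
            base_radius=t.base_radius * f,
        )
        return replace(self, height=height, width=width, tumor=tumor, **kwargs)


@dataclass
class MRVolume:
    """An ordered stack of 2-D grayscale slices with ground-truth labels.

    ``slices`` is (S, H, W) float in [0, 1], row-major with origin at the
    top-left; ``slice_labels`` is a boolean per-slice tumorous flag;
    ``multiclass_masks`` is (S, H, W) uint8 with values 0-4.
    """

    slices: np.ndarray
    slice_labels: np.ndarray
    multiclass_masks: np.ndarray
    modality_tag: str = "synthetic-T1"

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.float64)
        self.slice_labels = np.asarray(self.slice_labels, dtype=bool)
        self.multiclass_masks = np.asarray(self.multiclass_masks, dtype=np.uint8)
        if self.slices.ndim != 3:
            raise ValueError("slices must be a (S, H, W) stack")
        if self.multiclass_masks.shape != self.slices.shape:
            raise ValueError("masks must match slice dimensions")
        if self.slice_labels.shape != (self.slices.shape[0],):
            raise ValueError("one label per slice required")
        bad = np.setdiff1d(np.unique(self.multiclass_masks), [0, 1, 2, 3, 4])
        if bad.size:
            raise ValueError(f"mask labels outside 0..4: {bad.tolist()}")
        nonzero = self.multiclass_masks.reshape(len(self.slices), -1).any(axis=1)
        if np.any(nonzero & ~self.slice_labels):
            raise ValueError("nonzero mask on a slice labelled non-tumorous")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.slices.shape

    def tumorous_indices(self) -> np.ndarray:
        return np.flatnonzero(self.slice_labels)


def _brain_geometry(h: int, w: int):
    rows = np.arange(h)[:, None] - (h - 1) / 2.0
    cols = np.arange(w)[None, :] - (w - 1) / 2.0
    a, b = 0.42 * h, 0.38 * w  # brain ellipse semi-axes
    e = np.sqrt((rows / a) ** 2 + (cols / b) ** 2)
    return rows, cols, a, b, e


def _render_tissue(cfg: PhantomConfig) -> np.ndarray:
    h, w = cfg.height, cfg.width
    rows, cols, a, b, e = _brain_geometry(h, w)
    ti = cfg.tissue_intensities
    img = np.zeros((h, w))
    img[e <= 1.0] = ti["gm"]
    img[e <= 0.82] = ti["wm"]
    # two lateral-ventricle CSF ellipses near the brain center
    for sign in (-1.0, 1.0):
        vr = (rows + 0.05 * a) / (0.24 * a)
        vc = (cols - sign * 0.18 * b) / (0.10 * b)
        img[vr**2 + vc**2 <= 1.0] = ti["csf"]
    return img


def _bias_field(cfg: PhantomConfig) -> np.ndarray:
    h, w = cfg.height, cfg.width
    u = np.linspace(-1.0, 1.0, h)[:, None]
    v = np.linspace(-1.0, 1.0, w)[None, :]
    surface = 0.6 * u + 0.4 * v - 0.5 * u * v + 0.3 * u**2
    return cfg.bias_field_amplitude * surface


def _tumor_geometry(cfg: PhantomConfig, s: int):
    """Center (row, col) and radius of the tumor on slice ``s``."""
    lo, hi = cfg.tumorous_slice_range
    mid = 0.5 * (lo + hi)
    t = 0.5 if hi == lo else (s - lo) / (hi - lo)
    radius = cfg.tumor.base_radius * (1.0 - cfg.tumor.modulation * np.cos(np.pi * t) ** 2)
    cr = (cfg.height - 1) / 2.0 + cfg.tumor.center[0] + cfg.tumor.drift[0] * (s - mid)
    cc = (cfg.width - 1) / 2.0 + cfg.tumor.center[1] + cfg.tumor.drift[1] * (s - mid)
    return cr, cc, radius


def generate_volume(config: PhantomConfig) -> MRVolume:
    """Render a seeded phantom volume with ground truth.

    Deterministic for a fixed seed.  Raises ``ValueError`` if the tumor
    (including its edema halo) would not fit inside the brain ellipse on
    some tumorous slice.
    """
    h, w, s_count = config.height, config.width, config.slice_count
    rows, cols, a, b, _ = _brain_geometry(h, w)
    tissue = _render_tissue(config)
    bias = _bias_field(config)
    rng = np.random.default_rng(config.seed)

    slices = np.empty((s_count, h, w))
    masks = np.zeros((s_count, h, w), dtype=np.uint8)
    labels = np.zeros(s_count, dtype=bool)

    t_range = config.tumorous_slice_range
    t_slices = [] if t_range is None else list(range(t_range[0], t_range[1] + 1))

    # cumulative radial boundaries of the sub-compartments
    fr = config.tumor.subregion_fractions
    bounds = np.cumsum([fr[lab] for lab in _RADIAL_ORDER])

    for s in range(s_count):
        img = tissue.copy()
        if s in t_slices:
            cr, cc, radius = _tumor_geometry(config, s)
            # conservative fit check against the brain ellipse
            er = (cr - (h - 1) / 2.0) / a
            ec = (cc - (w - 1) / 2.0) / b
            if np.sqrt(er**2 + ec**2) + radius / min(a, b) > 1.0:
                raise ValueError(
                    f"tumor of radius {radius:.1f}px at slice {s} does not fit "
                    "inside the brain ellipse; reduce base_radius or drift"
                )
            rho = np.sqrt((rows + (h - 1) / 2.0 - cr) ** 2 + (cols + (w - 1) / 2.0 - cc) ** 2)
            rho = rho / radius
            mask = np.zeros((h, w), dtype=np.uint8)
            inner = 0.0
            for lab, outer in zip(_RADIAL_ORDER, bounds):
                if outer <= inner:  # zero-width compartment configured away
                    continue
                ring = (rho > inner if inner else rho >= 0) & (rho <= outer)
                mask[ring] = lab
                img[ring] = config.tumor.subregion_intensities[lab]
                inner = outer
            masks[s] = mask
            labels[s] = bool(mask.any())
        # skull-stripped convention: bias and noise only inside the brain,
        # the background stays exactly zero
        brain = img > 0
        img = img + np.where(brain, bias, 0.0)
        if config.noise_sigma > 0:
            img = img + np.where(
                brain, rng.normal(0.0, config.noise_sigma, size=img.shape), 0.0
            )
        slices[s] = np.clip(img, 0.0, 1.0)

    return MRVolume(slices, labels, masks)


def region_masks(mask: np.ndarray) -> dict[str, np.ndarray]:
    """Binary sub-compartment masks from a multiclass mask.

    Returns ``region1`` (complete tumor, labels 1+2+3+4), ``region2``
    (tumor core, 1+3+4) and ``region3`` (enhancing tumor, 4).
    """
    mask = np.asarray(mask)
    bad = np.setdiff1d(np.unique(mask), [0, 1, 2, 3, 4])
    if bad.size:
        raise ValueError(f"mask labels outside 0..4: {bad.tolist()}")
    return {
        name: np.isin(mask, sorted(labels))
        for name, labels in REGION_LABELS.items()
    }


def manifest_totals(cases: int, modalities: int, slices_per_modality: int) -> dict[str, int]:
    """Image-count bookkeeping for a multi-modality MR dataset manifest."""
    for name, v in {
        "cases": cases,
        "modalities": modalities,
        "slices_per_modality": slices_per_modality,
    }.items():
        if int(v) != v or v <= 0:
            raise ValueError(f"{name} must be a positive integer, got {v}")
    images_per_case = modalities * slices_per_modality
    return {
        "images_per_case": images_per_case,
        "total_images": cases * images_per_case,
        "annotation_images": cases * slices_per_modality,
    }
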