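"""Pre-processing: HU windowing, normalisation, CLAHE, slice selection, augmentation.

The adrenal gland sits in a narrow soft-tissue band of the Hounsfield
scale, so raw scans are first clipped to a (10, 60) HU window, rescaled to
[0, 1] over that window, and contrast-enhanced with CLAHE.  For training
only, slices that contain no gland are discarded (the gland typically
appears on a handful of the scan's slices) and the remainder is expanded
with random rotations and flips applied identically to image and label.
Test volumes are always processed whole.

Stage order is clip -> normalize -> CLAHE: clipping first makes the
normalisation window well-defined.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterator

import numpy as np
from skimage import exposure, transform

from .io_nifti import CtVolume, MaskVolume

__all__ = [
    "PreprocessConfig",
    "AugmentConfig",
    "SliceItem",
    "SliceDataset",
    "clip_hounsfield",
    "normalize",
    "apply_clahe",
    "preprocess_volume",
    "select_slices",
    "augment",
    "resize_slice",
]


@dataclasses.dataclass
class PreprocessConfig:
    """Intensity pre-processing parameters.

    hu_low / hu_high bound the soft-tissue window in Hounsfield units
    (default 10..60, the window in which adrenal tissue is separable from
    its surroundings).  CLAHE runs on the normalised [0, 1] slice with
    ``clahe_tile_grid`` tiles and clip limit ``clahe_clip_limit``.
    """

    hu_low: float = 10.0
    hu_high: float = 60.0
    clahe_clip_limit: float = 0.01
    clahe_tile_grid: tuple[int, int] = (8, 8)
    apply_clahe: bool = True

    def __post_init__(self) -> None:
        if self.hu_low >= self.hu_high:
            raise ValueError(
                f"hu_low must be below hu_high, got ({self.hu_low}, {self.hu_high})"
            )
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be positive")
        if min(self.clahe_tile_grid) < 1:
            raise ValueError("clahe_tile_grid entries must be >= 1")


@dataclasses.dataclass
class AugmentConfig:
    """Geometric training-data augmentation.

    Each source slice gains ``copies_per_slice`` augmented copies (default
    2, i.e. a threefold dataset: 1749 gland slices become 5247).  A copy
    draws a rotation angle uniformly in +/-``rotation_max_deg`` and,
    when ``allow_flips``, independent 50% horizontal/vertical flips; the
    same transform is applied to image and label, and labels are
    re-binarised after interpolation.
    """

    copies_per_slice: int = 2
    rotation_max_deg: float = 15.0
    allow_flips: bool = True
    seed: int = 0
    max_retries: int = 10

    def __post_init__(self) -> None:
        if self.copies_per_slice < 0:
            raise ValueError("copies_per_slice must be >= 0")
        if self.rotation_max_deg <= 0:
            raise ValueError("rotation_max_deg must be positive")


@dataclasses.dataclass
class SliceItem:
    image: np.ndarray  # 2D, values in [0, 1]
    label: np.ndarray  # 2D, values in {0, 1}
    scan_id: str
    augmented: bool = False

    def __post_init__(self) -> None:
        if self.image.shape != self.label.shape:
            raise ValueError(
                f"image/label shape mismatch: {self.image.shape} vs {self.label.shape}"
            )


class SliceDataset:
    """An ordered collection of (image, label) slice pairs tagged by scan."""

    def __init__(self, items: list[SliceItem] | None = None):
        self.items: list[SliceItem] = list(items or [])

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[SliceItem]:
        return iter(self.items)

    def __getitem__(self, i: int) -> SliceItem:
        return self.items[i]

    def append(self, item: SliceItem) -> None:
        self.items.append(item)

    def extend(self, other: "SliceDataset") -> None:
        self.items.extend(other.items)

    @property
    def scan_ids(self) -> set[str]:
        return {it.scan_id for it in self.items}

    def images(self) -> np.ndarray:
        return np.stack([it.image for it in self.items])

    def labels(self) -> np.ndarray:
        return np.stack([it.label for it in self.items])


def clip_hounsfield(volume: CtVolume, cfg: PreprocessConfig | None = None) -> CtVolume:
    """Clip every voxel into the [hu_low, hu_high] window (idempotent)."""
    cfg = cfg or PreprocessConfig()
    return volume.with_voxels(np.clip(volume.voxels, cfg.hu_low, cfg.hu_high))


def normalize(volume: CtVolume, cfg: PreprocessConfig | None = None) -> CtVolume:
    """Affinely rescale the HU window to [0, 1]; run after clipping.

    ``hu_low`` maps to 0 and ``hu_high`` (the maximum value a clipped
    voxel can take) to 1.
    """
    cfg = cfg or PreprocessConfig()
    width = cfg.hu_high - cfg.hu_low
    if width <= 0:
        raise ValueError("zero-width normalisation window")
    return volume.with_voxels((volume.voxels - cfg.hu_low) / width)


def apply_clahe(image: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation on one [0,1] slice."""
    cfg = cfg or PreprocessConfig()
    image = np.asarray(image, dtype=np.float64)
    if image.min() < -1e-6 or image.max() > 1 + 1e-6:
        raise ValueError("apply_clahe expects a normalised image in [0, 1]")
    kernel = (
        image.shape[0] // cfg.clahe_tile_grid[0],
        image.shape[1] // cfg.clahe_tile_grid[1],
    )
    if min(kernel) < 1:
        raise ValueError(
            f"tile grid {cfg.clahe_tile_grid} larger than image {image.shape}"
        )
    out = exposure.equalize_adapthist(
        np.clip(image, 0.0, 1.0), kernel_size=kernel, clip_limit=cfg.clahe_clip_limit
    )
    return out.astype(np.float32)


def preprocess_volume(volume: CtVolume, cfg: PreprocessConfig | None = None) -> CtVolume:
    """Full intensity pipeline: clip -> normalize -> (per-slice) CLAHE."""
    cfg = cfg or PreprocessConfig()
    vol = normalize(clip_hounsfield(volume, cfg), cfg)
    if cfg.apply_clahe:
        out = np.stack([apply_clahe(s, cfg) for s in vol.voxels])
        vol = vol.with_voxels(out)
    return vol


def resize_slice(image: np.ndarray, shape: tuple[int, int],
                 is_label: bool = False) -> np.ndarray:
    """Resize one slice to a target in-plane shape.

    Harmonises scanner matrix sizes (e.g. 768x768 down to 512x512) for a
    fixed-input model.  Images are interpolated bilinearly; labels
    nearest-neighbour and re-binarised.
    """
    order = 0 if is_label else 1
    out = transform.resize(np.asarray(image, dtype=np.float32), shape, order=order,
                           mode="edge", anti_aliasing=not is_label,
                           preserve_range=True)
    if is_label:
        return (out > 0.5).astype(np.uint8)
    return out.astype(np.float32)


def select_slices(volume: CtVolume, mask: MaskVolume) -> SliceDataset:
    """Keep exactly the axial slices whose label has foreground (training only).

    Order is preserved and the scan id propagates to every item.  Test
    volumes are never filtered — the model is evaluated on whole scans.
    """
    if volume.shape != mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match mask {mask.shape}"
        )
    ds = SliceDataset()
    for k in range(volume.n_slices):
        lab = mask.voxels[k]
        if lab.any():
            ds.append(
                SliceItem(
                    np.asarray(volume.voxels[k], dtype=np.float32),
                    lab.astype(np.uint8),
                    volume.patient_id,
                )
            )
    return ds


def _transform_pair(
    image: np.ndarray, label: np.ndarray, angle: float, flip_lr: bool, flip_ud: bool
) -> tuple[np.ndarray, np.ndarray]:
    img = image
    lab = label.astype(np.float32)
    if angle != 0.0:
        img = transform.rotate(img, angle, order=1, mode="constant", cval=0.0,
                               preserve_range=True)
        lab = transform.rotate(lab, angle, order=0, mode="constant", cval=0.0,
                               preserve_range=True)
    if flip_ud:
        img, lab = img[::-1, :], lab[::-1, :]
    if flip_lr:
        img, lab = img[:, ::-1], lab[:, ::-1]
    return (
        np.clip(img, 0.0, 1.0).astype(np.float32),
        (lab > 0.5).astype(np.uint8),
    )


def augment(dataset: SliceDataset, cfg: AugmentConfig | None = None) -> SliceDataset:
    """Expand a training dataset with rotated/flipped copies.

    Output size is ``len(dataset) * (1 + copies_per_slice)`` (originals are
    retained).  A draw that rotates the gland out of frame, emptying the
    label, is re-drawn up to ``max_retries`` times, then skipped with a
    warning.  Deterministic under ``cfg.seed``.
    """
    cfg = cfg or AugmentConfig()
    rng = np.random.default_rng(cfg.seed)
    out = SliceDataset(list(dataset.items))
    for item in dataset:
        if not item.label.any():
            raise ValueError("augment expects training slices with nonempty labels")
        for _ in range(cfg.copies_per_slice):
            for _attempt in range(cfg.max_retries):
                angle = float(rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg))
                flip_lr = cfg.allow_flips and bool(rng.random() < 0.5)
                flip_ud = cfg.allow_flips and bool(rng.random() < 0.5)
                img, lab = _transform_pair(item.image, item.label, angle, flip_lr, flip_ud)
                if lab.any():
                    out.append(SliceItem(img, lab, item.scan_id, augmented=True))
                    break
            else:
                warnings.warn(
                    f"augmentation emptied the label for scan {item.scan_id}; copy skipped",
                    stacklevel=2,
                )
    return out
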