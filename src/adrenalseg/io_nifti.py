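"""NIfTI input/output and the in-memory volume containers.

The pipeline works on axial CT volumes: axis 0 indexes the axial slice,
so ``voxels[k]`` is one 2D slice (row, col).  Volumes carry Hounsfield-unit
(HU) voxels; masks are strictly binary.  Multi-organ label maps (e.g. the
AMOS annotation convention, one integer id per organ) must be split into a
binary mask per gland with :func:`extract_label` before entering the
pipeline — left and right adrenal glands are segmented by independent
binary models.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "CtVolume",
    "MaskVolume",
    "ProbVolume",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "extract_label",
]


@dataclasses.dataclass
class CtVolume:
    """A 3D CT volume in Hounsfield units.

    Parameters
    ----------
    voxels
        3D float array, axes ``(slice, row, col)``; axis 0 is the axial
        (cranio-caudal) direction.
    spacing_mm
        Voxel spacing along each axis in millimetres, all positive.
    patient_id
        Identifier of the source scan; used to enforce train/validation
        exclusivity and per-patient evaluation.
    affine
        4x4 voxel-to-world matrix, carried opaquely for round-tripping.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    patient_id: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(f"expected a 3D volume, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxels")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing_mm) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def slice(self, k: int) -> np.ndarray:
        """Return axial slice ``k`` as a 2D (row, col) array."""
        return self.voxels[k]

    def with_voxels(self, voxels: np.ndarray) -> "CtVolume":
        return CtVolume(voxels, self.spacing_mm, self.patient_id, self.affine)


@dataclasses.dataclass
class MaskVolume:
    """A binary ground-truth or predicted mask co-registered to a CtVolume."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    patient_id: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {arr.shape}")
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded, atol=1e-6) or not np.isin(
            rounded, (0, 1)
        ).all():
            bad = np.unique(arr)[:10]
            raise ValueError(f"mask values must be binary, found {bad}")
        self.voxels = rounded.astype(np.uint8)
        if self.affine is None:
            self.affine = np.diag(list(self.spacing_mm) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    def slice(self, k: int) -> np.ndarray:
        return self.voxels[k]


@dataclasses.dataclass
class ProbVolume:
    """A per-voxel probability map (sigmoid outputs before thresholding)."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    patient_id: str = ""
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D probability map, got shape {self.voxels.shape}")
        if self.voxels.min() < -1e-6 or self.voxels.max() > 1 + 1e-6:
            raise ValueError("probabilities must lie in [0, 1]")
        np.clip(self.voxels, 0.0, 1.0, out=self.voxels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def _load(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {data.ndim} dimensions")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms, np.asarray(img.affine)


def read_volume(path: str | Path) -> CtVolume:
    """Read a CT volume from a NIfTI-1 file (.nii or .nii.gz).

    Voxels are promoted to float32; spacing comes from the header zooms.
    The patient id defaults to the file stem.
    """
    data, zooms, affine = _load(path)
    stem = Path(path).name.removesuffix(".gz").removesuffix(".nii")
    return CtVolume(data.astype(np.float32), zooms, stem, affine)


def read_mask(path: str | Path, reference: CtVolume | None = None) -> MaskVolume:
    """Read a binary mask, optionally enforcing co-registration to a volume.

    Raises
    ------
    ValueError
        If the file contains non-binary labels (split multi-organ maps
        with :func:`extract_label` first) or its shape differs from the
        reference volume.
    """
    data, zooms, affine = _load(path)
    if reference is not None and data.shape != reference.shape:
        raise ValueError(
            f"mask shape {data.shape} does not match reference {reference.shape}"
        )
    pid = reference.patient_id if reference is not None else Path(path).name.removesuffix(
        ".gz"
    ).removesuffix(".nii")
    return MaskVolume(data, zooms, pid, affine)


def write_volume(volume: CtVolume, path: str | Path) -> None:
    """Write a CT volume to NIfTI-1, preserving affine and spacing."""
    img = nib.Nifti1Image(volume.voxels.astype(np.float32), volume.affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def write_mask(mask: MaskVolume, path: str | Path) -> None:
    """Write a binary mask to NIfTI-1 as 8-bit integers."""
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))


def extract_label(path: str | Path, label_id: int, reference: CtVolume | None = None) -> MaskVolume:
    """Extract one integer organ id from a multi-organ label map.

    AMOS-style annotations store all organs in one file, one integer per
    organ; the pipeline only ever sees binary masks, so each gland is
    pulled out separately.
    """
    data, zooms, affine = _load(path)
    if reference is not None and data.shape != reference.shape:
        raise ValueError(
            f"label map shape {data.shape} does not match reference {reference.shape}"
        )
    binary = (np.rint(data).astype(np.int64) == int(label_id)).astype(np.uint8)
    pid = reference.patient_id if reference is not None else ""
    return MaskVolume(binary, zooms, pid, affine)
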