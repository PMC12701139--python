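"""Post-processing: flip test-time augmentation and unconnected-region removal.

Flip TTA predicts each axial slice four times — as-is, mirrored
left/right, mirrored up/down, and mirrored both ways — maps every
prediction back to the original orientation, and averages the four
probability maps.  A predictor whose errors differ between orientations
has them averaged down; a flip-equivariant predictor is left exactly
unchanged.

The gland occupies one spatially coherent region per scan, so after
thresholding, foreground voxels disconnected from the main region are
outliers (typically false positives far from the gland) and are removed
by keeping the largest 3D connected component.

Pipeline order: predict -> TTA average -> threshold -> component filter.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io_nifti import CtVolume, MaskVolume, ProbVolume
from .model import Predictor, predict_volume

__all__ = [
    "TtaConfig",
    "ComponentFilterConfig",
    "tta_predict",
    "binarize",
    "remove_unconnected",
]


@dataclasses.dataclass
class TtaConfig:
    """TTA switch and the probability threshold applied after averaging."""

    enabled: bool = True
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must lie in (0, 1), got {self.threshold}")


@dataclasses.dataclass
class ComponentFilterConfig:
    """Connected-component filtering policy.

    ``connectivity`` counts 3D neighbours (6 faces, 18 +edges, 26
    +corners; default 26).  Policy ``keep-largest`` retains exactly the
    largest component; ``min-size`` retains every component of at least
    ``min_size`` voxels.  ``mode`` selects 3D whole-scan components
    (default) or per-slice 2D components.
    """

    connectivity: int = 26
    policy: str = "keep-largest"
    min_size: int = 1
    mode: str = "3d"

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of {6, 18, 26}")
        if self.policy not in ("keep-largest", "min-size"):
            raise ValueError("policy must be 'keep-largest' or 'min-size'")
        if self.mode not in ("3d", "2d"):
            raise ValueError("mode must be '3d' or '2d'")


def _flip_lr(x: np.ndarray) -> np.ndarray:
    return x[:, ::-1]  # column (left/right) reversal of an axial slice


def _flip_ud(x: np.ndarray) -> np.ndarray:
    return x[::-1, :]  # row (up/down) reversal of an axial slice


def tta_predict(predictor: Predictor, volume: CtVolume,
                cfg: TtaConfig | None = None) -> ProbVolume:
    """Average the four flip-view predictions per axial slice.

    For each slice x the four views are predicted and mapped back to the
    original frame before averaging:

    1. ``p0 = f(x)``
    2. ``p1 = unflipLR(f(flipLR(x)))``
    3. ``p2 = unflipUD(f(flipUD(x)))``
    4. ``p3 = unflipUD(unflipLR(f(flipLR(flipUD(x)))))``
    5. output ``(p0 + p1 + p2 + p3) / 4``

    With ``cfg.enabled`` false this degrades to plain slice-wise
    prediction.
    """
    cfg = cfg or TtaConfig()
    if not cfg.enabled:
        return predict_volume(predictor, volume)
    v = volume.voxels
    if v.min() < -1e-6 or v.max() > 1 + 1e-6:
        raise ValueError("tta_predict expects a normalised volume in [0, 1]")
    out = np.empty_like(v, dtype=np.float32)
    for k in range(volume.n_slices):
        x = v[k]
        preds = []
        for view, unview in (
            (lambda s: s, lambda s: s),
            (_flip_lr, _flip_lr),
            (_flip_ud, _flip_ud),
            (lambda s: _flip_lr(_flip_ud(s)), lambda s: _flip_ud(_flip_lr(s))),
        ):
            p = np.asarray(predictor(np.ascontiguousarray(view(x))), dtype=np.float32)
            if p.shape != x.shape:
                raise ValueError(f"predictor changed shape: {p.shape} vs {x.shape}")
            preds.append(unview(p))
        out[k] = np.mean(preds, axis=0)
    return ProbVolume(out, volume.spacing_mm, volume.patient_id, volume.affine)


def binarize(prob: ProbVolume, threshold: float = 0.5) -> MaskVolume:
    """Threshold a probability map; voxels with p >= threshold are foreground."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return MaskVolume(
        (prob.voxels >= threshold).astype(np.uint8),
        prob.spacing_mm,
        prob.patient_id,
        prob.affine,
    )


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _filter_3d(mask: np.ndarray, cfg: ComponentFilterConfig) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_STRUCTURES[cfg.connectivity])
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    if cfg.policy == "min-size":
        keep = np.flatnonzero(sizes >= cfg.min_size) + 1
        return np.isin(labels, keep).astype(np.uint8)
    best = int(np.max(sizes))
    candidates = np.flatnonzero(sizes == best) + 1
    if len(candidates) > 1:
        # tie-break: keep the component whose minimum voxel coordinate is
        # lexicographically smallest (scan order)
        coords = np.argwhere(np.isin(labels, candidates))
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
        winner = labels[tuple(coords[order[0]])]
    else:
        winner = candidates[0]
    return (labels == winner).astype(np.uint8)


def remove_unconnected(mask: MaskVolume,
                       cfg: ComponentFilterConfig | None = None) -> MaskVolume:
    """Remove foreground disconnected from the main gland region.

    Under the default keep-largest policy the output is exactly the
    largest connected component of the input (the whole input if it is
    already connected, empty if it is empty).  Idempotent, and never adds
    voxels.
    """
    cfg = cfg or ComponentFilterConfig()
    src = mask.voxels
    if not src.any():
        return mask
    if cfg.mode == "2d":
        out = np.stack([_filter_3d(s[None], cfg)[0] for s in src])
    else:
        out = _filter_3d(src, cfg)
    return MaskVolume(out, mask.spacing_mm, mask.patient_id, mask.affine)
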