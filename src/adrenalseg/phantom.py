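"""Synthetic CT phantoms with gland-like labels and a controllable noisy oracle.

A phantom is an axial stack of soft-tissue slices (Gaussian HU noise
around a soft-tissue mean) containing one small, irregular,
ellipsoid-like "gland" spanning a contiguous run of slices — the regime
that makes adrenal segmentation hard: a small low-contrast target inside
the (10, 60) HU window.  Optional spurious bright structures far from the
gland exercise the false-positive failure mode.

The noisy oracle wraps a ground-truth mask as a slice predictor whose
output is the truth corrupted by boundary jitter, occasional slice
dropout, and distant high-probability blobs.  Its noise is seeded from a
hash of the presented pixel pattern, so it is a pure function of its
input, yet the four flip views of a slice receive independent noise —
exactly the situation in which flip test-time averaging helps and
connected-component filtering removes the distant blobs.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np
from scipy import ndimage

from .io_nifti import CtVolume, MaskVolume
from .model import Predictor
from .preprocess import PreprocessConfig, preprocess_volume

__all__ = [
    "PhantomSpec",
    "NoisyOracleSpec",
    "BenchmarkScan",
    "generate_phantom",
    "make_noisy_oracle",
    "make_benchmark_suite",
]


@dataclasses.dataclass
class PhantomSpec:
    """Geometry and HU statistics of one synthetic scan.

    Background and gland HU distributions overlap inside the (10, 60)
    soft-tissue window so the clipping and CLAHE stages act on realistic
    low-contrast input.  ``surface_irregularity`` is the relative
    amplitude of a smooth low-frequency perturbation of the ellipsoid
    radius; ``n_spurious_structures`` adds bright structures far from the
    gland in the image (not the label).
    """

    shape: tuple[int, int, int] = (32, 96, 96)
    background_hu: tuple[float, float] = (30.0, 15.0)
    gland_hu: tuple[float, float] = (45.0, 8.0)
    gland_semi_axes: tuple[float, float, float] = (4.0, 7.0, 5.0)
    gland_center_jitter: int = 2
    surface_irregularity: float = 0.15
    n_spurious_structures: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 4:
            raise ValueError("phantom shape too small")
        if self.background_hu[1] < 0 or self.gland_hu[1] < 0:
            raise ValueError("HU standard deviations must be >= 0")
        margin = 1.0 + max(self.surface_irregularity, 0.0)
        for ax in range(3):
            reach = self.gland_semi_axes[ax] * margin + self.gland_center_jitter
            if reach >= self.shape[ax] / 2:
                raise ValueError(
                    f"gland (axis {ax}) would exceed the volume bounds"
                )


@dataclasses.dataclass
class NoisyOracleSpec:
    """Controllable failure modes of the oracle predictor.

    boundary_noise_sd  Gaussian probability jitter in a 1-voxel band
                       around the gland boundary of each slice.
    fp_blob_rate       expected number of distant spurious blobs per scan
                       (per orientation view).
    fp_blob_size       inclusive pixel-count range of one blob.
    fn_dropout         probability that a gland slice's prediction is
                       zeroed entirely.
    orientation_bias   noise-amplitude multiplier applied to the three
                       flipped views (1.0 = same statistics as upright).
    min_blob_distance  minimum Chebyshev distance (voxels) between a blob
                       centre and the gland bounding box.
    """

    boundary_noise_sd: float = 0.35
    fp_blob_rate: float = 1.5
    fp_blob_size: tuple[int, int] = (8, 30)
    fn_dropout: float = 0.05
    orientation_bias: float = 1.0
    min_blob_distance: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_noise_sd < 0 or self.fp_blob_rate < 0:
            raise ValueError("noise rates must be >= 0")
        if not 0.0 <= self.fn_dropout <= 1.0:
            raise ValueError("fn_dropout must be a probability")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int, int]) -> np.ndarray:
    """A smooth low-frequency random field with roughly unit amplitude."""
    coarse = rng.standard_normal((4, 4, 4))
    zoom = [s / 4 for s in shape]
    field = ndimage.zoom(coarse, zoom, order=3, mode="nearest")
    # pad/trim rounding artefacts from zoom
    field = field[: shape[0], : shape[1], : shape[2]]
    out = np.zeros(shape)
    out[: field.shape[0], : field.shape[1], : field.shape[2]] = field
    peak = np.abs(out).max()
    return out / peak if peak > 0 else out


def generate_phantom(spec: PhantomSpec | None = None) -> tuple[CtVolume, MaskVolume]:
    """Generate one (CT volume, gland mask) pair, deterministic under seed."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    center = np.array([nz / 2, ny / 2, nx / 2]) + rng.uniform(
        -spec.gland_center_jitter, spec.gland_center_jitter, size=3
    )
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    r = np.sqrt(
        ((zz - center[0]) / spec.gland_semi_axes[0]) ** 2
        + ((yy - center[1]) / spec.gland_semi_axes[1]) ** 2
        + ((xx - center[2]) / spec.gland_semi_axes[2]) ** 2
    )
    if spec.surface_irregularity > 0:
        radius_limit = 1.0 + spec.surface_irregularity * _smooth_field(rng, spec.shape)
    else:
        radius_limit = 1.0
    mask = (r <= radius_limit).astype(np.uint8)

    bg_mean, bg_sd = spec.background_hu
    gl_mean, gl_sd = spec.gland_hu
    voxels = rng.normal(bg_mean, bg_sd, size=spec.shape)
    gland_tex = rng.normal(gl_mean, gl_sd, size=spec.shape)
    voxels = np.where(mask.astype(bool), gland_tex, voxels)

    # optional bright spurious structures in the image, far from the gland
    if spec.n_spurious_structures > 0:
        bbox = np.argwhere(mask)
        lo, hi = bbox.min(axis=0), bbox.max(axis=0)
        for _ in range(spec.n_spurious_structures):
            for _attempt in range(100):
                c = np.array([rng.integers(3, s - 3) for s in spec.shape])
                cheb = max(
                    max(lo[a] - c[a], c[a] - hi[a], 0) for a in range(3)
                )
                if cheb >= 8:
                    break
            ball = (
                ((zz - c[0]) / 2.0) ** 2
                + ((yy - c[1]) / 3.0) ** 2
                + ((xx - c[2]) / 3.0) ** 2
            ) <= 1.0
            voxels = np.where(ball, rng.normal(58.0, 3.0, size=spec.shape), voxels)

    vol = CtVolume(
        voxels.astype(np.float32),
        spacing_mm=(3.0, 0.8, 0.8),
        patient_id=f"phantom-{spec.seed}",
    )
    return vol, MaskVolume(mask, vol.spacing_mm, vol.patient_id, vol.affine)


_ORIENTATIONS = (
    ("id", lambda s: s),
    ("lr", lambda s: s[:, ::-1]),
    ("ud", lambda s: s[::-1, :]),
    ("udlr", lambda s: s[::-1, ::-1]),
)


def make_noisy_oracle(
    truth: MaskVolume, spec: NoisyOracleSpec, images: CtVolume
) -> Predictor:
    """Wrap a truth mask as a content-seeded noisy slice predictor.

    ``images`` must be the preprocessed volume whose slices will be fed
    to the predictor: the oracle recognises a presented slice (in any of
    the four flip orientations) by exact pixel content and returns the
    correspondingly oriented truth slice, corrupted by the failure modes
    in ``spec``.  The corruption RNG is seeded from a CRC of the pixel
    bytes, so the predictor is pure while flipped views get independent
    noise realisations.  Unrecognised input yields an all-zero map.
    """
    if truth.shape != images.shape:
        raise ValueError("truth and image volume shapes differ")
    index: dict[bytes, tuple[int, str]] = {}
    for k in range(images.shape[0]):
        for name, orient in _ORIENTATIONS:
            key = np.ascontiguousarray(
                orient(images.voxels[k]), dtype=np.float32
            ).tobytes()
            index.setdefault(key, (k, name))

    truth_f = truth.voxels.astype(np.float32)
    n_slices = truth.shape[0]
    p_blob = min(spec.fp_blob_rate / n_slices, 1.0) if n_slices else 0.0

    def predictor(image: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(image, dtype=np.float32)
        key = x.tobytes()
        hit = index.get(key)
        if hit is None:
            return np.zeros_like(x)
        k, name = hit
        orient = dict(_ORIENTATIONS)[name]
        base = np.ascontiguousarray(orient(truth_f[k])).copy()
        rng = np.random.default_rng((zlib.crc32(key) ^ (spec.seed * 2654435761)) % 2**31)
        amp = 1.0 if name == "id" else spec.orientation_bias
        has_gland = base.any()

        if has_gland and spec.fn_dropout > 0 and rng.random() < spec.fn_dropout:
            base = np.zeros_like(base)
        elif has_gland and spec.boundary_noise_sd > 0:
            fg = base > 0.5
            band = ndimage.binary_dilation(fg) ^ ndimage.binary_erosion(fg)
            noise = rng.normal(0.0, spec.boundary_noise_sd * amp, size=base.shape)
            base[band] = np.clip(base[band] + noise[band], 0.0, 1.0)

        if p_blob > 0 and rng.random() < p_blob:
            blob = _place_blob(rng, base.shape, orient(truth.voxels[k]),
                               spec.fp_blob_size, spec.min_blob_distance)
            if blob is not None:
                base = np.maximum(base, blob)
        return base

    return predictor


def _place_blob(
    rng: np.random.Generator,
    shape: tuple[int, int],
    truth_slice: np.ndarray,
    size_range: tuple[int, int],
    min_distance: int,
) -> np.ndarray | None:
    """A high-probability disk whose centre keeps a Chebyshev margin from the gland."""
    h, w = shape
    fg = np.argwhere(truth_slice)
    if fg.size:
        lo, hi = fg.min(axis=0), fg.max(axis=0)
    else:
        lo = hi = None
    area = int(rng.integers(size_range[0], size_range[1] + 1))
    radius = max(1.0, np.sqrt(area / np.pi))
    for _attempt in range(50):
        cy = int(rng.integers(2, h - 2))
        cx = int(rng.integers(2, w - 2))
        if lo is not None:
            cheb = max(lo[0] - cy, cy - hi[0], lo[1] - cx, cx - hi[1])
            if cheb < min_distance:
                continue
        yy, xx = np.ogrid[:h, :w]
        disk = ((yy - cy) ** 2 + (xx - cx) ** 2) <= radius**2
        return np.where(disk, 0.95, 0.0).astype(np.float32)
    return None


@dataclasses.dataclass
class BenchmarkScan:
    """One phantom scan ready for prediction: raw, preprocessed, truth, oracle."""

    scan_id: str
    seed: int
    volume: CtVolume
    preprocessed: CtVolume
    truth: MaskVolume
    predictor: Predictor


def make_benchmark_suite(
    n_scans: int,
    phantom: PhantomSpec | None = None,
    oracle: NoisyOracleSpec | None = None,
    seed: int = 0,
    preprocess_cfg: PreprocessConfig | None = None,
) -> tuple[list[BenchmarkScan], dict]:
    """Generate ``n_scans`` seeded phantom scans with per-scan noisy oracles.

    Per-scan seeds are spawned from the master seed, so the whole suite
    (volumes, masks, and oracle noise) is reproducible from one integer.
    Returns the scans and a manifest of seeds and slice/voxel counts.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    phantom = phantom or PhantomSpec()
    oracle = oracle or NoisyOracleSpec()
    preprocess_cfg = preprocess_cfg or PreprocessConfig()
    ss = np.random.SeedSequence(seed)
    scan_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_scans)]
    scans: list[BenchmarkScan] = []
    manifest: dict = {"master_seed": seed, "n_scans": n_scans, "scans": []}
    for i, s in enumerate(scan_seeds):
        pspec = dataclasses.replace(phantom, seed=s)
        vol, mask = generate_phantom(pspec)
        vol.patient_id = mask.patient_id = f"phantom-{i:03d}"
        pre = preprocess_volume(vol, preprocess_cfg)
        ospec = dataclasses.replace(oracle, seed=s)
        pred = make_noisy_oracle(mask, ospec, pre)
        scans.append(BenchmarkScan(vol.patient_id, s, vol, pre, mask, pred))
        manifest["scans"].append(
            {
                "scan_id": vol.patient_id,
                "seed": s,
                "n_slices": vol.n_slices,
                "foreground_voxels": mask.foreground_count(),
            }
        )
    manifest["total_slices"] = int(sum(m["n_slices"] for m in manifest["scans"]))
    return scans, manifest
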