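"""Slice predictor contract, reference 2D UNet, Jaccard loss, and training.

The pipeline is model-agnostic: any callable that maps a 2D image in
[0, 1] to a same-shaped probability map in [0, 1] — deterministically —
can plug in as the ``Predictor``.  The published pipeline was evaluated
with six such backbones (VGG16/ResNet34/InceptionV3 UNets, plain UNet,
nnUNet, TransUNet); this package ships a small reference UNet implemented
in numpy so the whole pipeline trains on a desktop CPU in minutes, and
the post-processing stages are tested against pluggable oracles.

Training minimises the smoothed soft Jaccard (1 - IoU) loss with Adam on
mini-batches; scans contributing slices to the training and validation
sets must be mutually exclusive, which is enforced, and no early stopping
is applied.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Protocol, runtime_checkable

import numpy as np

from ._nn import Adam, Conv2D, MaxPool2, ReLU, Upsample2, sigmoid
from .io_nifti import CtVolume, ProbVolume
from .preprocess import SliceDataset

__all__ = [
    "Predictor",
    "TrainConfig",
    "jaccard_loss",
    "UNet",
    "build_reference_unet",
    "train",
    "predict_volume",
]


@runtime_checkable
class Predictor(Protocol):
    """A pure function from a 2D [0,1] image to a same-shape [0,1] map."""

    def __call__(self, image: np.ndarray) -> np.ndarray: ...


@dataclasses.dataclass
class TrainConfig:
    """Mini-batch training parameters (Adam, batch 4 by default).

    ``epochs`` defaults to 100 as in full-scale training; desk-scale runs
    override it downward.  ``smoothing_eps`` is the additive smoothing in
    the soft Jaccard loss.
    """

    batch_size: int = 4
    epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0
    smoothing_eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def jaccard_loss(pred: np.ndarray, truth: np.ndarray, eps: float = 1e-6) -> float:
    """Smoothed soft Jaccard loss 1 - IoU, in [0, 1).

    ``1 - (sum(p*t) + eps) / (sum(p) + sum(t) - sum(p*t) + eps)`` with the
    sums taken over all pixels.  With binary ``pred == truth`` the loss
    tends to 0; with disjoint binary masks it tends to 1.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    inter = float((pred * truth).sum())
    union = float(pred.sum() + truth.sum() - inter)
    return 1.0 - (inter + eps) / (union + eps)


def _jaccard_grad(pred: np.ndarray, truth: np.ndarray, eps: float) -> np.ndarray:
    """dL/dpred for the smoothed soft Jaccard loss."""
    inter = float((pred * truth).sum())
    union = float(pred.sum() + truth.sum() - inter)
    denom = (union + eps) ** 2
    return (-(truth * (union + eps)) + (inter + eps) * (1.0 - truth)) / denom


class UNet:
    """A small encoder-decoder with skip connections and a sigmoid head.

    ``depth`` pooling stages double the channel count each level; the
    decoder mirrors them with nearest-neighbour upsampling and
    concatenates the equal-level encoder features before each
    convolution.  Input spatial dimensions must be divisible by
    ``2**depth``.  Weight initialisation is deterministic under ``seed``,
    and inference is deterministic always.
    """

    def __init__(self, depth: int = 2, base_channels: int = 8, seed: int = 0):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.enc = [
            Conv2D(1 if d == 0 else base_channels * 2 ** (d - 1),
                   base_channels * 2**d, 3, rng)
            for d in range(depth)
        ]
        self.enc_act = [ReLU() for _ in range(depth)]
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = Conv2D(base_channels * 2 ** (depth - 1),
                                 base_channels * 2**depth, 3, rng)
        self.bott_act = ReLU()
        self.ups = [Upsample2() for _ in range(depth)]
        # decoder conv at level d sees skip (base*2^d) + upsampled (base*2^(d+1))
        self.dec = [
            Conv2D(base_channels * 2**d + base_channels * 2 ** (d + 1),
                   base_channels * 2**d, 3, rng)
            for d in range(depth)
        ]
        self.dec_act = [ReLU() for _ in range(depth)]
        self.head = Conv2D(base_channels, 1, 1, rng)
        self._skip_channels = [base_channels * 2**d for d in range(depth)]

    @property
    def params(self):
        out = []
        for layer in [*self.enc, self.bottleneck, *self.dec, self.head]:
            out.extend(layer.params)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Batch forward pass: x is (N, 1, H, W); returns probabilities."""
        n, _, h, w = x.shape
        if h % 2**self.depth or w % 2**self.depth:
            raise ValueError(
                f"input size {(h, w)} not divisible by 2^depth={2**self.depth}"
            )
        skips = []
        hcur = x.astype(np.float32)
        for d in range(self.depth):
            hcur = self.enc_act[d].forward(self.enc[d].forward(hcur))
            skips.append(hcur)
            hcur = self.pools[d].forward(hcur)
        hcur = self.bott_act.forward(self.bottleneck.forward(hcur))
        for d in reversed(range(self.depth)):
            hcur = self.ups[d].forward(hcur)
            hcur = np.concatenate([skips[d], hcur], axis=1)
            hcur = self.dec_act[d].forward(self.dec[d].forward(hcur))
        self._p = sigmoid(self.head.forward(hcur))
        return self._p

    def backward(self, dp: np.ndarray) -> None:
        """Backprop dL/dp through the sigmoid head and the whole graph."""
        p = self._p
        dz = (dp * p * (1.0 - p)).astype(np.float32)
        dh = self.head.backward(dz)
        dskips = [None] * self.depth
        for d in range(self.depth):
            dh = self.dec[d].backward(self.dec_act[d].backward(dh))
            c_skip = self._skip_channels[d]
            dskips[d] = dh[:, :c_skip]
            dh = self.ups[d].backward(dh[:, c_skip:])
        dh = self.bottleneck.backward(self.bott_act.backward(dh))
        for d in reversed(range(self.depth)):
            dh = self.pools[d].backward(dh)
            dh = dh + dskips[d]
            dh = self.enc[d].backward(self.enc_act[d].backward(dh))

    def __call__(self, image: np.ndarray) -> np.ndarray:
        """Predictor interface: one 2D slice in, one probability map out."""
        image = np.asarray(image, dtype=np.float32)
        if image.ndim != 2:
            raise ValueError("predictor expects a single 2D slice")
        return self.forward(image[None, None])[0, 0]

    # -- checkpointing -------------------------------------------------
    def save(self, path) -> None:
        arrays = {}
        for i, (p, _) in enumerate(self.params):
            arrays[f"p{i}"] = p
        np.savez(path, depth=self.depth, **arrays)

    def load(self, path) -> None:
        data = np.load(path)
        for i, (p, _) in enumerate(self.params):
            p[...] = data[f"p{i}"]


def build_reference_unet(depth: int = 2, base_channels: int = 8, seed: int = 0) -> UNet:
    """Construct the reference UNet with deterministic initial weights."""
    return UNet(depth=depth, base_channels=base_channels, seed=seed)


def train(
    model: UNet | Callable[[], UNet],
    data: SliceDataset,
    val: SliceDataset | None,
    cfg: TrainConfig | None = None,
) -> tuple[UNet, list[dict]]:
    """Fit the model on a slice dataset with Adam and soft Jaccard loss.

    Returns the fitted model and a per-epoch log of train/validation
    loss (one entry per epoch; no early stopping).  Raises if any scan
    contributes slices to both the training and validation sets — that
    would leak patients across the split.
    """
    cfg = cfg or TrainConfig()
    if callable(model) and not isinstance(model, UNet):
        model = model()
    if len(data) == 0:
        raise ValueError("empty training dataset")
    if val is not None and len(val) > 0:
        overlap = data.scan_ids & val.scan_ids
        if overlap:
            raise ValueError(
                f"train/validation scans must be mutually exclusive; shared: {sorted(overlap)}"
            )
    rng = np.random.default_rng(cfg.seed)
    x = data.images()[:, None].astype(np.float32)
    y = data.labels()[:, None].astype(np.float32)
    xv = yv = None
    if val is not None and len(val) > 0:
        xv = val.images()[:, None].astype(np.float32)
        yv = val.labels()[:, None].astype(np.float32)
    opt = Adam(model.params, lr=cfg.learning_rate)
    n = len(data)
    log: list[dict] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            p = model.forward(x[idx])
            losses.append(jaccard_loss(p, y[idx], cfg.smoothing_eps))
            model.backward(
                _jaccard_grad(p.astype(np.float64), y[idx].astype(np.float64),
                              cfg.smoothing_eps)
            )
            opt.step()
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if xv is not None:
            entry["val_loss"] = float(
                np.mean([jaccard_loss(model.forward(xv[i : i + 1]), yv[i : i + 1],
                                      cfg.smoothing_eps) for i in range(len(xv))])
            )
        log.append(entry)
    return model, log


def predict_volume(predictor: Predictor, volume: CtVolume) -> ProbVolume:
    """Apply a slice predictor to every axial slice of a preprocessed volume."""
    v = volume.voxels
    if v.min() < -1e-6 or v.max() > 1 + 1e-6:
        raise ValueError("predict_volume expects a normalised volume in [0, 1]")
    out = np.stack([np.asarray(predictor(v[k]), dtype=np.float32)
                    for k in range(volume.n_slices)])
    if out.shape != v.shape:
        raise ValueError(f"predictor changed shape: {out.shape} vs {v.shape}")
    return ProbVolume(out, volume.spacing_mm, volume.patient_id, volume.affine)
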