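"""Published adrenal-gland benchmark results used as statistical inputs.

Before/after post-processing Dice scores for six slice-segmentation
models (UNet variants with VGG16/ResNet34/InceptionV3 backbones, plain
UNet, nnUNet, TransUNet) on the AMOS and MICCAI Multi-Atlas abdominal CT
test sets, per gland, as reported in the published benchmark of this
pipeline; plus the pooled voxel confusion counts for the VGG16 model on
AMOS.  These numbers are inputs to the statistics layer (increase rates,
bilateral averages, paired t-tests, ANOVA) — nothing in this module is
computed by this package.
"""

from __future__ import annotations

import pandas as pd

from .metrics import ConfusionCounts, comparison_table

__all__ = [
    "MODELS",
    "dice_before_after",
    "VGG16_AMOS_CONFUSION",
    "table3_vgg16_amos",
]

MODELS = ["VGG16", "ResNet34", "InceptionV3", "UNet", "nnUNet", "TransUNet"]

# (dataset, gland, model, mean per-scan Dice before post-processing, after)
_DICE_ROWS = [
    ("AMOS", "left", "VGG16", 0.82, 0.91),
    ("AMOS", "left", "ResNet34", 0.76, 0.89),
    ("AMOS", "left", "InceptionV3", 0.59, 0.85),
    ("AMOS", "left", "UNet", 0.72, 0.89),
    ("AMOS", "left", "nnUNet", 0.85, 0.92),
    ("AMOS", "left", "TransUNet", 0.88, 0.92),
    ("AMOS", "right", "VGG16", 0.75, 0.90),
    ("AMOS", "right", "ResNet34", 0.79, 0.88),
    ("AMOS", "right", "InceptionV3", 0.77, 0.89),
    ("AMOS", "right", "UNet", 0.80, 0.90),
    ("AMOS", "right", "nnUNet", 0.82, 0.91),
    ("AMOS", "right", "TransUNet", 0.83, 0.93),
    ("MICCAI", "left", "VGG16", 0.78, 0.90),
    ("MICCAI", "left", "ResNet34", 0.53, 0.78),
    ("MICCAI", "left", "InceptionV3", 0.74, 0.82),
    ("MICCAI", "left", "UNet", 0.76, 0.85),
    ("MICCAI", "left", "nnUNet", 0.80, 0.90),
    ("MICCAI", "left", "TransUNet", 0.79, 0.91),
    ("MICCAI", "right", "VGG16", 0.75, 0.84),
    ("MICCAI", "right", "ResNet34", 0.75, 0.86),
    ("MICCAI", "right", "InceptionV3", 0.78, 0.90),
    ("MICCAI", "right", "UNet", 0.77, 0.85),
    ("MICCAI", "right", "nnUNet", 0.81, 0.92),
    ("MICCAI", "right", "TransUNet", 0.82, 0.92),
]

# published round-half-up increase-rate cells, same row order.
# 23 of 24 reproduce from their before/after cells as
# round_half_up(100*(after-before)/before); the (AMOS, left, UNet) cell
# prints 19 where that formula gives 24 (19 corresponds to using the
# after-value as denominator: 0.17/0.89).  The printed value is kept
# as-is and the discrepancy flagged below.
PUBLISHED_INCREASE_RATES = [
    11, 17, 44, 19, 8, 5,
    20, 11, 16, 13, 11, 12,
    15, 47, 11, 12, 13, 15,
    12, 15, 15, 10, 14, 12,
]

# index into the row/ratio lists of the one inconsistent published cell
DISCREPANT_INCREASE_RATE_ROW = 3  # (AMOS, left, UNet): printed 19, formula 24

# published bilateral average Dice (percent over both glands and datasets)
PUBLISHED_BILATERAL_AVERAGES = {
    "VGG16": 89,
    "ResNet34": 85,
    "InceptionV3": 87,
    "UNet": 87,
    "nnUNet": 91,
    "TransUNet": 92,
}

# published paired t-statistics/p-values on d = before - after per (dataset, gland)
PUBLISHED_T_TESTS = {
    ("AMOS", "left"): (-3.89, 0.011),
    ("AMOS", "right"): (-11.45, 0.000089),
    ("MICCAI", "left"): (-4.96, 0.004),
    ("MICCAI", "right"): (-16.92, 0.000013),
}

# pooled voxel confusion counts, VGG16 on the AMOS test set
VGG16_AMOS_CONFUSION = {
    ("right", "before"): ConfusionCounts(tp=20400, fp=5681, fn=7819),
    ("right", "after"): ConfusionCounts(tp=24833, fp=2178, fn=3386),
    ("left", "before"): ConfusionCounts(tp=26293, fp=4640, fn=6989),
    ("left", "after"): ConfusionCounts(tp=29621, fp=2230, fn=3661),
}

# published voxel-level precision/recall/F1 for those counts (two decimals)
PUBLISHED_VGG16_AMOS_PRF = {
    ("left", "before"): (0.85, 0.79, 0.82),
    ("left", "after"): (0.93, 0.89, 0.91),
    ("right", "before"): (0.78, 0.72, 0.75),
    ("right", "after"): (0.92, 0.88, 0.90),
}

# published false-positive reduction percentages (right, left gland)
PUBLISHED_FP_REDUCTION = {"right": 62, "left": 52}


def dice_before_after() -> pd.DataFrame:
    """The benchmark Dice table as a comparison table with derived columns."""
    return comparison_table(_DICE_ROWS)


def table3_vgg16_amos() -> dict[tuple[str, str], tuple[float, float, float]]:
    """Published VGG16/AMOS precision, recall, F1 per (gland, stage)."""
    return dict(PUBLISHED_VGG16_AMOS_PRF)
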