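"""Evaluation metrics and before/after comparison statistics.

Per-scan Dice (one score per patient over the whole CT volume), pooled
voxel-level confusion counts with precision/recall/F1, and the statistics
used to compare a pipeline before and after post-processing: percentage
increase rate, bilateral average Dice, paired t-tests, and one-way ANOVA
on per-model improvements.

Percentages follow the round-half-up convention (12.5 -> 13), which is
what reproduces published before/after tables reported to two decimals.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_nifti import MaskVolume

__all__ = [
    "ConfusionCounts",
    "ScanScore",
    "PairedTestResult",
    "AnovaResult",
    "dice_per_scan",
    "confusion",
    "precision_recall_f1",
    "round_half_up",
    "increase_rate",
    "bilateral_average",
    "paired_ttest",
    "anova_oneway",
    "comparison_table",
]


@dataclasses.dataclass
class ConfusionCounts:
    """Voxel-level TP/FP/FN/TN pooled over a test set."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclasses.dataclass
class ScanScore:
    """Per-patient Dice score."""

    patient_id: str
    dice: float
    empty_pair: bool = False  # both masks empty; dice=1 by convention


@dataclasses.dataclass
class PairedTestResult:
    t_statistic: float
    p_value: float
    df: int
    zero_variance: bool = False


@dataclasses.dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    degenerate: bool = False


def dice_per_scan(pred: MaskVolume, truth: MaskVolume) -> ScanScore:
    """Dice similarity 2|P∩T| / (|P|+|T|) over one whole scan.

    When both masks are empty the score is 1.0 by convention (a scan with
    no gland that the model correctly leaves empty); such scans are
    flagged so pooled statistics can exclude them.
    """
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.voxels.astype(bool)
    t = truth.voxels.astype(bool)
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return ScanScore(pred.patient_id, 1.0, empty_pair=True)
    inter = int(np.logical_and(p, t).sum())
    return ScanScore(pred.patient_id, 2.0 * inter / denom)


def confusion(preds: Iterable[MaskVolume], truths: Iterable[MaskVolume]) -> ConfusionCounts:
    """Pool voxel-level confusion counts over matched scan sets."""
    total = ConfusionCounts()
    preds, truths = list(preds), list(truths)
    if len(preds) != len(truths):
        raise ValueError("prediction and truth sets differ in length")
    for pr, tr in zip(preds, truths):
        if pr.patient_id != tr.patient_id:
            raise ValueError(
                f"scan id mismatch: {pr.patient_id!r} vs {tr.patient_id!r}"
            )
        if pr.shape != tr.shape:
            raise ValueError(f"shape mismatch on {pr.patient_id!r}")
        p = pr.voxels.astype(bool)
        t = tr.voxels.astype(bool)
        total = total + ConfusionCounts(
            tp=int(np.logical_and(p, t).sum()),
            fp=int(np.logical_and(p, ~t).sum()),
            fn=int(np.logical_and(~p, t).sum()),
            tn=int(np.logical_and(~p, ~t).sum()),
        )
    return total


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean from pooled counts.

    Degenerate denominators yield NaN for the affected quantity rather
    than raising.
    """
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else math.nan
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    if math.isnan(precision) or math.isnan(recall) or (precision + recall) == 0:
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (12.5 -> 13).

    Applied after rounding to 9 decimals so that a value that is exactly
    a half in decimal arithmetic (e.g. 0.10/0.80 = 12.5%) is not pushed
    below the tie by binary floating-point representation error.
    """
    return int(math.floor(round(x, 9) + 0.5))


def increase_rate(before: float, after: float) -> int:
    """Relative improvement 100*(after-before)/before as a round-half-up percent."""
    if before <= 0:
        raise ValueError(f"before must be positive, got {before}")
    return round_half_up(100.0 * (after - before) / before)


def comparison_table(rows: Sequence[tuple[str, str, str, float, float]]) -> pd.DataFrame:
    """Build a before/after comparison table.

    Rows are (dataset, gland, model, before, after) with metric values in
    [0, 1]; the returned frame adds the actual difference and the
    percentage increase rate per row.
    """
    df = pd.DataFrame(rows, columns=["dataset", "gland", "model", "before", "after"])
    if ((df["before"] < 0) | (df["before"] > 1) | (df["after"] < 0) | (df["after"] > 1)).any():
        raise ValueError("before/after metric values must lie in [0, 1]")
    df["actual_diff"] = df["after"] - df["before"]
    df["increase_rate_pct"] = [
        increase_rate(b, a) for b, a in zip(df["before"], df["after"])
    ]
    return df


def bilateral_average(table: pd.DataFrame, model: str) -> int:
    """Mean post-processing metric over both glands and both datasets, in percent.

    Requires the model to have an ``after`` value for each (dataset,
    gland) cell present in the table — four cells in the two-dataset,
    two-gland design.
    """
    sub = table[table["model"] == model]
    n_expected = table["dataset"].nunique() * table["gland"].nunique()
    have = set(zip(sub["dataset"], sub["gland"]))
    if len(have) < n_expected:
        raise ValueError(f"model {model!r} is missing (dataset, gland) cells")
    return round_half_up(100.0 * float(sub["after"].mean()))


def paired_ttest(before: Sequence[float], after: Sequence[float]) -> PairedTestResult:
    """Two-sided paired t-test on d = before - after.

    The sign convention makes an improvement (after > before) produce a
    negative t statistic.  If all differences are identical the variance
    is zero and the result is flagged instead of raising.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before/after must be equal-length 1D sequences")
    n = len(before)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = before - after
    if np.allclose(d.std(ddof=1), 0.0):
        return PairedTestResult(0.0 if np.allclose(d, 0) else math.inf, math.nan,
                                n - 1, zero_variance=True)
    t, p = stats.ttest_rel(before, after)
    return PairedTestResult(float(t), float(p), n - 1)


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way ANOVA across >= 2 groups of >= 2 values each."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    n = sum(len(g) for g in arrays)
    df_between, df_within = k - 1, n - k
    within_ss = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    if np.allclose(within_ss, 0.0):
        grand = np.concatenate(arrays).mean()
        between_ss = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
        if np.allclose(between_ss, 0.0):
            return AnovaResult(0.0, 1.0, df_between, df_within)
        return AnovaResult(math.inf, 0.0, df_between, df_within, degenerate=True)
    f, p = stats.f_oneway(*arrays)
    return AnovaResult(float(f), float(p), df_between, df_within)
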