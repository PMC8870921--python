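"""Volumetry, segmentation performance measures, and volumetric agreement.

Lesion load is the count of segmented voxels times the voxel volume, in mm³.
Segmentation quality is summarised by the five overlap measures computed from
the voxel-wise confusion table (Dice, accuracy, precision, sensitivity,
specificity). Agreement between automatic and manual per-subject volumes is
assessed Bland–Altman style (bias and 1.96·SD limits of agreement) together
with the squared Pearson correlation.

Empty-vs-empty comparisons are legal (lesion-free subjects exist): the
vacuous ratios (Dice, precision, sensitivity on two empty masks) are defined
as 1 and flagged via ``ConfusionCounts.degenerate_metrics``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .volume import BinaryMask

__all__ = [
    "ConfusionCounts",
    "AgreementStats",
    "lesion_volume",
    "confusion",
    "dice",
    "accuracy",
    "precision",
    "sensitivity",
    "specificity",
    "all_metrics",
    "bland_altman",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """Voxel-wise 2x2 tabulation of a predicted vs a reference mask."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def degenerate_metrics(self) -> list[str]:
        """Names of metrics whose denominator is zero for these counts."""
        out = []
        if 2 * self.tp + self.fp + self.fn == 0:
            out.append("dice")
        if self.tp + self.fp == 0:
            out.append("precision")
        if self.tp + self.fn == 0:
            out.append("sensitivity")
        if self.tn + self.fp == 0:
            out.append("specificity")
        return out


@dataclasses.dataclass(frozen=True)
class AgreementStats:
    """Bland–Altman summary of automatic vs manual volumes (mm³)."""

    bias: float          # mean(auto - manual)
    loa_low: float       # bias - 1.96 * SD(differences)
    loa_high: float      # bias + 1.96 * SD(differences)
    r_squared: float     # squared Pearson correlation
    n: int
    means: np.ndarray = dataclasses.field(repr=False, default=None)
    differences: np.ndarray = dataclasses.field(repr=False, default=None)


def lesion_volume(mask: BinaryMask) -> float:
    """Total volume of a binary mask in mm³ (voxel count x voxel volume)."""
    return float(np.count_nonzero(mask.data)) * mask.voxel_volume_mm3


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Voxel-wise confusion counts between a prediction and its reference."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.data.astype(bool)
    t = truth.data.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: float, den: float) -> float:
    # zero denominator means the comparison is vacuous -> perfect by convention
    return 1.0 if den == 0 else num / den


def dice(c: ConfusionCounts) -> float:
    """Dice coefficient 2·TP / (2·TP + FP + FN); 1 for two empty masks."""
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total)


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp)


def sensitivity(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fp)


_METRIC_FUNCS = {
    "dice": dice,
    "accuracy": accuracy,
    "precision": precision,
    "sensitivity": sensitivity,
    "specificity": specificity,
}


def all_metrics(pred: BinaryMask, truth: BinaryMask) -> dict[str, float]:
    """The five performance measures of a prediction against its reference."""
    c = confusion(pred, truth)
    return {name: f(c) for name, f in _METRIC_FUNCS.items()}


def bland_altman(auto, manual) -> AgreementStats:
    """Agreement between automatic and manual per-case volumes.

    Differences are ``auto - manual``; limits of agreement are
    bias ± 1.96·SD of the differences (SD with ddof=1). ``r_squared`` is the
    squared Pearson correlation of the two series; if either series has zero
    variance but the series are affinely identical (e.g. auto = manual + c),
    agreement is perfect and r² is 1.
    """
    auto = np.asarray(auto, dtype=np.float64)
    manual = np.asarray(manual, dtype=np.float64)
    if auto.shape != manual.shape or auto.ndim != 1:
        raise ValueError("auto and manual must be 1D series of equal length")
    n = auto.size
    if n < 2:
        raise ValueError("need at least two paired volumes")
    diffs = auto - manual
    means = (auto + manual) / 2.0
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if auto.std() == 0 or manual.std() == 0:
        # degenerate series: perfectly correlated iff the differences are constant
        r2 = 1.0 if sd == 0 else math.nan
    else:
        r = float(np.corrcoef(auto, manual)[0, 1])
        r2 = r * r
    return AgreementStats(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        r_squared=r2,
        n=n,
        means=means,
        differences=diffs,
    )
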