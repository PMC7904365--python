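"""Image-quality and segmentation-quality metrics.

Image quality follows the speckle-imaging conventions: the contrast-to-noise
ratio (CNR) of homogeneous regions of interest against a background region,

    CNR = (1/R) sum_r (mu_r - mu_b) / sqrt(sigma_r^2 + sigma_b^2),

and the equivalent number of looks (ENL) of homogeneous regions,

    ENL = (1/R) sum_r mu_r^2 / sigma_r^2,

both averaged over the supplied ROIs.  CNR is returned raw; a decibel view
(10 log10) is available separately.  Larger ENL means smoother speckle.

Segmentation quality is the standard pixelwise confusion suite: accuracy,
precision, sensitivity, specificity, Dice, IoU and Cohen's kappa.  A Dice
above 0.70 is conventionally labelled excellent agreement.  Undefined
ratios (zero denominators) are reported as NaN, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateROIError",
    "ROISet",
    "ConfusionCounts",
    "SegmentationScores",
    "MetricsReport",
    "cnr",
    "cnr_db",
    "enl",
    "confusion",
    "scores",
    "EXCELLENT_DICE",
]

EXCELLENT_DICE = 0.70


class DegenerateROIError(ValueError):
    """An ROI (or the background) has zero variance where variance is needed."""


@dataclass(frozen=True)
class ROISet:
    """Homogeneous regions of interest plus one background region."""

    rois: tuple[np.ndarray, ...]
    background: np.ndarray

    def __post_init__(self) -> None:
        if len(self.rois) == 0:
            raise ValueError("at least one ROI is required")
        bg = np.asarray(self.background, dtype=bool)
        for i, roi in enumerate(self.rois):
            r = np.asarray(roi, dtype=bool)
            if r.shape != bg.shape:
                raise ValueError(f"ROI #{i} shape {r.shape} != background {bg.shape}")
            if not r.any():
                raise ValueError(f"ROI #{i} is empty")
            if np.any(r & bg):
                raise ValueError(f"ROI #{i} overlaps the background region")
        if not bg.any():
            raise ValueError("background region is empty")


def _mean_var(image: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    vals = np.asarray(image, dtype=float)[np.asarray(mask, dtype=bool)]
    return float(vals.mean()), float(vals.var())


def cnr(image: np.ndarray, rois: ROISet) -> float:
    """Mean over ROIs of (mu_r - mu_b) / sqrt(sigma_r^2 + sigma_b^2), raw."""
    mu_b, var_b = _mean_var(image, rois.background)
    vals = []
    for i, roi in enumerate(rois.rois):
        mu_r, var_r = _mean_var(image, roi)
        joint = var_r + var_b
        if joint <= 0:
            raise DegenerateROIError(f"ROI #{i}: joint variance is zero, CNR undefined")
        vals.append((mu_r - mu_b) / math.sqrt(joint))
    return float(np.mean(vals))


def cnr_db(raw_cnr: float) -> float:
    """Decibel view 10*log10 of a positive raw CNR."""
    if raw_cnr <= 0:
        raise ValueError("dB view requires a positive raw CNR")
    return 10.0 * math.log10(raw_cnr)


def enl(image: np.ndarray, rois: ROISet) -> float:
    """Mean over ROIs of mu^2 / sigma^2 (scale-invariant smoothness index)."""
    vals = []
    for i, roi in enumerate(rois.rois):
        mu, var = _mean_var(image, roi)
        if var <= 0:
            raise DegenerateROIError(f"ROI #{i}: zero variance, ENL undefined")
        vals.append(mu * mu / var)
    return float(np.mean(vals))


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixelwise confusion counts (positive = structure present)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Count pixelwise agreement between a predicted and a reference mask."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


@dataclass(frozen=True)
class SegmentationScores:
    """The seven confusion-based scores; NaN marks an undefined ratio."""

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    dice: float
    iou: float
    kappa: float

    @property
    def excellent_agreement(self) -> bool:
        """Dice above 0.70, the conventional excellent-agreement badge."""
        return self.dice > EXCELLENT_DICE

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "dice": self.dice,
            "iou": self.iou,
            "kappa": self.kappa,
        }


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def scores(counts: ConfusionCounts) -> SegmentationScores:
    """Derive the seven scores from confusion counts.

    Kappa uses chance agreement from the product of the marginals (standard
    two-class Cohen's kappa on the pixel labelling).
    """
    t = counts.total
    if t == 0:
        raise ValueError("empty confusion table")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    po = (tp + tn) / t
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (t * t)
    return SegmentationScores(
        accuracy=po,
        precision=_ratio(tp, tp + fp),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        dice=_ratio(2 * tp, 2 * tp + fp + fn),
        iou=_ratio(tp, tp + fp + fn),
        kappa=(po - pe) / (1.0 - pe) if pe < 1.0 else math.nan,
    )


@dataclass
class MetricsReport:
    """Bundle of image-quality and per-structure segmentation metrics."""

    cnr: float | None = None
    enl: float | None = None
    per_structure: dict[str, SegmentationScores] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out: dict = {"cnr": self.cnr, "enl": self.enl}
        for name, sc in self.per_structure.items():
            out[name] = sc.as_dict()
        return out
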