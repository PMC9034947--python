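"""Evaluation metrics: pixel accuracy, average voxel error, diagnostic metrics.

Three layers match the three levels at which a segmentation pipeline is
judged: per-slice pixel accuracy of the aorta segmenter, per-volume average
voxel error of the grown coronary mask, and patient-level diagnostic metrics
of the resulting reads against an invasive reference standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import EvaluationError, InputError


@dataclass
class PixelAccuracyReport:
    acc: float
    n_samples: int
    per_sample: list[float]
    n_excluded: int  # samples with no positive label pixels


@dataclass
class VoxelErrorReport:
    error: float  # mean absolute intensity difference, HU per compared voxel
    n_voxels: int


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def validate(self) -> None:
        if any(v < 0 for v in (self.tp, self.fp, self.fn, self.tn)):
            raise InputError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Percentages, rounded half-up to 2 decimals; None when undefined (0/0)."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }


#: image-quality rubric levels (3 best): structure visibility, anatomical
#: variant clarity, artifact burden.  Representation only — scoring is a
#: human read, not a computation.
QUALITY_SCORE_LABELS = {
    0: "non-diagnostic",
    1: "poor",
    2: "adequate",
    3: "excellent",
}


def pixel_accuracy(
    predicted_masks: list[np.ndarray], label_masks: list[np.ndarray]
) -> PixelAccuracyReport:
    """Mean, over samples, of (correctly predicted positive pixels / positive label pixels).

    Samples whose label has no positive pixel are excluded from the mean and
    counted in the report.
    """
    if len(predicted_masks) != len(label_masks):
        raise InputError("predicted and label lists differ in length")
    fracs: list[float] = []
    n_excluded = 0
    for pred, lab in zip(predicted_masks, label_masks):
        pred = np.asarray(pred)
        lab = np.asarray(lab)
        if pred.shape != lab.shape:
            raise InputError(f"shape mismatch {pred.shape} vs {lab.shape}")
        if not np.isin(lab, (0, 1)).all():
            raise InputError("labels must be binary")
        g = int(np.count_nonzero(lab))
        if g == 0:
            n_excluded += 1
            continue
        v = int(np.count_nonzero((pred != 0) & (lab != 0)))
        fracs.append(v / g)
    if not fracs:
        raise EvaluationError("every sample has an empty label; accuracy undefined")
    return PixelAccuracyReport(
        acc=float(np.mean(fracs)),
        n_samples=len(fracs),
        per_sample=fracs,
        n_excluded=n_excluded,
    )


def average_voxel_error(
    volume: np.ndarray, predicted_mask: np.ndarray, reference_mask: np.ndarray
) -> VoxelErrorReport:
    """Mean absolute HU difference between masked volumes over their union.

    Over the compared set C = predicted ∪ reference, each voxel contributes
    |o_i - O_i| where o_i is the volume HU under the predicted mask (else 0)
    and O_i the volume HU under the reference mask (else 0); disagreements
    therefore cost the full local HU magnitude.
    """
    volume = np.asarray(volume, dtype=np.float64)
    predicted = np.asarray(predicted_mask).astype(bool)
    reference = np.asarray(reference_mask).astype(bool)
    if not (volume.shape == predicted.shape == reference.shape):
        raise InputError("volume and masks are misaligned")
    union = predicted | reference
    n = int(np.count_nonzero(union))
    if n == 0:
        raise EvaluationError("empty mask union; voxel error undefined")
    o = np.where(predicted, volume, 0.0)
    ref = np.where(reference, volume, 0.0)
    err = float(np.abs(o - ref)[union].sum() / n)
    return VoxelErrorReport(error=err, n_voxels=n)


def confusion_from_labels(
    predicted: list[int] | np.ndarray, reference: list[int] | np.ndarray
) -> ConfusionCounts:
    """2x2 tabulation of per-patient binary calls, reference as truth."""
    pred = np.asarray(predicted).astype(bool)
    ref = np.asarray(reference).astype(bool)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise InputError("predicted and reference must be equal-length 1D lists")
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & ref)),
        fp=int(np.count_nonzero(pred & ~ref)),
        fn=int(np.count_nonzero(~pred & ref)),
        tn=int(np.count_nonzero(~pred & ~ref)),
    )


def _pct(num: int, den: int) -> float | None:
    """100*num/den rounded half-up to 2 decimals; None for a 0 denominator."""
    if den == 0:
        return None
    ratio = Decimal(100 * num) / Decimal(den)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def diagnostic_metrics(c: ConfusionCounts) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy as percentages.

    Each metric with a zero denominator is returned as None (undefined) rather
    than raising.
    """
    c.validate()
    return DiagnosticMetrics(
        sensitivity=_pct(c.tp, c.tp + c.fn),
        specificity=_pct(c.tn, c.tn + c.fp),
        ppv=_pct(c.tp, c.tp + c.fp),
        npv=_pct(c.tn, c.tn + c.fn),
        accuracy=_pct(c.tp + c.tn, c.n) if c.n else None,
    )
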