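"""Region-composite segmentation evaluation.

Three composite regions are scored from the 5-class labels: complete tumor
(classes 1-4), tumor core (1, 3, 4) and enhancing tumor (4).  Each region
is a binary overlap problem measured by Dice, PPV, sensitivity and
specificity; a metric whose denominator is zero is reported as undefined
(None), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

#: Composite region -> member tissue classes.
REGIONS: dict[str, frozenset[int]] = {
    "complete": frozenset({1, 2, 3, 4}),
    "core": frozenset({1, 3, 4}),
    "enhancing": frozenset({4}),
}

COHORTS = ("HGG&LGG", "HGG", "LGG")
METRIC_NAMES = ("dice", "ppv", "sensitivity", "specificity")


def region_masks(labels: np.ndarray) -> dict[str, np.ndarray]:
    """Binary masks for the three composite regions."""
    labels = np.asarray(labels)
    return {name: np.isin(labels, list(classes)) for name, classes in REGIONS.items()}


def confusion_counts(
    pred_mask: np.ndarray, truth_mask: np.ndarray
) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) voxel counts of two binary masks."""
    pred_mask = np.asarray(pred_mask, dtype=bool)
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if pred_mask.shape != truth_mask.shape:
        raise ValueError(f"shape mismatch: {pred_mask.shape} vs {truth_mask.shape}")
    tp = int(np.count_nonzero(pred_mask & truth_mask))
    fp = int(np.count_nonzero(pred_mask & ~truth_mask))
    fn = int(np.count_nonzero(~pred_mask & truth_mask))
    tn = int(np.count_nonzero(~pred_mask & ~truth_mask))
    return tp, fp, fn, tn


def metrics(
    tp: int, fp: int, fn: int, tn: int
) -> tuple[float | None, float | None, float | None, float | None]:
    """(Dice, PPV, sensitivity, specificity); None where the denominator is 0.

    Dice = TP / [((TP+FP) + (TP+FN)) / 2].
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    dice_den = ((tp + fp) + (tp + fn)) / 2.0
    dice = tp / dice_den if dice_den > 0 else None
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (fp + tn) if (fp + tn) > 0 else None
    return dice, ppv, sens, spec


@dataclass(frozen=True)
class RegionScores:
    """Confusion counts and derived metrics for one composite region."""

    tp: int
    fp: int
    fn: int
    tn: int
    dice: float | None
    ppv: float | None
    sensitivity: float | None
    specificity: float | None
    undefined: bool = False  # truth region empty: the "-" convention

    @classmethod
    def from_counts(
        cls, tp: int, fp: int, fn: int, tn: int, undefined: bool = False
    ) -> "RegionScores":
        if undefined:
            return cls(tp, fp, fn, tn, None, None, None, None, undefined=True)
        dice, ppv, sens, spec = metrics(tp, fp, fn, tn)
        return cls(tp, fp, fn, tn, dice, ppv, sens, spec)

    def metric(self, name: str) -> float | None:
        return getattr(self, name)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "dice": self.dice,
            "ppv": self.ppv,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "undefined": self.undefined,
        }


def evaluate_segmentation(
    pred_labels: np.ndarray,
    truth_labels: np.ndarray,
    domain: np.ndarray | None = None,
) -> dict[str, RegionScores]:
    """Score predicted vs true labels over the three composite regions.

    ``domain`` restricts evaluation to a voxel subset (e.g. the detected
    ROI); by default every voxel counts.  A region absent from the truth is
    flagged undefined, reproducing the "-" convention for e.g. LGG
    enhancing tumor.
    """
    pred_labels = np.asarray(pred_labels)
    truth_labels = np.asarray(truth_labels)
    if pred_labels.shape != truth_labels.shape:
        raise ValueError(f"shape mismatch: {pred_labels.shape} vs {truth_labels.shape}")
    if domain is not None:
        pred_labels = pred_labels[domain]
        truth_labels = truth_labels[domain]
    pred_masks = region_masks(pred_labels)
    truth_masks = region_masks(truth_labels)
    scores: dict[str, RegionScores] = {}
    for region in REGIONS:
        truth_mask = truth_masks[region]
        tp, fp, fn, tn = confusion_counts(pred_masks[region], truth_mask)
        scores[region] = RegionScores.from_counts(
            tp, fp, fn, tn, undefined=not bool(truth_mask.any())
        )
    return scores


def mean_metric(
    score_maps: list[Mapping[str, RegionScores]], region: str, metric_name: str
) -> float | None:
    """Mean of a metric over reports where it is defined; None if nowhere."""
    values = [
        scores[region].metric(metric_name)
        for scores in score_maps
        if region in scores and scores[region].metric(metric_name) is not None
    ]
    return float(np.mean(values)) if values else None
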