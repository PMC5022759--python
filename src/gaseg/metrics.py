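"""Segmentation evaluation: RMS error and Dice overlap.

The headline score is the root-mean-square error between predicted and
reference maps,

    RMS = sqrt( sum_i (P_i - G_i)^2 / N )

over all N pixels.  Computed on per-class 0/1 maps, RMS^2 * N is the
Hamming distance between the maps, so the score is a dimensionless
mismatch fraction's square root, 0 iff the maps are identical and at
most 1.  The per-class binary RMS values are averaged into the headline
score; the RMS over the raw integer label map is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .errors import DataError
from .phantom import ReferenceSegmentation


def rms_error(pred: np.ndarray, ref: np.ndarray) -> float:
    """Root-mean-square pixelwise difference between two maps."""
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(ref, dtype=np.float64)
    if p.shape != g.shape:
        raise DataError(f"shape mismatch: {p.shape} vs {g.shape}")
    return float(np.sqrt(np.mean((p - g) ** 2)))


def dice(pred_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(ref_mask, dtype=bool)
    if a.shape != b.shape:
        raise DataError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


@dataclass
class EvalReport:
    """Summary of one segmentation against a reference.

    ``rms`` is the mean of the per-class binary RMS errors (0 iff the
    compared maps agree on every class); ``label_rms`` is the RMS over
    the integer label maps themselves.
    """

    rms: float
    per_class_rms: Dict[int, float]
    label_rms: float
    dice_per_class: Dict[int, float]
    pixel_counts: Dict[int, Dict[str, int]]

    def to_dict(self) -> dict:
        return {
            "rms": self.rms,
            "per_class_rms": {str(k): v for k, v in self.per_class_rms.items()},
            "label_rms": self.label_rms,
            "dice_per_class": {str(k): v for k, v in self.dice_per_class.items()},
            "pixel_counts": {str(k): v for k, v in self.pixel_counts.items()},
        }


def evaluate(pred: np.ndarray, ref: ReferenceSegmentation) -> EvalReport:
    """Score a predicted label map against reference class masks."""
    labels = np.asarray(pred)
    if labels.shape != ref.shape:
        raise DataError(
            f"prediction shape {labels.shape} != reference shape {ref.shape}"
        )
    per_class_rms = {}
    dice_per_class = {}
    pixel_counts = {}
    for c, mask in ref.masks.items():
        pred_mask = labels == c
        per_class_rms[c] = rms_error(pred_mask, mask)
        dice_per_class[c] = dice(pred_mask, mask)
        pixel_counts[c] = {
            "predicted": int(pred_mask.sum()),
            "reference": int(mask.sum()),
            "intersection": int((pred_mask & mask).sum()),
        }
    return EvalReport(
        rms=float(np.mean(list(per_class_rms.values()))),
        per_class_rms=per_class_rms,
        label_rms=rms_error(labels, ref.label_map()),
        dice_per_class=dice_per_class,
        pixel_counts=pixel_counts,
    )
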