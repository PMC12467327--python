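"""Overlap metrics, confusion accounting and difference maps.

Given a binary prediction P and ground truth G over N pixels,

    DSC = 2 TP / (2 TP + FP + FN),    IoU = TP / (TP + FP + FN),

with DSC = 2 IoU / (1 + IoU) whenever IoU is defined, hence DSC >= IoU
always.  Both metrics are taken as 1.0 when prediction and truth are both
empty (perfect agreement on absence) and 0.0 when exactly one is empty.
Counts are exact integers; metrics are computed in double precision.

The sensitivity of DSC to one additional false-positive pixel,

    dDSC/dFP = -2 TP / (2 TP + FP + FN)^2,

is always <= 0 and shows why IoU penalizes false positives more harshly
than DSC when comparing kernel-size settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricsResult",
    "confusion_counts",
    "dsc",
    "iou",
    "dsc_from_counts",
    "iou_from_counts",
    "difference_map",
    "render_difference_map",
    "save_difference_map",
    "dsc_fp_sensitivity",
    "DIFFERENCE_CATEGORIES",
    "DIFFERENCE_COLORS",
]

# category codes of the difference map
DIFFERENCE_CATEGORIES = {"TN": 0, "TP": 1, "FN": 2, "FP": 3}
# fixed legend: black TN, white TP, blue FN, red FP
DIFFERENCE_COLORS = np.array(
    [[0, 0, 0], [255, 255, 255], [0, 0, 255], [255, 0, 0]], dtype=np.uint8
)


def _as_binary(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return a.astype(bool)


def confusion_counts(P: np.ndarray, G: np.ndarray) -> tuple[int, int, int, int]:
    """Exact (TP, FP, FN, TN) pixel counts for binary masks of equal shape."""
    p = _as_binary(P, "prediction")
    g = _as_binary(G, "ground truth")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return tp, fp, fn, tn


def dsc_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def iou_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = tp + fp + fn
    return 1.0 if denom == 0 else tp / denom


def dsc(P: np.ndarray, G: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks."""
    tp, fp, fn, _ = confusion_counts(P, G)
    return dsc_from_counts(tp, fp, fn)


def iou(P: np.ndarray, G: np.ndarray) -> float:
    """Intersection-over-union of two binary masks."""
    tp, fp, fn, _ = confusion_counts(P, G)
    return iou_from_counts(tp, fp, fn)


@dataclass(frozen=True)
class MetricsResult:
    """Pixel confusion counts with the derived overlap metrics."""

    TP: int
    FP: int
    FN: int
    TN: int

    @classmethod
    def from_masks(cls, P: np.ndarray, G: np.ndarray) -> "MetricsResult":
        return cls(*confusion_counts(P, G))

    @property
    def N(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @property
    def dsc(self) -> float:
        return dsc_from_counts(self.TP, self.FP, self.FN)

    @property
    def iou(self) -> float:
        return iou_from_counts(self.TP, self.FP, self.FN)

    def as_dict(self) -> dict:
        return {"TP": self.TP, "FP": self.FP, "FN": self.FN, "TN": self.TN,
                "N": self.N, "DSC": self.dsc, "IoU": self.iou}


def difference_map(P: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Per-pixel error categorization: 0=TN, 1=TP, 2=FN, 3=FP."""
    p = _as_binary(P, "prediction")
    g = _as_binary(G, "ground truth")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    out = np.zeros(p.shape, dtype=np.uint8)
    out[p & g] = DIFFERENCE_CATEGORIES["TP"]
    out[~p & g] = DIFFERENCE_CATEGORIES["FN"]
    out[p & ~g] = DIFFERENCE_CATEGORIES["FP"]
    return out


def render_difference_map(categories: np.ndarray) -> np.ndarray:
    """RGB render with the fixed legend (black/white/blue/red)."""
    return DIFFERENCE_COLORS[np.asarray(categories, dtype=np.uint8)]


def save_difference_map(categories: np.ndarray, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, render_difference_map(categories))


def dsc_fp_sensitivity(TP: int, FP: int, FN: int) -> float:
    """Marginal change of DSC per additional false-positive pixel.

    Equals -2*TP / (2*TP + FP + FN)**2; non-positive for all valid counts.
    """
    if TP < 0 or FP < 0 or FN < 0:
        raise ValueError("counts must be non-negative")
    denom = 2 * TP + FP + FN
    if denom == 0:
        raise ValueError("sensitivity undefined for all-zero counts")
    return -2.0 * TP / denom**2
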