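"""Segmentation performance measures for 3D mask pairs.

Voxelwise confusion counts and the derived rates (sensitivity, specificity,
positive predictive value, accuracy, Dice similarity coefficient), the
symmetric Hausdorff distance between mask boundaries (voxel or mm units),
and the Pearson correlation coefficient for paired per-case score lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from petas3d.volume_io import BinaryMask

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "rates",
    "hausdorff",
    "pearson",
    "evaluate_masks",
]

_FACE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity cross


@dataclass(frozen=True)
class ConfusionCounts:
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


@dataclass
class MetricsReport:
    """The seven-measure report; hd is attached separately when surfaces exist."""

    sensitivity: float
    specificity: float
    ppv: float
    accuracy: float
    dsc: float
    counts: ConfusionCounts
    hd: float | None = None
    hd_units: str | None = None
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "accuracy": self.accuracy,
            "dsc": self.dsc,
            "hd": self.hd,
            "hd_units": self.hd_units,
            "counts": {"tp": self.counts.tp, "fp": self.counts.fp, "fn": self.counts.fn, "tn": self.counts.tn},
            "flags": list(self.flags),
        }


def confusion(pred: BinaryMask, gold: BinaryMask) -> ConfusionCounts:
    """Voxelwise TP/FP/FN/TN of a predicted mask against the gold standard."""
    if pred.grid != gold.grid:
        raise ValueError("prediction and gold standard must share a grid")
    p, g = pred.bool, gold.bool
    return ConfusionCounts(
        tp=int(np.sum(p & g)),
        fp=int(np.sum(p & ~g)),
        fn=int(np.sum(~p & g)),
        tn=int(np.sum(~p & ~g)),
    )


def _rate(num: int, den: int, name: str, flags: list) -> float:
    if den == 0:
        flags.append(f"{name}: empty denominator, defined as 1.0")
        return 1.0
    return num / den


def rates(c: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, PPV, accuracy and DSC from confusion counts.

    An empty condition set (0/0) is defined as 1.0 and flagged, so
    degenerate phantoms do not crash parameter sweeps.
    """
    flags: list = []
    return MetricsReport(
        sensitivity=_rate(c.tp, c.tp + c.fn, "sensitivity", flags),
        specificity=_rate(c.tn, c.tn + c.fp, "specificity", flags),
        ppv=_rate(c.tp, c.tp + c.fp, "ppv", flags),
        accuracy=_rate(c.tp + c.tn, c.total, "accuracy", flags),
        dsc=_rate(2 * c.tp, 2 * c.tp + c.fp + c.fn, "dsc", flags),
        counts=c,
        flags=flags,
    )


def _surface_points(mask: BinaryMask) -> np.ndarray:
    """Mask voxels with at least one face-adjacent background voxel (grid edge counts)."""
    m = mask.bool
    interior = ndimage.binary_erosion(m, structure=_FACE, border_value=0)
    return np.argwhere(m & ~interior).astype(np.float64)


def hausdorff(a: BinaryMask, b: BinaryMask, units: str = "voxel") -> float:
    """Symmetric Hausdorff distance between the surfaces of two masks.

    HD = max{d(A,B), d(B,A)} with d the directed farthest-nearest-point
    distance between surface voxel sets, Euclidean in voxel units or scaled
    per-axis by the grid spacing in mm mode.
    """
    if units not in ("voxel", "mm"):
        raise ValueError("units must be 'voxel' or 'mm'")
    if a.grid != b.grid:
        raise ValueError("masks must share a grid")
    if a.count() == 0 or b.count() == 0:
        raise ValueError("Hausdorff distance requires two non-empty masks")
    pa, pb = _surface_points(a), _surface_points(b)
    if units == "mm":
        s = np.asarray(a.grid.spacing)
        pa, pb = pa * s, pb * s
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


def pearson(x, y) -> float:
    """Pearson correlation coefficient of two equal-length score lists."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D sequences")
    if len(x) < 2:
        raise ValueError("Pearson correlation requires at least 2 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(pearsonr(x, y)[0])


def evaluate_masks(pred: BinaryMask, gold: BinaryMask, units: str = "voxel") -> MetricsReport:
    """Full report: rates plus the Hausdorff distance (when both masks are non-empty)."""
    report = rates(confusion(pred, gold))
    if pred.count() > 0 and gold.count() > 0:
        report.hd = hausdorff(pred, gold, units=units)
        report.hd_units = units
    else:
        report.flags.append("hd: undefined for an empty mask")
    return report
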