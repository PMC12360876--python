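"""Segmentation evaluation: Jaccard index, Dice coefficient and HD95.

Overlap metrics are computed from pixelwise confusion counts::

    JI   = TP / (TP + FP + FN)
    Dice = 2*TP / (2*TP + FP + FN)      (equivalently 2*JI / (1 + JI))

The boundary metric is the 95th-percentile Hausdorff distance between the
boundary point sets of the two masks: for each direction the 95th percentile
of the minimum Euclidean point-to-set distances is taken, and the two
directed values are combined by max. ``percentile=100`` recovers the
classical (maximum) Hausdorff distance. Distances are in pixel units
between boundary-pixel centers; no physical spacing is applied.

Degenerate masks are handled with explicit conventions so that batch
evaluation never aborts: two empty masks score JI = Dice = 1 (with a
warning) and HD95 = 0; one empty mask scores JI = Dice = 0 and HD95 equal
to the image diagonal, flagged in the report.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial import cKDTree

from .types import BinaryMask

_FOUR_CONN = generate_binary_structure(2, 1)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixelwise true/false positive/negative counts for a mask pair."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Per-pair evaluation result.

    ``empty_flag`` is set when either mask was empty and a degenerate-case
    convention (rather than the formulas) produced the values.
    """

    jaccard: float
    dice: float
    hd95: float
    empty_flag: bool = False


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Count TP/FP/FN/TN pixels between a predicted and a reference mask."""
    if pred.shape != truth.shape:
        raise ValueError(f"mask dimensions differ: {pred.shape} vs {truth.shape}")
    p = pred.pixels.astype(bool)
    t = truth.pixels.astype(bool)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def jaccard(counts: ConfusionCounts) -> float:
    """Jaccard index TP/(TP+FP+FN); 1.0 (with a warning) if both masks empty."""
    denom = counts.tp + counts.fp + counts.fn
    if denom == 0:
        warnings.warn(
            "both masks empty: Jaccard defined as 1.0 by convention", stacklevel=2
        )
        return 1.0
    return counts.tp / denom


def dice(counts: ConfusionCounts) -> float:
    """Dice coefficient 2TP/(2TP+FP+FN); 1.0 (with a warning) if both empty."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        warnings.warn(
            "both masks empty: Dice defined as 1.0 by convention", stacklevel=2
        )
        return 1.0
    return 2 * counts.tp / denom


def extract_boundary(mask: BinaryMask) -> np.ndarray:
    """Boundary pixels of a mask: mask minus its 4-connected erosion.

    Out-of-frame pixels count as background, so a full-frame mask has its
    frame border as boundary. Returns an (N, 2) array of (row, col)
    coordinates. Raises on an empty mask.
    """
    m = mask.pixels.astype(bool)
    if not m.any():
        raise ValueError("cannot extract the boundary of an empty mask")
    eroded = binary_erosion(m, structure=_FOUR_CONN, border_value=0)
    return np.argwhere(m & ~eroded)


def _directed_percentile(a: np.ndarray, b: np.ndarray, percentile: float) -> float:
    dists, _ = cKDTree(b).query(a, k=1)
    return float(np.percentile(dists, percentile))


def hd95(pred: BinaryMask, truth: BinaryMask, percentile: float = 95.0) -> float:
    """Percentile Hausdorff distance between two mask boundaries (pixels).

    Symmetric in its arguments; 0 for identical masks. If exactly one mask
    is empty the image diagonal is returned as a defined penalty; two empty
    masks score 0.
    """
    if pred.shape != truth.shape:
        raise ValueError(f"mask dimensions differ: {pred.shape} vs {truth.shape}")
    if not 0.0 < percentile <= 100.0:
        raise ValueError(f"percentile must lie in (0, 100], got {percentile}")
    p_empty = not pred.pixels.any()
    t_empty = not truth.pixels.any()
    if p_empty and t_empty:
        return 0.0
    if p_empty or t_empty:
        h, w = pred.shape
        return math.hypot(h, w)
    a = extract_boundary(pred).astype(np.float64)
    b = extract_boundary(truth).astype(np.float64)
    return max(
        _directed_percentile(a, b, percentile),
        _directed_percentile(b, a, percentile),
    )


def evaluate_pair(
    pred: BinaryMask, truth: BinaryMask, hd_percentile: float = 95.0
) -> MetricsReport:
    """Compute Jaccard, Dice and HD95 for one prediction/reference pair."""
    p_empty = not pred.pixels.any()
    t_empty = not truth.pixels.any()
    counts = confusion(pred, truth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ji = jaccard(counts)
        dc = dice(counts)
    return MetricsReport(
        jaccard=ji,
        dice=dc,
        hd95=hd95(pred, truth, percentile=hd_percentile),
        empty_flag=p_empty or t_empty,
    )
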