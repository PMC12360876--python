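"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as plain per-pixel / per-point
Python so it shares no code path with the package under test.
"""

from __future__ import annotations

import math

import numpy as np


def _clip01(v: float) -> float:
    return min(1.0, max(0.0, v))


def pixmix_loop(il: np.ndarray, iu: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    out = np.empty_like(il)
    for i in range(il.shape[0]):
        for j in range(il.shape[1]):
            out[i, j] = _clip01(alpha * il[i, j] + beta * iu[i, j])
    return out


def segmix2_loop(
    il: np.ndarray, iu: np.ndarray, soft: np.ndarray, gamma: float
) -> np.ndarray:
    out = np.empty_like(il)
    for i in range(il.shape[0]):
        for j in range(il.shape[1]):
            inner = gamma * il[i, j] + (1.0 - gamma) * iu[i, j]
            out[i, j] = _clip01((1.0 - soft[i, j]) * iu[i, j] + soft[i, j] * inner)
    return out


def lesionblend_loop(il: np.ndarray, iu: np.ndarray, soft: np.ndarray) -> np.ndarray:
    out = np.empty_like(il)
    for i in range(il.shape[0]):
        for j in range(il.shape[1]):
            out[i, j] = _clip01(soft[i, j] * il[i, j] + (1.0 - soft[i, j]) * iu[i, j])
    return out


def lesionblend2_loop(il: np.ndarray, iu: np.ndarray, soft: np.ndarray) -> np.ndarray:
    out = np.empty_like(il)
    for i in range(il.shape[0]):
        for j in range(il.shape[1]):
            out[i, j] = _clip01((1.0 - soft[i, j]) * il[i, j] + soft[i, j] * iu[i, j])
    return out


def pixmix2_loop(il: np.ndarray, iu: np.ndarray) -> np.ndarray:
    total = np.empty_like(il)
    for i in range(il.shape[0]):
        for j in range(il.shape[1]):
            total[i, j] = il[i, j] + iu[i, j]
    lo = total.min()
    hi = total.max()
    out = np.empty_like(total)
    for i in range(total.shape[0]):
        for j in range(total.shape[1]):
            out[i, j] = 0.0 if hi <= lo else (total[i, j] - lo) / (hi - lo)
    return out


def gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Normalized discrete Gaussian as used by a truncated convolution."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def confusion_loop(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, t = pred[i, j], truth[i, j]
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def boundary_loop(mask: np.ndarray) -> list[tuple[int, int]]:
    """Mask pixels with at least one 4-neighbor background pixel
    (out-of-frame counts as background)."""
    h, w = mask.shape
    pts = []
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ni, nj = i + di, j + dj
                if ni < 0 or ni >= h or nj < 0 or nj >= w or not mask[ni, nj]:
                    pts.append((i, j))
                    break
    return pts


def _percentile_linear(values: list[float], percentile: float) -> float:
    """Linear-interpolation percentile on sorted data (numpy's default)."""
    vals = sorted(values)
    if len(vals) == 1:
        return vals[0]
    rank = (percentile / 100.0) * (len(vals) - 1)
    lo = math.floor(rank)
    hi = math.ceil(rank)
    frac = rank - lo
    return vals[lo] * (1.0 - frac) + vals[hi] * frac


def hausdorff_percentile_bruteforce(
    pred: np.ndarray, truth: np.ndarray, percentile: float = 95.0
) -> float:
    """All-pairs directed percentile Hausdorff distance on boundary points."""
    a = boundary_loop(pred)
    b = boundary_loop(truth)
    d_ab = [min(math.hypot(p[0] - q[0], p[1] - q[1]) for q in b) for p in a]
    d_ba = [min(math.hypot(p[0] - q[0], p[1] - q[1]) for q in a) for p in b]
    return max(
        _percentile_linear(d_ab, percentile), _percentile_linear(d_ba, percentile)
    )


def random_blob_mask(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Small random non-empty mask: a union of a few filled discs."""
    mask = np.zeros((h, w), dtype=np.uint8)
    for _ in range(int(rng.integers(1, 4))):
        cr = rng.uniform(0, h - 1)
        cc = rng.uniform(0, w - 1)
        rad = rng.uniform(1.0, max(h, w) / 3)
        rows = np.arange(h)[:, None]
        cols = np.arange(w)[None, :]
        mask |= ((rows - cr) ** 2 + (cols - cc) ** 2 <= rad**2).astype(np.uint8)
    if not mask.any():
        mask[int(rng.integers(0, h)), int(rng.integers(0, w))] = 1
    return mask
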