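"""Traditional single-image augmentation baselines.

These are the conventional operators the mixed-sample strategies are
compared against: random rotation, random translation and additive Gaussian
noise, plus random horizontal flipping used as training-time preprocessing.
Geometric operators transform image and mask jointly with the same drawn
parameters; the noise operator never touches the mask. Every draw is
reproducible from ``(rng_seed, params)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import AugmentedSample, BinaryMask, GrayImage, LabeledSample, Strategy


@dataclass(frozen=True)
class BaselineParams:
    """Parameter ranges for the traditional baselines.

    angle_range
        Rotation angles drawn uniformly from this interval (degrees); the
        default [15, 345] deliberately avoids near-identity rotations.
    shift_fraction
        Translation drawn per axis from +/- this fraction of the axis length.
    noise_var_range
        Gaussian noise variance drawn uniformly from this range on the
        8-bit (0-255) intensity scale, then converted to the [0, 1] domain.
    flip_prob
        Probability of a horizontal flip.
    """

    angle_range: tuple[float, float] = (15.0, 345.0)
    shift_fraction: float = 0.20
    noise_var_range: tuple[float, float] = (10.0, 50.0)
    flip_prob: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.angle_range
        if not (0.0 <= lo <= hi < 360.0):
            raise ValueError(f"angle_range must lie within [0, 360), got {self.angle_range}")
        if not 0.0 <= self.shift_fraction <= 0.5:
            raise ValueError(f"shift_fraction must lie in [0, 0.5], got {self.shift_fraction}")
        nlo, nhi = self.noise_var_range
        if nlo < 0 or nhi < nlo:
            raise ValueError(f"noise_var_range must be non-negative and ordered, got {self.noise_var_range}")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError(f"flip_prob must lie in [0, 1], got {self.flip_prob}")


def _wrap(
    image: np.ndarray,
    mask: np.ndarray,
    sample: LabeledSample,
    strategy: Strategy,
    params: dict,
    seed: int,
) -> AugmentedSample:
    return AugmentedSample(
        image=GrayImage(np.clip(image, 0.0, 1.0)),
        mask=BinaryMask(mask),
        strategy=strategy,
        labeled_source_id=sample.source_id,
        params=params,
        seed=seed,
    )


def rotate_pair(
    sample: LabeledSample, rng_seed: int, params: BaselineParams = BaselineParams()
) -> AugmentedSample:
    """Rotate image (bilinear) and mask (nearest-neighbor) by a random angle.

    Out-of-frame pixels are zero-filled and the mask is re-binarized.
    """
    rng = np.random.default_rng(rng_seed)
    angle = float(rng.uniform(*params.angle_range))
    image = ndimage.rotate(
        sample.image.pixels, angle, reshape=False, order=1, mode="constant", cval=0.0
    )
    mask = ndimage.rotate(
        sample.mask.pixels.astype(np.float64),
        angle,
        reshape=False,
        order=0,
        mode="constant",
        cval=0.0,
    )
    return _wrap(
        image,
        (mask > 0.5).astype(np.uint8),
        sample,
        Strategy.ROTATION,
        {"angle_range": list(params.angle_range), "angle": angle},
        rng_seed,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def _shift2d(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Integer-pixel shift with zero fill (positive = down/right)."""
    out = np.zeros_like(arr)
    h, w = arr.shape
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = arr[src_r, src_c]
    return out


def translate_pair(
    sample: LabeledSample, rng_seed: int, params: BaselineParams = BaselineParams()
) -> AugmentedSample:
    """Shift image and mask jointly by an integer-pixel random translation.

    Shifts are drawn independently per axis from +/- shift_fraction of the
    axis length, rounded half away from zero; vacated pixels are zero.
    """
    rng = np.random.default_rng(rng_seed)
    h, w = sample.image.shape
    f = params.shift_fraction
    dr = _round_half_away(float(rng.uniform(-f, f)) * h)
    dc = _round_half_away(float(rng.uniform(-f, f)) * w)
    return _wrap(
        _shift2d(sample.image.pixels, dr, dc),
        _shift2d(sample.mask.pixels, dr, dc),
        sample,
        Strategy.TRANSLATION,
        {"shift_fraction": f, "shift": [dr, dc]},
        rng_seed,
    )


def gaussian_noise_pair(
    sample: LabeledSample, rng_seed: int, params: BaselineParams = BaselineParams()
) -> AugmentedSample:
    """Add zero-mean Gaussian noise to the image only; the mask is untouched.

    The variance is drawn uniformly on the 8-bit scale (e.g. 10-50) and
    converted to the [0, 1] intensity domain as ``var / 255**2``; the noisy
    image is clipped back to [0, 1].
    """
    rng = np.random.default_rng(rng_seed)
    var_8bit = float(rng.uniform(*params.noise_var_range))
    sigma = math.sqrt(var_8bit) / 255.0
    noisy = sample.image.pixels + rng.normal(0.0, sigma, size=sample.image.shape)
    return _wrap(
        noisy,
        sample.mask.pixels.copy(),
        sample,
        Strategy.GAUSSIAN_NOISE,
        {"noise_var_range": list(params.noise_var_range), "variance": var_8bit},
        rng_seed,
    )


def hflip_pair(
    sample: LabeledSample, rng_seed: int, flip_prob: float = 0.5
) -> AugmentedSample:
    """Mirror image and mask left-right with probability ``flip_prob``."""
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError(f"flip_prob must lie in [0, 1], got {flip_prob}")
    rng = np.random.default_rng(rng_seed)
    flipped = bool(rng.uniform() < flip_prob)
    image = sample.image.pixels[:, ::-1] if flipped else sample.image.pixels
    mask = sample.mask.pixels[:, ::-1] if flipped else sample.mask.pixels
    return _wrap(
        image.copy(),
        mask.copy(),
        sample,
        Strategy.HFLIP,
        {"flip_prob": flip_prob, "flipped": flipped},
        rng_seed,
    )


#: Dispatch table used by dataset expansion and manifest replay.
BASELINE_OPS = {
    Strategy.ROTATION: rotate_pair,
    Strategy.TRANSLATION: translate_pair,
    Strategy.GAUSSIAN_NOISE: gaussian_noise_pair,
}
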