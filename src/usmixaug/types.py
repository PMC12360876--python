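"""Core in-memory containers for images, masks and augmented samples.

All image arithmetic in this package happens on normalized float fields in
[0, 1]; masks are strict {0, 1} integer fields aligned pixel-for-pixel with
their image. The containers below are thin validated wrappers around numpy
arrays so that every operator can assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Mapping, Optional

import numpy as np

#: Minimum side length for a grayscale ultrasound image.
MIN_IMAGE_DIM = 8


class Strategy(str, Enum):
    """Augmentation strategies that can label an :class:`AugmentedSample`."""

    PIXMIX = "pixmix"
    SEGMIX2 = "segmix2"
    LESIONBLEND = "lesionblend"
    LESIONBLEND2 = "lesionblend2"
    PIXMIX2 = "pixmix2"
    ROTATION = "rotation"
    TRANSLATION = "translation"
    GAUSSIAN_NOISE = "gaussian_noise"
    HFLIP = "hflip"
    ORIGINAL = "original"


#: The five mixed-sample (pseudolabel) strategies.
MIXED_STRATEGIES = (
    Strategy.PIXMIX,
    Strategy.SEGMIX2,
    Strategy.LESIONBLEND,
    Strategy.LESIONBLEND2,
    Strategy.PIXMIX2,
)

#: Traditional single-image baselines usable in dataset expansion.
BASELINE_STRATEGIES = (
    Strategy.ROTATION,
    Strategy.TRANSLATION,
    Strategy.GAUSSIAN_NOISE,
)


def _validate_image_array(pixels: np.ndarray) -> np.ndarray:
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < MIN_IMAGE_DIM or arr.shape[1] < MIN_IMAGE_DIM:
        raise ValueError(
            f"image must be at least {MIN_IMAGE_DIM}x{MIN_IMAGE_DIM}, got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    return np.ascontiguousarray(arr)


def _validate_mask_array(pixels: np.ndarray) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
    uniq = np.unique(arr)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError("mask values must be exactly 0 or 1")
    return np.ascontiguousarray(arr.astype(np.uint8))


@dataclass(eq=False)
class GrayImage:
    """A 2-D grayscale intensity field with values in [0, 1]."""

    pixels: np.ndarray
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = _validate_image_array(self.pixels)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(eq=False)
class BinaryMask:
    """A 2-D lesion indicator field over {0, 1}."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = _validate_mask_array(self.pixels)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.pixels.copy())


@dataclass(eq=False)
class SoftMask:
    """A Gaussian-smoothed mask used as continuous per-pixel blend weights.

    Values live in [0, 1]; ``sigma`` records the smoothing scale in pixels.
    As sigma approaches zero the soft mask reduces to the hard source mask.
    """

    pixels: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("soft mask must be 2-D")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("soft mask values must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        self.pixels = np.ascontiguousarray(arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(eq=False)
class LabeledSample:
    """An annotated (image, mask) pair with a stable identifier."""

    image: GrayImage
    mask: BinaryMask
    source_id: str

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} dimensions differ"
            )


@dataclass(eq=False)
class AugmentedSample:
    """A generated (image, mask) pair plus the provenance needed to replay it.

    For the five mixed strategies the mask is bit-identical to the labeled
    source mask (pseudolabel contract); geometric baselines transform the
    mask jointly with the image.
    """

    image: GrayImage
    mask: BinaryMask
    strategy: Strategy
    labeled_source_id: str
    unlabeled_source_id: Optional[str] = None
    params: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("augmented image and mask dimensions differ")
        self.strategy = Strategy(self.strategy)
        self.params = dict(self.params)


@dataclass(frozen=True)
class MixParams:
    """Weights for the mixed-sample operators.

    alpha
        Fraction of the labeled image kept in PixMix; ``alpha + beta = 1``.
    beta
        Fraction contributed by the unlabeled image in PixMix.
    gamma
        Inner blend weight for the lesion content in SegMix2.
    sigma
        Gaussian smoothing scale (pixels) for the soft lesion mask.
    pixmix2_overflow
        How PixMix2 maps the raw image sum back into [0, 1]:
        ``"rescale"`` (min-max) or ``"clip"``.
    """

    alpha: float = 0.8
    beta: float = 0.2
    gamma: float = 0.5
    sigma: float = 5.0
    pixmix2_overflow: str = "rescale"

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError(
                f"alpha + beta must equal 1, got {self.alpha} + {self.beta}"
            )
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.pixmix2_overflow not in ("rescale", "clip"):
            raise ValueError("pixmix2_overflow must be 'rescale' or 'clip'")
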