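"""Synthetic ultrasound-like phantoms for testing and demonstration.

Real breast/thyroid ultrasound frames are grayscale, low contrast, and
dominated by multiplicative speckle; lesions appear as roughly elliptical
hypo- or hyperechoic regions with blurred boundaries. The phantoms here
emulate exactly those features: a smoothed unit-mean gamma speckle field as
background, one elliptical lesion offset in intensity with a Gaussian-
feathered edge, and the exact hard ellipse indicator as ground-truth mask.
Lesion-free phantoms stand in for the unlabeled pool.

They are not beamformed simulations — no shadowing, reverberation or
depth-dependent attenuation — so they exercise the augmentation and metric
machinery, not clinical realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import BinaryMask, GrayImage, LabeledSample

#: Background tissue intensity before speckle modulation.
DEFAULT_BASE_INTENSITY = 0.35
#: Spatial correlation (pixels) of the smoothed speckle field.
SPECKLE_SMOOTH_SIGMA = 1.2
#: Lesion must sit this many pixels inside the frame.
FRAME_MARGIN = 2


@dataclass(frozen=True)
class PhantomSpec:
    """Full recipe for one phantom; two equal specs give bit-equal phantoms."""

    height: int = 224
    width: int = 224
    lesion_axes: tuple[float, float] = (20.0, 14.0)
    lesion_center: tuple[float, float] = (112.0, 112.0)
    lesion_contrast: float = -0.2
    edge_sigma: float = 2.0
    speckle_scale: float = 0.3
    base_intensity: float = DEFAULT_BASE_INTENSITY
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.lesion_axes
        if a < 3 or b < 3:
            raise ValueError(f"lesion axes must be >= 3 px, got {self.lesion_axes}")
        if not -0.5 <= self.lesion_contrast <= 0.5:
            raise ValueError("lesion_contrast must lie in [-0.5, 0.5]")
        cr, cc = self.lesion_center
        if (
            cr - a < FRAME_MARGIN
            or cr + a > self.height - 1 - FRAME_MARGIN
            or cc - b < FRAME_MARGIN
            or cc + b > self.width - 1 - FRAME_MARGIN
        ):
            raise ValueError(
                f"lesion (center {self.lesion_center}, axes {self.lesion_axes}) "
                f"leaves less than a {FRAME_MARGIN} px margin in a "
                f"{self.height}x{self.width} frame"
            )


@dataclass
class PhantomDataset:
    labeled: list[LabeledSample]
    unlabeled: list[GrayImage]
    spec_log: list[PhantomSpec] = field(default_factory=list)


def _speckle_background(
    height: int,
    width: int,
    rng: np.random.Generator,
    speckle_scale: float,
    base_intensity: float,
) -> np.ndarray:
    """Base intensity modulated by smoothed unit-mean gamma speckle."""
    if speckle_scale <= 0:
        return np.full((height, width), base_intensity)
    shape = 1.0 / speckle_scale**2  # unit mean, sd = speckle_scale
    noise = rng.gamma(shape=shape, scale=1.0 / shape, size=(height, width))
    return base_intensity * gaussian_filter(noise, sigma=SPECKLE_SMOOTH_SIGMA)


def ellipse_indicator(spec: PhantomSpec) -> np.ndarray:
    """Hard {0,1} rasterization of the lesion ellipse at pixel centers."""
    rows = np.arange(spec.height, dtype=np.float64)[:, None]
    cols = np.arange(spec.width, dtype=np.float64)[None, :]
    cr, cc = spec.lesion_center
    a, b = spec.lesion_axes
    return (((rows - cr) / a) ** 2 + ((cols - cc) / b) ** 2 <= 1.0).astype(np.uint8)


def make_phantom(spec: PhantomSpec, source_id: Optional[str] = None) -> LabeledSample:
    """Synthesize one speckled image with an elliptical lesion and its mask."""
    rng = np.random.default_rng(spec.seed)
    background = _speckle_background(
        spec.height, spec.width, rng, spec.speckle_scale, spec.base_intensity
    )
    indicator = ellipse_indicator(spec)
    feathered = gaussian_filter(indicator.astype(np.float64), sigma=spec.edge_sigma)
    image = np.clip(background + spec.lesion_contrast * feathered, 0.0, 1.0)
    sid = source_id or f"phantom_seed{spec.seed}"
    return LabeledSample(
        image=GrayImage(image, source_id=sid),
        mask=BinaryMask(indicator),
        source_id=sid,
    )


def make_unlabeled_phantom(
    height: int,
    width: int,
    seed: int,
    speckle_scale: float = 0.3,
    base_intensity: float = DEFAULT_BASE_INTENSITY,
    source_id: Optional[str] = None,
) -> GrayImage:
    """Lesion-free speckle phantom for the unlabeled pool."""
    rng = np.random.default_rng(seed)
    image = np.clip(
        _speckle_background(height, width, rng, speckle_scale, base_intensity),
        0.0,
        1.0,
    )
    return GrayImage(image, source_id=source_id or f"unlabeled_seed{seed}")


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def make_dataset(
    n_labeled: int,
    n_unlabeled: int,
    seed: int,
    height: int = 224,
    width: int = 224,
    axes_range: tuple[float, float] = (8.0, 40.0),
    contrast_magnitude_range: tuple[float, float] = (0.1, 0.3),
    edge_sigma: float = 2.0,
    speckle_scale: float = 0.3,
) -> PhantomDataset:
    """Generate a reproducible labeled + unlabeled phantom corpus.

    Lesion semi-axes are drawn uniformly from ``axes_range``, the contrast
    magnitude uniformly from ``contrast_magnitude_range`` with a random
    sign, and centers uniformly among positions keeping the lesion fully
    in frame. Fully determined by ``(n_labeled, n_unlabeled, seed)``.
    """
    if n_labeled < 1 or n_unlabeled < 0:
        raise ValueError("need at least one labeled phantom and n_unlabeled >= 0")
    a_hi = min(axes_range[1], (height - 1) / 2 - FRAME_MARGIN - 1)
    b_hi = min(axes_range[1], (width - 1) / 2 - FRAME_MARGIN - 1)
    if a_hi < axes_range[0] or b_hi < axes_range[0]:
        raise ValueError("frame too small for the requested lesion axes")

    rng = np.random.default_rng(seed)
    seeds = _child_seeds(seed, n_labeled + n_unlabeled)

    labeled: list[LabeledSample] = []
    spec_log: list[PhantomSpec] = []
    for i in range(n_labeled):
        a = float(rng.uniform(axes_range[0], a_hi))
        b = float(rng.uniform(axes_range[0], b_hi))
        cr = float(rng.uniform(a + FRAME_MARGIN, height - 1 - FRAME_MARGIN - a))
        cc = float(rng.uniform(b + FRAME_MARGIN, width - 1 - FRAME_MARGIN - b))
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        contrast = sign * float(rng.uniform(*contrast_magnitude_range))
        spec = PhantomSpec(
            height=height,
            width=width,
            lesion_axes=(a, b),
            lesion_center=(cr, cc),
            lesion_contrast=contrast,
            edge_sigma=edge_sigma,
            speckle_scale=speckle_scale,
            seed=seeds[i],
        )
        spec_log.append(spec)
        labeled.append(make_phantom(spec, source_id=f"phantom_{i:04d}"))

    unlabeled = [
        make_unlabeled_phantom(
            height,
            width,
            seeds[n_labeled + j],
            speckle_scale=speckle_scale,
            source_id=f"unlabeled_{j:04d}",
        )
        for j in range(n_unlabeled)
    ]
    return PhantomDataset(labeled=labeled, unlabeled=unlabeled, spec_log=spec_log)


def expected_mean_lesion_area(
    axes_range: tuple[float, float] = (8.0, 40.0),
) -> float:
    """Analytic mean of pi*a*b for independent uniform semi-axes."""
    mean_axis = 0.5 * (axes_range[0] + axes_range[1])
    return math.pi * mean_axis**2
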