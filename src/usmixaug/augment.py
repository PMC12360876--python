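"""The five mixed-sample augmentation operators.

Each operator fuses a labeled ultrasound image ``I_L`` (with lesion mask
``T_L``) and an unlabeled image ``I_U`` into a pseudolabeled sample whose
mask is the *unaltered* ``T_L`` — the central contract that lets unlabeled
data enter supervised training without corrupting the segmentation target.

Writing ``T'_L`` for the Gaussian-smoothed soft mask, the operators are

* ``pixmix``:        I = alpha*I_L + beta*I_U                (alpha+beta=1)
* ``segmix2``:       I = (1-T'_L)*I_U + T'_L*(gamma*I_L + (1-gamma)*I_U)
* ``lesionblend``:   I = T'_L*I_L + (1-T'_L)*I_U
* ``lesionblend2``:  I = (1-T'_L)*I_L + T'_L*I_U
* ``pixmix2``:       I = I_L + I_U, renormalized back into [0, 1]

All operators are deterministic: randomness lives only in how partners are
paired (see :mod:`usmixaug.expand`).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import (
    AugmentedSample,
    BinaryMask,
    GrayImage,
    LabeledSample,
    MixParams,
    SoftMask,
    Strategy,
)

#: Gaussian kernels are truncated at this many standard deviations.
GAUSSIAN_TRUNCATE = 4.0


def smooth_mask(mask: BinaryMask, sigma: float) -> SoftMask:
    """Gaussian-smooth a binary mask into soft blend weights.

    Uses a normalized Gaussian kernel truncated at 4*sigma with reflective
    boundary handling, so constant masks are fixed points and mask mass is
    approximately conserved away from image borders.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    soft = gaussian_filter(
        mask.pixels.astype(np.float64),
        sigma=sigma,
        mode="reflect",
        truncate=GAUSSIAN_TRUNCATE,
    )
    return SoftMask(np.clip(soft, 0.0, 1.0), sigma=sigma)


def _check_dims(labeled: LabeledSample, unlabeled: GrayImage) -> None:
    if labeled.image.shape != unlabeled.shape:
        raise ValueError(
            f"labeled image {labeled.image.shape} and unlabeled image "
            f"{unlabeled.shape} dimensions differ; resize first"
        )


def _wrap(
    image: np.ndarray,
    labeled: LabeledSample,
    unlabeled: GrayImage,
    strategy: Strategy,
    params: dict,
) -> AugmentedSample:
    return AugmentedSample(
        image=GrayImage(np.clip(image, 0.0, 1.0)),
        mask=labeled.mask.copy(),
        strategy=strategy,
        labeled_source_id=labeled.source_id,
        unlabeled_source_id=unlabeled.source_id,
        params=params,
    )


def pixmix(
    labeled: LabeledSample, unlabeled: GrayImage, params: MixParams = MixParams()
) -> AugmentedSample:
    """Global convex blend: keep an alpha fraction of the labeled image and
    mix in a beta fraction of unlabeled context; the mask is untouched."""
    _check_dims(labeled, unlabeled)
    image = params.alpha * labeled.image.pixels + params.beta * unlabeled.pixels
    return _wrap(
        image,
        labeled,
        unlabeled,
        Strategy.PIXMIX,
        {"alpha": params.alpha, "beta": params.beta},
    )


def segmix2(
    labeled: LabeledSample, unlabeled: GrayImage, params: MixParams = MixParams()
) -> AugmentedSample:
    """Transplant the labeled lesion onto the unlabeled image.

    The lesion content itself is an inner gamma-blend of the two images
    (``I'_L = gamma*I_L + (1-gamma)*I_U``), feathered into the unlabeled
    background through the soft mask.
    """
    _check_dims(labeled, unlabeled)
    soft = smooth_mask(labeled.mask, params.sigma).pixels
    inner = params.gamma * labeled.image.pixels + (1.0 - params.gamma) * unlabeled.pixels
    image = (1.0 - soft) * unlabeled.pixels + soft * inner
    return _wrap(
        image,
        labeled,
        unlabeled,
        Strategy.SEGMIX2,
        {"gamma": params.gamma, "sigma": params.sigma},
    )


def lesionblend(
    labeled: LabeledSample, unlabeled: GrayImage, params: MixParams = MixParams()
) -> AugmentedSample:
    """Soft-mask composite keeping the labeled lesion and swapping in
    unlabeled background content."""
    _check_dims(labeled, unlabeled)
    soft = smooth_mask(labeled.mask, params.sigma).pixels
    image = soft * labeled.image.pixels + (1.0 - soft) * unlabeled.pixels
    return _wrap(
        image, labeled, unlabeled, Strategy.LESIONBLEND, {"sigma": params.sigma}
    )


def lesionblend2(
    labeled: LabeledSample, unlabeled: GrayImage, params: MixParams = MixParams()
) -> AugmentedSample:
    """Complement of :func:`lesionblend`: the lesion region is filled from
    the unlabeled image while the labeled background is preserved."""
    _check_dims(labeled, unlabeled)
    soft = smooth_mask(labeled.mask, params.sigma).pixels
    image = (1.0 - soft) * labeled.image.pixels + soft * unlabeled.pixels
    return _wrap(
        image, labeled, unlabeled, Strategy.LESIONBLEND2, {"sigma": params.sigma}
    )


def pixmix2(
    labeled: LabeledSample, unlabeled: GrayImage, params: MixParams = MixParams()
) -> AugmentedSample:
    """Direct per-pixel sum of the two images, mapped back into [0, 1].

    The raw sum lives in [0, 2]; with ``pixmix2_overflow="rescale"`` it is
    min-max rescaled (a constant sum maps to all zeros), with ``"clip"`` it
    is clipped at 1.
    """
    _check_dims(labeled, unlabeled)
    total = labeled.image.pixels + unlabeled.pixels
    if params.pixmix2_overflow == "clip":
        image = np.clip(total, 0.0, 1.0)
    else:
        lo, hi = float(total.min()), float(total.max())
        if hi <= lo:
            image = np.zeros_like(total)
        else:
            image = (total - lo) / (hi - lo)
    return _wrap(
        image,
        labeled,
        unlabeled,
        Strategy.PIXMIX2,
        {"pixmix2_overflow": params.pixmix2_overflow},
    )


#: Dispatch table used by dataset expansion and manifest replay.
MIXED_OPS = {
    Strategy.PIXMIX: pixmix,
    Strategy.SEGMIX2: segmix2,
    Strategy.LESIONBLEND: lesionblend,
    Strategy.LESIONBLEND2: lesionblend2,
    Strategy.PIXMIX2: pixmix2,
}
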