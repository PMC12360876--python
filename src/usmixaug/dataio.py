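"""Reading and writing paired image/mask datasets.

Directory layout
----------------
A labeled dataset is two flat directories of PNG files with matching stems::

    images/case001.png   masks/case001.png
    images/case002.png   masks/case002.png

An unlabeled pool is a single flat directory of PNG files. All files are
8-bit grayscale or RGB PNG; RGB content is converted to luminance on load.

Normalization
-------------
Every image is min-max normalized per file to [0, 1]; a zero-range
(constant) file maps to all zeros. Mask files are binarized at 0.5 of their
own dynamic range, which is robust to anti-aliased mask PNGs.

Generated datasets are written back as 8-bit grayscale PNG together with a
``manifest.csv`` recording, per sample, the strategy, source identifiers,
parameters (JSON) and seed — enough to regenerate each sample bit-exactly.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence, Union

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

from .types import (
    AugmentedSample,
    BinaryMask,
    GrayImage,
    LabeledSample,
    Strategy,
)

# ITU-R BT.601 luma weights, matching PIL's "L" conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

MANIFEST_NAME = "manifest.csv"
MANIFEST_COLUMNS = (
    "output_stem",
    "strategy",
    "labeled_source",
    "unlabeled_source",
    "params_json",
    "seed",
)


def _to_gray2d(raw: np.ndarray) -> np.ndarray:
    """Collapse an imageio array to a 2-D float field (luminance for RGB)."""
    arr = np.asarray(raw, dtype=np.float64)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = arr @ _LUMA
        elif arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"unsupported channel count {arr.shape[2]}")
    if arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim}")
    return arr


def _minmax_normalize(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        return np.zeros_like(arr, dtype=np.float64)
    return (arr - lo) / (hi - lo)


def _binarize(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return (arr >= lo + 0.5 * (hi - lo)).astype(np.uint8)


def read_image(path: Union[str, Path], source_id: str | None = None) -> GrayImage:
    """Read a PNG file as a min-max normalized :class:`GrayImage`."""
    path = Path(path)
    arr = _to_gray2d(iio.imread(path))
    return GrayImage(_minmax_normalize(arr), source_id=source_id or path.stem)


def read_mask(path: Union[str, Path]) -> BinaryMask:
    """Read a PNG mask file, binarized at half its dynamic range."""
    arr = _to_gray2d(iio.imread(Path(path)))
    return BinaryMask(_binarize(arr))


def _png_files(directory: Path) -> list[Path]:
    return sorted(p for p in directory.iterdir() if p.suffix.lower() == ".png")


def load_labeled_dataset(
    images_dir: Union[str, Path], masks_dir: Union[str, Path]
) -> list[LabeledSample]:
    """Load all (image, mask) stem pairs from two flat directories.

    Raises
    ------
    FileNotFoundError
        If an image has no mask file with the same stem.
    ValueError
        If an image and its mask have different dimensions.
    """
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    image_files = _png_files(images_dir)
    if not image_files:
        raise FileNotFoundError(f"no PNG images found in {images_dir}")
    samples = []
    for img_path in image_files:
        mask_path = masks_dir / img_path.name
        if not mask_path.exists():
            raise FileNotFoundError(
                f"missing mask for stem '{img_path.stem}' in {masks_dir}"
            )
        image = read_image(img_path)
        mask = read_mask(mask_path)
        if image.shape != mask.shape:
            raise ValueError(
                f"dimension mismatch for stem '{img_path.stem}': "
                f"image {image.shape} vs mask {mask.shape}"
            )
        samples.append(LabeledSample(image=image, mask=mask, source_id=img_path.stem))
    return samples


def load_unlabeled_pool(images_dir: Union[str, Path]) -> list[GrayImage]:
    """Load a flat directory of unlabeled PNG images."""
    images_dir = Path(images_dir)
    files = _png_files(images_dir)
    if not files:
        raise FileNotFoundError(f"no PNG images found in {images_dir}")
    return [read_image(p) for p in files]


def resize_to(image: GrayImage, height: int, width: int) -> GrayImage:
    """Resize an image with bilinear interpolation; output stays in [0, 1]."""
    if height <= 0 or width <= 0:
        raise ValueError("target dimensions must be positive")
    if (height, width) == image.shape:
        return GrayImage(image.pixels.copy(), source_id=image.source_id)
    out = _sk_resize(
        image.pixels,
        (height, width),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return GrayImage(np.clip(out, 0.0, 1.0), source_id=image.source_id)


def resize_mask(mask: BinaryMask, height: int, width: int) -> BinaryMask:
    """Resize a mask with nearest-neighbor interpolation and re-binarize."""
    if height <= 0 or width <= 0:
        raise ValueError("target dimensions must be positive")
    if (height, width) == mask.shape:
        return mask.copy()
    out = _sk_resize(
        mask.pixels.astype(np.float64),
        (height, width),
        order=0,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return BinaryMask((out > 0.5).astype(np.uint8))


def to_uint8(pixels: np.ndarray) -> np.ndarray:
    """Quantize a [0, 1] float field to 8 bits (round(pixel * 255))."""
    return np.rint(np.clip(pixels, 0.0, 1.0) * 255.0).astype(np.uint8)


def write_png(path: Union[str, Path], pixels: np.ndarray) -> None:
    iio.imwrite(Path(path), to_uint8(pixels))


Sample = Union[LabeledSample, AugmentedSample]


def _sample_stem(sample: Sample, index: int) -> str:
    if isinstance(sample, LabeledSample):
        return sample.source_id
    return f"{sample.strategy.value}_{index:05d}_{sample.labeled_source_id}"


def write_augmented_dataset(
    samples: Sequence[Sample], out_dir: Union[str, Path]
) -> Path:
    """Write samples as 8-bit PNG pairs plus a provenance manifest.

    Original :class:`LabeledSample` entries are written under their own stem
    with strategy ``original``; augmented samples get a strategy-prefixed
    stem. Returns the manifest path.
    """
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    masks_dir = out_dir / "masks"
    images_dir.mkdir(parents=True, exist_ok=True)
    masks_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    seen: set[str] = set()
    for i, sample in enumerate(samples):
        stem = _sample_stem(sample, i)
        if stem in seen:
            raise ValueError(f"output name collision for stem '{stem}'")
        seen.add(stem)
        write_png(images_dir / f"{stem}.png", sample.image.pixels)
        write_png(masks_dir / f"{stem}.png", sample.mask.pixels.astype(np.float64))
        if isinstance(sample, LabeledSample):
            rows.append(
                {
                    "output_stem": stem,
                    "strategy": Strategy.ORIGINAL.value,
                    "labeled_source": sample.source_id,
                    "unlabeled_source": "",
                    "params_json": "{}",
                    "seed": "",
                }
            )
        else:
            rows.append(
                {
                    "output_stem": stem,
                    "strategy": sample.strategy.value,
                    "labeled_source": sample.labeled_source_id,
                    "unlabeled_source": sample.unlabeled_source_id or "",
                    "params_json": json.dumps(sample.params, sort_keys=True),
                    "seed": str(sample.seed),
                }
            )

    manifest_path = out_dir / MANIFEST_NAME
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    return manifest_path


def read_manifest(path: Union[str, Path]) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def replay_sample(
    record: dict,
    labeled_by_id: dict[str, LabeledSample],
    pool_by_id: dict[str, GrayImage],
) -> Sample:
    """Regenerate a sample from its manifest record (provenance replay)."""
    # local import to avoid a circular dependency at module load
    from . import augment as _augment
    from . import baseline as _baseline
    from .types import MixParams

    strategy = Strategy(record["strategy"])
    if strategy is Strategy.ORIGINAL:
        return labeled_by_id[record["labeled_source"]]

    labeled = labeled_by_id[record["labeled_source"]]
    params = json.loads(record["params_json"]) if record["params_json"] else {}
    seed = int(record["seed"]) if record["seed"] else 0

    if strategy in (
        Strategy.PIXMIX,
        Strategy.SEGMIX2,
        Strategy.LESIONBLEND,
        Strategy.LESIONBLEND2,
        Strategy.PIXMIX2,
    ):
        unlabeled = pool_by_id[record["unlabeled_source"]]
        mix_kwargs = {
            k: v
            for k, v in params.items()
            if k in ("alpha", "beta", "gamma", "sigma", "pixmix2_overflow")
        }
        mix = MixParams(**mix_kwargs)
        fn = {
            Strategy.PIXMIX: _augment.pixmix,
            Strategy.SEGMIX2: _augment.segmix2,
            Strategy.LESIONBLEND: _augment.lesionblend,
            Strategy.LESIONBLEND2: _augment.lesionblend2,
            Strategy.PIXMIX2: _augment.pixmix2,
        }[strategy]
        out = fn(labeled, unlabeled, mix)
        out.seed = seed
        return out

    bl = _baseline.BaselineParams(
        angle_range=tuple(params.get("angle_range", (15.0, 345.0))),
        shift_fraction=params.get("shift_fraction", 0.20),
        noise_var_range=tuple(params.get("noise_var_range", (10.0, 50.0))),
        flip_prob=params.get("flip_prob", 0.5),
    )
    if strategy is Strategy.ROTATION:
        return _baseline.rotate_pair(labeled, seed, bl)
    if strategy is Strategy.TRANSLATION:
        return _baseline.translate_pair(labeled, seed, bl)
    if strategy is Strategy.GAUSSIAN_NOISE:
        return _baseline.gaussian_noise_pair(labeled, seed, bl)
    if strategy is Strategy.HFLIP:
        return _baseline.hflip_pair(labeled, seed, bl.flip_prob)
    raise ValueError(f"cannot replay strategy {strategy}")
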