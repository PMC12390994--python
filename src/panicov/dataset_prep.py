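"""Preprocessing for segmentation training sets: tiling, augmentation, splits.

Mirrors the preparation used for nadir rice-canopy imagery: images are
cropped into 512x512 tiles, panicle annotations become binary masks
(0 = background, 1 = panicle), the labeled set is enlarged by photometric
and scale augmentation (brightness/contrast in [0.8, 1.2], Gaussian noise,
upscaling by 1.1-2.0 or downscaling by 0.6-0.9), and items are divided
into train/validation/test partitions at a 7:2:1 ratio.

Splitting is performed at the *source-image* level by default, so that
augmented copies of one photograph can never straddle partitions; item-level
splitting of the augmented pool is available behind ``by_source=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "AugmentationTag",
    "LabeledImage",
    "SplitManifest",
    "crop_to_tiles",
    "augment",
    "augment_dataset",
    "split",
    "largest_remainder",
]

BRIGHTNESS_CONTRAST_RANGE = (0.8, 1.2)
UPSCALE_RANGE = (1.1, 2.0)
DOWNSCALE_RANGE = (0.6, 0.9)
DEFAULT_NOISE_SD = 0.02  # fraction of the 0-255 dynamic range


class AugmentationTag(str, Enum):
    NONE = "none"
    NOISE = "noise"
    BRIGHTNESS_CONTRAST = "brightness_contrast"
    RESCALE = "rescale"


@dataclass
class LabeledImage:
    """An RGB image with its binary panicle mask."""

    image: np.ndarray  # H x W x 3, uint8
    mask: np.ndarray  # H x W, values {0, 1}
    source_id: str
    augmentation_tag: AugmentationTag = AugmentationTag.NONE

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} shapes differ"
            )
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask must be binary {{0,1}}, found {vals}")


@dataclass
class SplitManifest:
    train: list[str]
    val: list[str]
    test: list[str]
    ratios: tuple[float, float, float]

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.val), set(self.test)]
        n = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != n:
            raise ValueError("partitions must be disjoint")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {self.ratios}")


def crop_to_tiles(image: np.ndarray, tile: int = 512) -> list[np.ndarray]:
    """Cut an image into non-overlapping tile x tile blocks, row-major.

    Both dimensions must be integer multiples of ``tile`` (resize first
    otherwise). Concatenating the returned tiles reconstructs the input.
    """
    h, w = image.shape[:2]
    if h % tile or w % tile:
        raise ValueError(
            f"image {h}x{w} is not divisible into {tile}x{tile} tiles; resize first"
        )
    return [
        image[r : r + tile, c : c + tile]
        for r in range(0, h, tile)
        for c in range(0, w, tile)
    ]


def _rescale_pair(
    image: np.ndarray, mask: np.ndarray, factor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale then center-crop/pad back to the original shape.

    Image uses bilinear interpolation, mask nearest-neighbor so it stays
    binary. Padding uses background (0 mask, edge-mean image value).
    """
    h, w = mask.shape
    nh, nw = max(1, round(h * factor)), max(1, round(w * factor))
    img = _sk_resize(image, (nh, nw), order=1, preserve_range=True, anti_aliasing=factor < 1)
    msk = _sk_resize(mask.astype(float), (nh, nw), order=0, preserve_range=True)
    img = img.astype(image.dtype)
    msk = (msk > 0.5).astype(mask.dtype)

    out_img = np.zeros_like(image)
    out_msk = np.zeros_like(mask)
    if factor >= 1:  # center crop
        r0, c0 = (nh - h) // 2, (nw - w) // 2
        out_img = img[r0 : r0 + h, c0 : c0 + w]
        out_msk = msk[r0 : r0 + h, c0 : c0 + w]
    else:  # center pad with background
        out_img[:] = int(np.mean(image))
        r0, c0 = (h - nh) // 2, (w - nw) // 2
        out_img[r0 : r0 + nh, c0 : c0 + nw] = img
        out_msk[r0 : r0 + nh, c0 : c0 + nw] = msk
    return out_img, out_msk


def _one_augmentation(
    item: LabeledImage, ops: list[str], rng: np.random.Generator, noise_sd: float
) -> LabeledImage:
    op = ops[rng.integers(len(ops))]
    img = item.image.astype(float)
    msk = item.mask.copy()
    if op == "gaussian_noise":
        img = img + rng.normal(0.0, noise_sd * 255.0, size=img.shape)
        tag = AugmentationTag.NOISE
    elif op == "brightness_contrast":
        b = rng.uniform(*BRIGHTNESS_CONTRAST_RANGE)
        c = rng.uniform(*BRIGHTNESS_CONTRAST_RANGE)
        img = (img - 127.5) * c + 127.5 + (b - 1.0) * 255.0
        tag = AugmentationTag.BRIGHTNESS_CONTRAST
    elif op in ("upscale", "downscale"):
        rng_lo, rng_hi = UPSCALE_RANGE if op == "upscale" else DOWNSCALE_RANGE
        factor = rng.uniform(rng_lo, rng_hi)
        img8, msk = _rescale_pair(item.image, item.mask, factor)
        img = img8.astype(float)
        tag = AugmentationTag.RESCALE
    else:
        raise ValueError(f"unknown augmentation op {op!r}")
    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return LabeledImage(out, msk, item.source_id, tag)


VALID_OPS = ("gaussian_noise", "brightness_contrast", "upscale", "downscale")


def augment(
    item: LabeledImage,
    n: int,
    seed: int,
    ops: list[str] | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> list[LabeledImage]:
    """Produce ``n`` augmented variants of one labeled image.

    Each variant applies one operation drawn from ``ops`` (default: all
    four families) with factors drawn uniformly within the standard
    ranges. Masks track geometric ops via nearest-neighbor resampling and
    are untouched by photometric ops. Deterministic per seed.
    """
    ops = list(ops) if ops is not None else list(VALID_OPS)
    bad = [o for o in ops if o not in VALID_OPS]
    if bad:
        raise ValueError(f"unknown augmentation ops {bad}; valid: {VALID_OPS}")
    rng = np.random.default_rng(seed)
    return [_one_augmentation(item, ops, rng, noise_sd) for _ in range(n)]


def augment_dataset(
    items: list[LabeledImage], multiplicity: int = 2, seed: int = 0, **kwargs
) -> list[LabeledImage]:
    """Enlarge a labeled set: originals plus ``multiplicity`` variants each.

    The default multiplicity of 2 triples the dataset (867 source images
    become 2,601 labeled items).
    """
    out: list[LabeledImage] = []
    for i, item in enumerate(items):
        out.append(item)
        out.extend(augment(item, multiplicity, seed=seed + i, **kwargs))
    return out


def largest_remainder(n: int, ratios) -> list[int]:
    """Apportion ``n`` items to parts by the largest-remainder method."""
    quotas = [n * r for r in ratios]
    sizes = [int(np.floor(q)) for q in quotas]
    short = n - sum(sizes)
    order = np.argsort([-(q - s) for q, s in zip(quotas, sizes)], kind="stable")
    for i in order[:short]:
        sizes[i] += 1
    return sizes


def split(
    ids: list[str],
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
    source_of: dict[str, str] | None = None,
) -> SplitManifest:
    """Shuffle ids and divide them into train/val/test partitions.

    Sizes follow the largest-remainder apportionment of ``len(ids)`` (or
    of the distinct sources when ``source_of`` maps item id -> source id,
    in which case every item of one source lands in the same partition).
    Deterministic per seed.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("cannot split an empty id list")
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must be positive and sum to 1, got {ratios}")

    units = sorted(set(source_of.values())) if source_of else sorted(ids)
    if len(units) < len(ratios):
        raise ValueError(f"{len(units)} units cannot fill {len(ratios)} partitions")
    rng = np.random.default_rng(seed)
    units = list(np.array(units, dtype=object)[rng.permutation(len(units))])
    n_train, n_val, n_test = largest_remainder(len(units), ratios)
    parts = {
        "train": set(units[:n_train]),
        "val": set(units[n_train : n_train + n_val]),
        "test": set(units[n_train + n_val :]),
    }
    if source_of:
        members: dict[str, list[str]] = {k: [] for k in parts}
        for item in ids:
            src = source_of[item]
            for name, unit_set in parts.items():
                if src in unit_set:
                    members[name].append(item)
                    break
        return SplitManifest(
            members["train"], members["val"], members["test"], tuple(ratios)
        )
    return SplitManifest(
        sorted(parts["train"]), sorted(parts["val"]), sorted(parts["test"]), tuple(ratios)
    )
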