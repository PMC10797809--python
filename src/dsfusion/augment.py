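"""Six-fold RGB image augmentation: resize, rotate, mirror, channel permute.

Each input image yields six outputs — the original plus a random rotation,
a horizontal mirror, a vertical mirror, and the two channel reorderings
RGB→RBG and RGB→BGR — so a dataset of n images expands to 6n. Channel
reordering changes brightness/contrast but not structure: every per-plane
histogram is preserved exactly, only the planes' roles swap. Mirrors and
permutations are lossless involutions; rotation (uniform angle in
[−180°, 180°), bilinear resampling, black corner fill) is the one lossy
transform. Images are resized to a square target (default 512×512×3) by
direct rescale with bilinear interpolation — no cropping.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from PIL import Image

__all__ = [
    "RgbImage",
    "resize",
    "permute_channels",
    "mirror",
    "rotate_random",
    "augment_sixfold",
    "augment_directory",
    "load_image",
    "save_image",
    "train_test_split_files",
]

# channel-plane index order, relative to RGB
_ORDERS = {"RGB": (0, 1, 2), "RBG": (0, 2, 1), "BGR": (2, 1, 0)}


class ImageError(ValueError):
    """Invalid image input (wrong shape, empty dimension)."""


@dataclass(frozen=True)
class RgbImage:
    """An 8-bit image of shape (height, width, 3) with a channel tag."""

    pixels: np.ndarray
    channel_order: str = "RGB"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ImageError(f"expected (H, W, 3) pixels, got shape {px.shape}")
        if px.shape[0] == 0 or px.shape[1] == 0:
            raise ImageError("image has a zero dimension")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ImageError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if self.channel_order not in _ORDERS:
            raise ValueError(f"unknown channel order {self.channel_order!r}")
        object.__setattr__(self, "pixels", px)
        px.setflags(write=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


def resize(img: RgbImage, size: int = 512) -> RgbImage:
    """Rescale to size×size×3 (bilinear, no crop; aspect not preserved)."""
    if size <= 0:
        raise ImageError(f"target size must be positive, got {size}")
    pil = Image.fromarray(img.pixels)
    out = pil.resize((size, size), Image.BILINEAR)
    return RgbImage(np.asarray(out), img.channel_order)


def permute_channels(img: RgbImage, order: str) -> RgbImage:
    """Swap channel planes into ``order`` ∈ {"RBG", "BGR"} (or back to RGB).

    Pure plane permutation: per-plane histograms are preserved bitwise.
    """
    if order not in _ORDERS:
        raise ValueError(f"unknown channel order {order!r}; expected one of {sorted(_ORDERS)}")
    return RgbImage(img.pixels[:, :, _ORDERS[order]], order)


def mirror(img: RgbImage, axis: str) -> RgbImage:
    """Reverse one axis: ``axis`` ∈ {"horizontal", "vertical"}.

    Horizontal mirroring flips left-right (reverses columns), vertical flips
    top-bottom (reverses rows). Both are bitwise involutions.
    """
    if axis == "horizontal":
        return RgbImage(img.pixels[:, ::-1], img.channel_order)
    if axis == "vertical":
        return RgbImage(img.pixels[::-1], img.channel_order)
    raise ValueError(f"unknown mirror axis {axis!r}; expected 'horizontal' or 'vertical'")


def rotate_random(img: RgbImage, rng: np.random.Generator) -> RgbImage:
    """Rotate by an angle drawn uniformly from [−180°, 180°).

    Bilinear resampling, output size unchanged, exposed corners filled black.
    """
    angle = float(rng.uniform(-180.0, 180.0))
    pil = Image.fromarray(img.pixels)
    out = pil.rotate(angle, resample=Image.BILINEAR, fillcolor=(0, 0, 0))
    return RgbImage(np.asarray(out), img.channel_order)


def augment_sixfold(img: RgbImage, rng: np.random.Generator) -> list[RgbImage]:
    """The 6× expansion of one image.

    Returns ``[original, rotated, h-mirrored, v-mirrored, RBG, BGR]``;
    deterministic given the state of ``rng``.
    """
    return [
        img,
        rotate_random(img, rng),
        mirror(img, "horizontal"),
        mirror(img, "vertical"),
        permute_channels(img, "RBG"),
        permute_channels(img, "BGR"),
    ]


def load_image(path) -> RgbImage:
    with Image.open(path) as im:
        return RgbImage(np.asarray(im.convert("RGB")))


def save_image(path, img: RgbImage) -> None:
    Image.fromarray(img.pixels).save(path)


_VARIANT_TAGS = ("orig", "rot", "hmir", "vmir", "rbg", "bgr")


def augment_directory(
    in_dir,
    out_dir,
    seed: int,
    size: int | None = 512,
    patterns: Iterable[str] = ("*.png", "*.jpg", "*.jpeg"),
) -> int:
    """Augment every image under ``in_dir`` six-fold into ``out_dir``.

    Each input produces six PNGs tagged orig/rot/hmir/vmir/rbg/bgr; files are
    processed in sorted order so the run is reproducible for a fixed seed.
    Returns the number of images written (6 × inputs).
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    files = sorted({p for pat in patterns for p in in_dir.glob(pat)})
    written = 0
    for path in files:
        img = load_image(path)
        if size is not None:
            img = resize(img, size)
        for tag, variant in zip(_VARIANT_TAGS, augment_sixfold(img, rng)):
            save_image(out_dir / f"{path.stem}_{tag}.png", variant)
            written += 1
    return written


def train_test_split_files(
    items: list, test_fraction: float = 0.2, seed: int = 0
) -> tuple[list, list]:
    """Seeded random split (default 8:2) of an item list, e.g. augmented files.

    .. warning::
        Splitting *after* augmentation puts variants of the same source image
        on both sides of the split — information leakage that inflates test
        scores. Split before augmenting unless you specifically want the
        post-augmentation protocol.
    """
    import warnings

    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    warnings.warn(
        "splitting after augmentation leaks augmented variants of one source "
        "image across the train/test boundary",
        stacklevel=2,
    )
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(items))
    n_test = round(len(items) * test_fraction)
    test = [items[i] for i in sorted(idx[:n_test])]
    train = [items[i] for i in sorted(idx[n_test:])]
    return train, test
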