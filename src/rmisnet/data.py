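"""Image/mask IO, resizing, paired augmentation and manifest splitting.

Images are loaded channel-first and scaled to [0, 1]; masks are
binarised (any value > 0 becomes foreground).  Resizing uses the same
corner-aligned bilinear interpolation as the network's upsampler for
images, and nearest neighbour for masks so binarity is preserved.  The
three training-time augmentations (horizontal flip, rotation, random
crop-and-resize-back) are each applied independently with probability
0.20 by default, with the identical geometric transform applied to the
image and its mask.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .nn import interp_matrix

__all__ = [
    "ManifestRecord",
    "DatasetManifest",
    "AugmentationConfig",
    "load_pair",
    "save_mask_png",
    "resize_pair",
    "augment_pair",
    "split_manifest",
]

SPLITS = ("train", "val", "test")


@dataclass(frozen=True)
class ManifestRecord:
    image: str
    mask: str
    split: str

    def __post_init__(self):
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}, got {self.split!r}")


@dataclass
class DatasetManifest:
    """Image/mask path pairs with train/val/test assignment."""

    root: Path
    records: list[ManifestRecord] = field(default_factory=list)

    def __post_init__(self):
        self.root = Path(self.root)

    def subset(self, split: str) -> list[ManifestRecord]:
        return [r for r in self.records if r.split == split]

    def resolve(self, rec: ManifestRecord) -> tuple[Path, Path]:
        return self.root / rec.image, self.root / rec.mask

    def validate_paths(self):
        for rec in self.records:
            for p in self.resolve(rec):
                if not p.exists():
                    raise FileNotFoundError(f"manifest entry missing on disk: {p}")

    def save_csv(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image", "mask", "split"])
            for rec in self.records:
                writer.writerow([rec.image, rec.mask, rec.split])

    @classmethod
    def load_csv(cls, path, root=None) -> "DatasetManifest":
        path = Path(path)
        root = Path(root) if root is not None else path.parent
        records = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if set(reader.fieldnames or ()) != {"image", "mask", "split"}:
                raise ValueError(
                    f"manifest {path} must have header image,mask,split"
                )
            for row in reader:
                records.append(ManifestRecord(row["image"], row["mask"], row["split"]))
        return cls(root=root, records=records)


@dataclass(frozen=True)
class AugmentationConfig:
    p_flip: float = 0.20
    p_rotate: float = 0.20
    p_crop: float = 0.20
    rotate_range_deg: tuple[float, float] = (-30.0, 30.0)
    crop_fraction: float = 0.8

    def __post_init__(self):
        for p in (self.p_flip, self.p_rotate, self.p_crop):
            if not 0.0 <= p <= 1.0:
                raise ValueError("augmentation probabilities must lie in [0, 1]")
        if not 0.0 < self.crop_fraction <= 1.0:
            raise ValueError("crop_fraction must lie in (0, 1]")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def load_pair(image_path, mask_path) -> tuple[np.ndarray, np.ndarray]:
    """Read an image (channel-first floats in [0,1]) and its binary mask."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    try:
        with Image.open(image_path) as im:
            if im.mode not in ("L", "I;16", "I"):
                im = im.convert("RGB")
            arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise ValueError(f"unreadable image {image_path}: {exc}") from exc
    try:
        with Image.open(mask_path) as mm:
            mask = np.asarray(mm.convert("L"))
    except (OSError, ValueError) as exc:
        raise ValueError(f"unreadable mask {mask_path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None, :, :]
    else:
        arr = arr.transpose(2, 0, 1)
    denom = 65535.0 if arr.dtype == np.uint16 else 255.0
    image = (arr.astype(np.float32) / denom).clip(0.0, 1.0)
    if image.shape[1:] != mask.shape:
        raise ValueError(
            f"dimension mismatch between {image_path} {image.shape[1:]} "
            f"and {mask_path} {mask.shape}"
        )
    return image, (mask > 0).astype(np.uint8)


def save_mask_png(mask: np.ndarray, path):
    """Write a binary mask as an 8-bit {0, 255} PNG (lossless)."""
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr, mode="L").save(path, format="PNG")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _resize_image(image: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    h, w = image.shape[-2], image.shape[-1]
    lh = interp_matrix(h, target[0])
    lw = interp_matrix(w, target[1])
    return (lh @ image.astype(np.float64) @ lw.T).astype(image.dtype)


def _nearest_index(n_in: int, n_out: int) -> np.ndarray:
    if n_out == 1 or n_in == 1:
        return np.zeros(n_out, dtype=int)
    src = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    return np.round(src).astype(int)


def _resize_mask(mask: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    ri = _nearest_index(mask.shape[0], target[0])
    ci = _nearest_index(mask.shape[1], target[1])
    return mask[np.ix_(ri, ci)]


def resize_pair(image, mask, target: tuple[int, int]):
    """Resize image (bilinear) and mask (nearest neighbour) to (H, W)."""
    th, tw = target
    if th <= 0 or tw <= 0:
        raise ValueError("target dims must be positive")
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[-2:] == (th, tw) and mask.shape == (th, tw):
        return image, mask
    return _resize_image(image, target), _resize_mask(mask, target)


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    config: AugmentationConfig,
    rng: np.random.Generator,
):
    """Apply flip / rotate / crop, each with its probability, to both arrays."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[-2:] != mask.shape:
        raise ValueError("image and mask spatial dims differ")
    if rng.random() < config.p_flip:
        image = image[..., ::-1].copy()
        mask = mask[:, ::-1].copy()
    if rng.random() < config.p_rotate:
        angle = rng.uniform(*config.rotate_range_deg)
        image = ndimage.rotate(
            image, angle, axes=(-2, -1), reshape=False, order=1, mode="reflect"
        )
        mask = ndimage.rotate(
            mask, angle, axes=(-2, -1), reshape=False, order=0, mode="reflect"
        )
        mask = (mask > 0).astype(np.uint8)
    if rng.random() < config.p_crop:
        h, w = mask.shape
        ch = max(1, int(round(h * config.crop_fraction)))
        cw = max(1, int(round(w * config.crop_fraction)))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        image = image[..., top : top + ch, left : left + cw]
        crop_mask = mask[top : top + ch, left : left + cw]
        image, mask = resize_pair(image, crop_mask, (h, w))
    return image, mask


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _sizes_from_fractions(fractions, n: int) -> tuple[int, int, int]:
    fractions = tuple(float(f) for f in fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    # distribute the remainder by largest fractional part
    order = np.argsort([s - r for s, r in zip(sizes, raw)])
    for i in range(n - sum(sizes)):
        sizes[order[i]] += 1
    return tuple(sizes)


def split_manifest(
    pairs,
    counts: tuple[int, int, int] | None = None,
    fractions: tuple[float, float, float] | None = None,
    seed: int = 0,
    root=".",
) -> DatasetManifest:
    """Randomly assign (image, mask) pairs to train/val/test.

    Exactly one of ``counts`` / ``fractions`` controls the sizes; the
    assignment is uniform, disjoint, exhaustive and reproducible for a
    given seed.  Explicit counts take precedence when both are given.
    """
    pairs = list(pairs)
    n = len(pairs)
    if counts is None:
        if fractions is None:
            raise ValueError("provide counts or fractions")
        counts = _sizes_from_fractions(fractions, n)
    counts = tuple(int(c) for c in counts)
    if len(counts) != 3 or min(counts) < 0:
        raise ValueError("counts must be three nonnegative integers")
    if sum(counts) != n:
        raise ValueError(f"counts {counts} do not sum to record total {n}")
    perm = np.random.default_rng(seed).permutation(n)
    labels = np.empty(n, dtype=object)
    start = 0
    for split, size in zip(SPLITS, counts):
        labels[perm[start : start + size]] = split
        start += size
    records = [
        ManifestRecord(str(img), str(msk), labels[i])
        for i, (img, msk) in enumerate(pairs)
    ]
    return DatasetManifest(root=Path(root), records=records)
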