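"""Radiograph preprocessing, flip-based rebalancing, and a baseline
texture descriptor.

The preparation chain mirrors what is done to poor-contrast knee
X-rays before feature extraction: resize to a common side, emphasize
trabecular-bone texture with a frequency-domain high-pass filter,
spread contrast with histogram equalization, then sharpen by unsharp
masking.  Class imbalance is corrected split-wise by duplicating every
minority-class image as its horizontal mirror, which doubles the
minority count and leaves the majority untouched.

All stages operate on 8-bit grayscale intensities in [0, 255] and are
deterministic for fixed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize as _sk_resize

L_LEVELS = 256

__all__ = [
    "ImageSample",
    "DatasetManifest",
    "to_grayscale",
    "equalize_histogram",
    "highpass_frequency",
    "sharpen",
    "resize_image",
    "preprocess_pipeline",
    "flip_augment",
    "rebalance_counts",
    "rebalance_splits",
    "extract_texture_features",
    "load_image_dir",
    "save_images",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ImageSample:
    """An 8-bit grayscale image with its class, split and provenance."""

    pixels: np.ndarray
    class_label: str = "normal"
    split: str = "train"
    source_id: str = ""
    augmented_flag: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 3:
            px = to_grayscale(px)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must form a non-empty 2-D matrix")
        if px.min() < 0 or px.max() > L_LEVELS - 1:
            raise ValueError("intensities must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)


class DatasetManifest:
    """Per-(split, class) image counts with percentage bookkeeping."""

    def __init__(self, counts: dict[tuple[str, str], int]):
        for key, c in counts.items():
            if c < 0:
                raise ValueError(f"negative count for {key}")
        self.counts = dict(counts)

    @classmethod
    def from_images(cls, images: Iterable[ImageSample]) -> "DatasetManifest":
        counts: dict[tuple[str, str], int] = {}
        for img in images:
            key = (img.split, img.class_label)
            counts[key] = counts.get(key, 0) + 1
        return cls(counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count(self, split: str, class_label: str) -> int:
        return self.counts.get((split, class_label), 0)

    def class_total(self, class_label: str) -> int:
        return sum(c for (s, cl), c in self.counts.items() if cl == class_label)

    def percentages(self) -> dict[tuple[str, str], float]:
        """Share of the manifest's own grand total, in percent."""
        total = self.total
        return {k: 100.0 * c / total for k, c in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"split": s, "class": cl, "count": c,
             "percent": 100.0 * c / self.total if self.total else 0.0}
            for (s, cl), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["split", "class", "count", "percent"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        frame = pd.read_csv(path)
        return cls({(r["split"], r["class"]): int(r["count"]) for _, r in frame.iterrows()})


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Luminance conversion with weights 0.299/0.587/0.114."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim == 2:
        return pixels
    gray = pixels[..., 0] * 0.299 + pixels[..., 1] * 0.587 + pixels[..., 2] * 0.114
    return np.floor(gray + 0.5)


def equalize_histogram(img: ImageSample) -> ImageSample:
    """Histogram equalization through the cumulative intensity
    distribution: level k maps to ``round((L-1) * CDF(k))`` with
    round = floor(x + 0.5).  The mapping is monotone non-decreasing."""
    px = img.pixels
    if px.size == 0:
        raise ValueError("empty image")
    counts = np.bincount(px.ravel(), minlength=L_LEVELS)
    cdf = np.cumsum(counts) / px.size
    mapping = np.floor((L_LEVELS - 1) * cdf + 0.5).astype(np.uint8)
    return replace(img, pixels=mapping[px])


def highpass_frequency(img: ImageSample, cutoff: float = 0.05) -> ImageSample:
    """Gaussian high-pass filter in the 2-D frequency domain,
    ``H = 1 - exp(-D^2 / (2*D0^2))`` with ``D0 = cutoff * side``,
    rescaled linearly back to [0, 255].  A constant image (no AC
    energy) maps to a constant output."""
    if not 0.0 < cutoff < 0.5:
        raise ValueError("cutoff must lie in (0, 0.5)")
    px = img.pixels.astype(float)
    rows, cols = px.shape
    fu = np.fft.fftfreq(rows)[:, None] * rows
    fv = np.fft.fftfreq(cols)[None, :] * cols
    d2 = fu**2 + fv**2
    d0 = cutoff * max(rows, cols)
    transfer = 1.0 - np.exp(-d2 / (2.0 * d0**2))
    filtered = np.real(np.fft.ifft2(np.fft.fft2(px) * transfer))
    lo, hi = filtered.min(), filtered.max()
    if hi - lo < 1e-12:
        out = np.full_like(px, 0.0)
    else:
        out = (filtered - lo) / (hi - lo) * (L_LEVELS - 1)
    return replace(img, pixels=np.floor(out + 0.5).astype(np.uint8))


def sharpen(img: ImageSample, amount: float = 1.0, sigma: float = 1.0) -> ImageSample:
    """Unsharp masking: ``clip(in + amount * (in - blur(in)))`` with a
    3x3 Gaussian blur (sigma=1)."""
    px = img.pixels.astype(float)
    blur = ndimage.gaussian_filter(px, sigma=sigma, truncate=1.0, mode="nearest")
    out = np.clip(px + amount * (px - blur), 0, L_LEVELS - 1)
    return replace(img, pixels=np.floor(out + 0.5).astype(np.uint8))


def resize_image(img: ImageSample, side: int = 224) -> ImageSample:
    """Bilinear resize to side x side; a same-size input is untouched."""
    if side < 1:
        raise ValueError("side must be >= 1")
    if img.pixels.shape == (side, side):
        return replace(img, pixels=img.pixels.copy())
    out = _sk_resize(
        img.pixels.astype(float), (side, side), order=1,
        preserve_range=True, anti_aliasing=False,
    )
    out = np.clip(out, 0, L_LEVELS - 1)
    return replace(img, pixels=np.floor(out + 0.5).astype(np.uint8))


def preprocess_pipeline(
    img: ImageSample,
    side: int = 224,
    cutoff: float = 0.05,
    sharpen_amount: float = 1.0,
) -> ImageSample:
    """Full chain: resize -> frequency-domain high-pass -> histogram
    equalization -> sharpening."""
    out = resize_image(img, side)
    out = highpass_frequency(out, cutoff)
    out = equalize_histogram(out)
    out = sharpen(out, amount=sharpen_amount)
    return out


def flip_augment(img: ImageSample) -> ImageSample:
    """Horizontal mirror with the augmented flag set; class and split
    are preserved, the intensity histogram is unchanged."""
    return replace(
        img,
        pixels=np.fliplr(img.pixels).copy(),
        augmented_flag=True,
        source_id=f"{img.source_id}_flip" if img.source_id else "flip",
    )


# ---------------------------------------------------------------------------
# Rebalancing
# ---------------------------------------------------------------------------

def rebalance_counts(manifest: DatasetManifest) -> DatasetManifest:
    """Count-level flip-doubling rule: within each split, the minority
    class count doubles; the majority class and balanced splits are
    untouched."""
    counts = dict(manifest.counts)
    splits = {s for s, _ in counts}
    for split in splits:
        classes = {cl: c for (s, cl), c in counts.items() if s == split}
        if len(classes) != 2:
            raise ValueError(f"split {split!r} must have exactly two classes")
        (cl_a, c_a), (cl_b, c_b) = sorted(classes.items())
        if c_a == c_b:
            continue
        minority = cl_a if c_a < c_b else cl_b
        counts[(split, minority)] *= 2
    return DatasetManifest(counts)


def rebalance_splits(
    images: Sequence[ImageSample],
    method: str = "flip",
    seed: int = 0,
) -> tuple[DatasetManifest, list[ImageSample]]:
    """Image-level rebalancing, split by split.

    ``method='flip'`` (default): every minority-class image is
    duplicated once as its horizontal flip; nothing is removed.
    ``method='subsample'``: the majority class is randomly downsampled
    (seeded) to the minority count instead.  Returns the recomputed
    manifest and the new collection."""
    if method not in ("flip", "subsample"):
        raise ValueError("method must be 'flip' or 'subsample'")
    before = DatasetManifest.from_images(images)
    rng = np.random.default_rng(seed)
    out = list(images)
    for split in sorted({img.split for img in images}):
        classes = {cl: c for (s, cl), c in before.counts.items() if s == split}
        if len(classes) != 2:
            raise ValueError(f"split {split!r} must have exactly two classes")
        (cl_a, c_a), (cl_b, c_b) = sorted(classes.items())
        if c_a == c_b:
            continue
        minority = cl_a if c_a < c_b else cl_b
        majority = cl_b if minority == cl_a else cl_a
        if method == "flip":
            for img in images:
                if img.split == split and img.class_label == minority:
                    out.append(flip_augment(img))
        else:
            members = [img for img in out
                       if img.split == split and img.class_label == majority]
            keep_n = min(c_a, c_b)
            drop_idx = rng.choice(len(members), size=len(members) - keep_n,
                                  replace=False)
            dropped = {id(members[i]) for i in drop_idx}
            out = [img for img in out if id(img) not in dropped]
    return DatasetManifest.from_images(out), out


# ---------------------------------------------------------------------------
# Baseline texture descriptor
# ---------------------------------------------------------------------------

def extract_texture_features(img: ImageSample, grid: int = 4) -> np.ndarray:
    """Deterministic block descriptor of a preprocessed image.

    The image is tiled into ``grid x grid`` equal blocks (row-major).
    The vector concatenates all block means, then all block standard
    deviations, then all block mean gradient magnitudes (gradients
    computed on the full image before tiling), length ``3 * grid**2``.
    """
    px = img.pixels.astype(float)
    side = px.shape[0]
    if px.shape[0] != px.shape[1]:
        raise ValueError("texture descriptor expects a square image")
    if side % grid != 0:
        raise ValueError(f"grid {grid} does not divide image side {side}")
    block = side // grid
    gy, gx = np.gradient(px)
    grad = np.sqrt(gx**2 + gy**2)
    means, sds, grads = [], [], []
    for i in range(grid):
        for j in range(grid):
            tile = px[i * block:(i + 1) * block, j * block:(j + 1) * block]
            gtile = grad[i * block:(i + 1) * block, j * block:(j + 1) * block]
            means.append(tile.mean())
            sds.append(tile.std())
            grads.append(gtile.mean())
    return np.array(means + sds + grads)


# ---------------------------------------------------------------------------
# Disk I/O (PNG/JPEG via Pillow; layout root/split/class/*.png)
# ---------------------------------------------------------------------------

def load_image_dir(root) -> list[ImageSample]:
    from PIL import Image

    root = Path(root)
    images: list[ImageSample] = []
    for split_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for class_dir in sorted(p for p in split_dir.iterdir() if p.is_dir()):
            for f in sorted(class_dir.iterdir()):
                if f.suffix.lower() not in {".png", ".jpg", ".jpeg"}:
                    continue
                px = np.asarray(Image.open(f).convert("L"))
                images.append(ImageSample(px, class_label=class_dir.name,
                                          split=split_dir.name, source_id=f.stem))
    return images


def save_images(images: Iterable[ImageSample], root) -> None:
    from PIL import Image

    root = Path(root)
    for img in images:
        d = root / img.split / img.class_label
        d.mkdir(parents=True, exist_ok=True)
        Image.fromarray(img.pixels).save(d / f"{img.source_id or id(img)}.png")
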