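"""Seeded synthetic data: feature tables with a planted informative
subset, and two-class knee-like textured images.

The feature generator plants ``k`` informative columns whose
class-conditional means are separated by ``effect`` standard-deviation
units; the remaining columns are class-independent noise, so a wrapper
selector has a known ground truth to recover.

The image generator emulates the visual hallmark of knee
osteoarthritis — joint-space narrowing: two bright granular "bone"
bands separated by a dark horizontal gap whose width is drawn from
``Normal(gap_mean, gap_sd)``; the osteoarthritis class uses a smaller
``gap_mean`` than the normal class.  No radiographic realism is
attempted beyond that.  Every generator is a pure function of its spec
(bit-reproducible by seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import DatasetManifest, ImageSample, save_images
from .select import FeatureTable, BinaryMask

__all__ = [
    "FeatureTableSpec",
    "KneeImageSpec",
    "gen_feature_table",
    "gen_knee_image",
    "gen_dataset",
    "measure_joint_gap",
    "DEFAULT_GAP_FRACTIONS",
]

# Default joint-gap widths as a fraction of the image side: the normal
# class keeps a wide joint space, the osteoarthritis class a narrowed one.
DEFAULT_GAP_FRACTIONS = {"normal": 0.14, "osteoarthritis": 0.06}


@dataclass
class FeatureTableSpec:
    """Two-class table with a planted informative subset."""

    n_samples: int = 120
    D: int = 8
    k: int = 2
    effect: float = 6.0
    noise_sd: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.D:
            raise ValueError("need 1 <= k <= D")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.n_samples < 4:
            raise ValueError("need n_samples >= 4")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")


@dataclass
class KneeImageSpec:
    """One knee-like textured image with a dark joint gap."""

    side: int = 64
    class_label: str = "normal"
    gap_mean: float | None = None
    gap_sd: float | None = None
    texture_grain: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side < 32:
            raise ValueError("side must be >= 32")
        if self.gap_mean is None:
            frac = DEFAULT_GAP_FRACTIONS.get(self.class_label, 0.10)
            self.gap_mean = frac * self.side
        if self.gap_sd is None:
            self.gap_sd = 0.02 * self.side
        if self.gap_mean <= 0:
            raise ValueError("gap_mean must be positive")


def gen_feature_table(spec: FeatureTableSpec) -> tuple[FeatureTable, BinaryMask]:
    """Generate the table and the ground-truth informative mask.

    Informative columns are class-conditional normals with means
    ``-/+ effect/2`` (in units of ``noise_sd``); the rest are
    class-independent ``Normal(0, noise_sd)`` noise.
    """
    rng = np.random.default_rng(spec.seed)
    n0 = int(round(spec.n_samples * spec.class_balance))
    labels = np.array([0] * n0 + [1] * (spec.n_samples - n0))
    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.D))
    informative = rng.choice(spec.D, size=spec.k, replace=False)
    shift = spec.effect / 2.0 * spec.noise_sd
    signs = np.where(labels == 0, -1.0, 1.0)
    for col in informative:
        values[:, col] += signs * shift
    bits = np.zeros(spec.D, dtype=np.int8)
    bits[informative] = 1
    table = FeatureTable(values, labels, [f"f{i}" for i in range(spec.D)])
    return table, BinaryMask(bits)


def gen_knee_image(spec: KneeImageSpec) -> ImageSample:
    """Render one image: bright textured bone bands (mean 170) above
    and below a dark gap (mean 40) of width ~ Normal(gap_mean, gap_sd),
    centred mid-image with a small vertical jitter."""
    rng = np.random.default_rng(spec.seed)
    side = spec.side
    img = 170.0 + spec.texture_grain * rng.standard_normal((side, side))
    gap_width = max(2, int(round(rng.normal(spec.gap_mean, spec.gap_sd))))
    gap_width = min(gap_width, side // 2)
    jitter = int(round(rng.normal(0.0, 0.02 * side)))
    centre = side // 2 + jitter
    top = max(1, centre - gap_width // 2)
    bottom = min(side - 1, top + gap_width)
    img[top:bottom, :] = 40.0 + 5.0 * rng.standard_normal((bottom - top, side))
    img = np.clip(np.floor(img + 0.5), 0, 255)
    return ImageSample(img.astype(np.uint8), class_label=spec.class_label)


def measure_joint_gap(img: ImageSample, threshold: int = 100) -> int:
    """Operational gap width: the longest run of pixels darker than
    ``threshold`` in the centre column."""
    col = img.pixels[:, img.pixels.shape[1] // 2]
    best = run = 0
    for v in col:
        run = run + 1 if v < threshold else 0
        best = max(best, run)
    return best


def gen_dataset(
    counts: dict[tuple[str, str], int],
    seed: int = 0,
    side: int = 64,
    texture_grain: float = 20.0,
    out_dir=None,
) -> tuple[list[ImageSample], DatasetManifest]:
    """Generate a per-(split, class) image collection matching the
    requested counts exactly, optionally writing the
    ``root/split/class/*.png`` layout consumed by the preprocessing
    stage.  Per-image seeds derive from the master seed."""
    master = np.random.default_rng(seed)
    images: list[ImageSample] = []
    for (split, class_label), count in sorted(counts.items()):
        if count < 0:
            raise ValueError("counts must be non-negative")
        for i in range(count):
            child_seed = int(master.integers(2**31))
            sample = gen_knee_image(KneeImageSpec(
                side=side, class_label=class_label,
                texture_grain=texture_grain, seed=child_seed,
            ))
            sample.split = split
            sample.source_id = f"{split}_{class_label}_{i:05d}"
            images.append(sample)
    manifest = DatasetManifest.from_images(images)
    for key, count in counts.items():
        if count > 0 and manifest.count(*key) != count:
            raise AssertionError("manifest does not match requested counts")
    if out_dir is not None:
        save_images(images, Path(out_dir))
        manifest.to_csv(Path(out_dir) / "manifest.csv")
    return images, manifest
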