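"""Background masking, augmentation and leakage-free splitting.

The foreground/background separation follows the classic recipe for tissue
images with packaging artifacts: convert to 8-bit, max-filter, erode and
Gaussian-blur to consolidate the tissue region, then 2-cluster k-means on
intensities; the cluster with the higher mean intensity is foreground.
k-means is initialised deterministically from the two intensity extremes so
the mask is reproducible.

Augmentation emits independent transformed copies per input image: a random
rotation up to +/-45 degrees, horizontal and vertical flips, random width /
height shifts up to 20%, and three contrast-enhanced variants (contrast
stretching, histogram equalisation, CLAHE).  Geometric fills use constant
zero, matching background-removed images.  Labels and sample identity are
always preserved.

Splitting is performed at the *sample* level so that no sample contributes
slices to more than one of train/val/test -- the leakage rule for sliced
volumetric data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, transform

from .exceptions import ConfigurationError, ContractError, DegenerateInputError
from .synthetic import SliceImage

__all__ = ["ForegroundConfig", "SplitAssignment", "foreground_mask", "augment",
           "split_by_sample", "PARTITIONS"]

PARTITIONS = ("train", "val", "test")


@dataclass(frozen=True)
class ForegroundConfig:
    """Kernel sizes for the background-masking pipeline.

    Defaults are the smallest standard 3x3 square filters with a Gaussian
    sigma of 0.5, sized for the 64-128 px desk-scale images this package
    targets; at higher resolutions scale sigma with the image."""

    max_filter_size: int = 3
    erosion_size: int = 3
    gaussian_sigma: float = 0.5


def foreground_mask(image, config: ForegroundConfig | None = None) -> np.ndarray:
    """Binary foreground mask (1 = tissue) via filtering + 2-means clustering.

    Accepts a :class:`SliceImage` or a 2-D array with values in [0, 1].
    Raises :class:`DegenerateInputError` on a constant image, where two
    intensity clusters do not exist.
    """
    cfg = config or ForegroundConfig()
    img = image.image if isinstance(image, SliceImage) else np.asarray(image)
    if img.ndim != 2:
        raise ContractError("foreground_mask expects a 2-D grayscale image")
    img8 = np.clip(np.round(np.clip(img, 0.0, 1.0) * 255), 0, 255).astype(np.uint8)
    if img8.max() == img8.min():
        raise DegenerateInputError("constant image: background clustering is degenerate")
    x = ndimage.maximum_filter(img8, size=cfg.max_filter_size)
    x = ndimage.grey_erosion(x, size=(cfg.erosion_size, cfg.erosion_size))
    x = ndimage.gaussian_filter(x.astype(float), sigma=cfg.gaussian_sigma)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateInputError("filtered image is constant; cannot form two clusters")
    # 1-D Lloyd iterations from the two intensity extremes (deterministic)
    centers = np.array([lo, hi], dtype=float)
    flat = x.ravel()
    for _ in range(100):
        assign = np.abs(flat[:, None] - centers[None, :]).argmin(axis=1)
        new = np.array([
            flat[assign == k].mean() if np.any(assign == k) else centers[k]
            for k in (0, 1)
        ])
        if np.allclose(new, centers):
            centers = new
            break
        centers = new
    assign = np.abs(flat[:, None] - centers[None, :]).argmin(axis=1)
    fg_cluster = int(np.argmax(centers))
    return (assign == fg_cluster).reshape(img.shape).astype(np.uint8)


def _wrap_like(source, arr: np.ndarray):
    if isinstance(source, SliceImage):
        return SliceImage(arr, source.sample_id, source.slice_index, source.y,
                          source.treatment_level)
    return arr


def augment(
    image,
    rng: np.random.Generator,
    max_rotation_deg: float = 45.0,
    max_shift_frac: float = 0.20,
    geometric: bool = True,
    contrast: bool = True,
) -> list:
    """Independent augmented copies of a training image; labels preserved."""
    img = image.image if isinstance(image, SliceImage) else np.asarray(image)
    img = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    out = []
    if geometric:
        angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
        out.append(transform.rotate(img, angle, mode="constant", cval=0.0,
                                    preserve_range=True))
        out.append(img[:, ::-1].copy())      # horizontal flip
        out.append(img[::-1, :].copy())      # vertical flip
        dy = rng.uniform(-max_shift_frac, max_shift_frac) * img.shape[0]
        dx = rng.uniform(-max_shift_frac, max_shift_frac) * img.shape[1]
        out.append(ndimage.shift(img, (dy, dx), order=1, mode="constant", cval=0.0))
    if contrast:
        p2, p98 = np.percentile(img, (2, 98))
        out.append(exposure.rescale_intensity(img, in_range=(p2, p98)))
        out.append(exposure.equalize_hist(img))
        out.append(exposure.equalize_adapthist(img, clip_limit=0.02))
    return [_wrap_like(image, np.clip(a, 0.0, 1.0)) for a in out]


@dataclass
class SplitAssignment:
    """Sample-level partition map honouring the leakage rule."""

    assignment: dict  # sample_id -> partition name

    def partition_of(self, sample_id: str) -> str:
        return self.assignment[sample_id]

    def samples_in(self, partition: str) -> list:
        return sorted(s for s, p in self.assignment.items() if p == partition)

    def sizes(self) -> dict:
        return {p: len(self.samples_in(p)) for p in PARTITIONS}


def split_by_sample(samples, fractions=(0.8, 0.1, 0.1), seed: int = 0) -> SplitAssignment:
    """Randomly assign whole samples to train/val/test.

    ``samples`` may be SyntheticSample objects or bare sample-id strings.
    Counts follow the largest-remainder rule; any partition with a positive
    fraction is guaranteed at least one sample (taken from the largest
    partition), so the smallest usable input is 3 samples.
    """
    ids = [s if isinstance(s, str) else s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ContractError("duplicate sample ids")
    if len(ids) < 3:
        raise ContractError("need at least 3 samples to split")
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ConfigurationError("fractions must be three non-negative numbers")
    if not np.isclose(sum(fractions), 1.0):
        raise ConfigurationError("fractions must sum to 1")
    n = len(ids)
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rema = np.array(raw) - np.array(counts)
    for k in np.argsort(-rema)[: n - sum(counts)]:
        counts[k] += 1
    for k, f in enumerate(fractions):
        while f > 0 and counts[k] == 0:
            donor = int(np.argmax(counts))
            counts[donor] -= 1
            counts[k] += 1
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(ids))
    assignment, at = {}, 0
    for part, cnt in zip(PARTITIONS, counts):
        for sid in order[at : at + cnt]:
            assignment[sid] = part
        at += cnt
    return SplitAssignment(assignment)
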