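"""Extreme-point cropping, resizing, augmentation, and dataset splitting.

Brain MR slices typically show the head surrounded by a large dark border.
The crop stage removes that border by thresholding the image, cleaning the
binary mask with erosions/dilations, tracing the largest connected foreground
component, locating its four extreme points (leftmost, rightmost, topmost,
bottommost boundary pixels), and cropping to the box they span.  Images are
then resized with bicubic interpolation to the extractor's input size, and the
training set may be augmented with the eight dihedral variants (0/90/180/270
degree rotations, each with and without horizontal flip).

Images are plain 2-D ``numpy`` arrays of intensities; masks are 2-D boolean
arrays; coordinates are 0-based ``(row, col)`` pairs and crop intervals are
inclusive at both ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian
from skimage.transform import resize as _sk_resize

from .errors import InvalidInputError, NoForegroundError

__all__ = [
    "ExtremePoints",
    "SplitPartition",
    "binarize",
    "morph_clean",
    "largest_component_contour",
    "find_extreme_points",
    "crop_to_extremes",
    "crop_pipeline",
    "resize_bicubic",
    "augment_dihedral",
    "dihedral_transform",
    "split_dataset",
]

_STRUCT_3X3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ExtremePoints:
    """The four extreme boundary pixels of a contour, as (row, col) pairs."""

    left: tuple[int, int]
    right: tuple[int, int]
    top: tuple[int, int]
    bottom: tuple[int, int]

    def __post_init__(self) -> None:
        if self.left[1] > self.right[1] or self.top[0] > self.bottom[0]:
            raise InvalidInputError("extreme points are not consistently ordered")


@dataclass(frozen=True)
class SplitPartition:
    """A reproducible train/test partition of sample ids."""

    train_ids: tuple
    test_ids: tuple
    train_fraction: float
    seed: int
    stratified: bool = False


def _require_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidInputError("expected a non-empty 2-D grayscale image")
    return arr


def binarize(image: np.ndarray, threshold: float = 45.0, smooth_radius: float = 2.0) -> np.ndarray:
    """Threshold a grayscale image into a boolean foreground mask.

    A Gaussian blur of standard deviation ``smooth_radius`` (0 disables it) is
    applied first so isolated noise pixels do not survive thresholding; a pixel
    is foreground iff its (smoothed) intensity strictly exceeds ``threshold``.
    """
    arr = _require_image(image).astype(float)
    if smooth_radius and smooth_radius > 0:
        arr = gaussian(arr, sigma=smooth_radius, preserve_range=True)
    return arr > threshold


def morph_clean(mask: np.ndarray, erode_iters: int = 2, dilate_iters: int = 2) -> np.ndarray:
    """Erode then dilate a mask with a 3x3 structuring element.

    Equal iteration counts perform a morphological opening, which removes
    speckle smaller than the structuring element while leaving solid convex
    components unchanged. Zero iterations of either kind is the identity.
    """
    if erode_iters < 0 or dilate_iters < 0:
        raise InvalidInputError("iteration counts must be >= 0")
    out = np.asarray(mask, dtype=bool)
    if erode_iters > 0:
        out = ndimage.binary_erosion(out, structure=_STRUCT_3X3, iterations=erode_iters)
    if dilate_iters > 0:
        out = ndimage.binary_dilation(out, structure=_STRUCT_3X3, iterations=dilate_iters)
    return out


def largest_component_contour(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of the largest 8-connected foreground component.

    Returns an (n, 2) integer array of (row, col) boundary pixels, sorted
    lexicographically so the result is deterministic for a fixed mask.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise NoForegroundError("mask contains no foreground pixels")
    labels, n = ndimage.label(m, structure=_STRUCT_3X3)
    sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
    biggest = m if n == 1 else labels == (1 + int(np.argmax(sizes)))
    interior = ndimage.binary_erosion(biggest, structure=_STRUCT_3X3, border_value=0)
    boundary = biggest & ~interior
    pts = np.argwhere(boundary)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    return pts[order]


def find_extreme_points(contour: np.ndarray) -> ExtremePoints:
    """Locate the left/right/top/bottom extreme points of a contour.

    Ties are broken by lowest row, then lowest column.
    """
    pts = np.asarray(contour)
    if pts.size == 0:
        raise InvalidInputError("contour is empty")
    pts = pts.reshape(-1, 2)

    def _pick(mask_vals: np.ndarray) -> tuple[int, int]:
        cand = pts[mask_vals]
        i = np.lexsort((cand[:, 1], cand[:, 0]))[0]
        return int(cand[i, 0]), int(cand[i, 1])

    return ExtremePoints(
        left=_pick(pts[:, 1] == pts[:, 1].min()),
        right=_pick(pts[:, 1] == pts[:, 1].max()),
        top=_pick(pts[:, 0] == pts[:, 0].min()),
        bottom=_pick(pts[:, 0] == pts[:, 0].max()),
    )


def crop_to_extremes(image: np.ndarray, ep: ExtremePoints, margin: int = 0) -> np.ndarray:
    """Crop to the box spanned by the extreme points, inclusive, plus margin.

    The margin is clipped at the image border rather than raising.
    """
    arr = _require_image(image)
    h, w = arr.shape
    for r, c in (ep.left, ep.right, ep.top, ep.bottom):
        if not (0 <= r < h and 0 <= c < w):
            raise InvalidInputError(f"extreme point ({r}, {c}) outside image of shape {arr.shape}")
    if margin < 0:
        raise InvalidInputError("margin must be >= 0")
    r0 = max(ep.top[0] - margin, 0)
    r1 = min(ep.bottom[0] + margin, h - 1)
    c0 = max(ep.left[1] - margin, 0)
    c1 = min(ep.right[1] + margin, w - 1)
    return arr[r0 : r1 + 1, c0 : c1 + 1]


def crop_pipeline(
    image: np.ndarray,
    threshold: float = 45.0,
    smooth_radius: float = 2.0,
    erode_iters: int = 2,
    dilate_iters: int = 2,
    margin: int = 0,
) -> np.ndarray:
    """Full extreme-point crop: threshold, clean, trace, locate, crop."""
    mask = morph_clean(binarize(image, threshold, smooth_radius), erode_iters, dilate_iters)
    contour = largest_component_contour(mask)
    return crop_to_extremes(image, find_extreme_points(contour), margin)


def resize_bicubic(image: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Resize with bicubic interpolation to exactly (target_h, target_w)."""
    arr = _require_image(image)
    if target_h < 1 or target_w < 1:
        raise InvalidInputError("target dimensions must be >= 1")
    return _sk_resize(
        arr.astype(float), (target_h, target_w), order=3, anti_aliasing=False, preserve_range=True
    )


def dihedral_transform(image: np.ndarray, k: int, flip: bool) -> np.ndarray:
    """Rotate 90 degrees ``k`` times then optionally flip horizontally."""
    out = np.rot90(_require_image(image), k % 4)
    return np.fliplr(out) if flip else out


def augment_dihedral(
    image: np.ndarray, mode: str = "exhaustive", seed: int = 0
) -> list[np.ndarray]:
    """The dihedral-group augmentations of an image.

    ``exhaustive`` returns all 8 variants in fixed order (k = 0..3 rotations,
    unflipped then flipped); ``random`` draws one (k, flip) pair from the seed,
    matching an augmentation policy of rotating by 90 degrees zero or more
    times and optionally flipping.
    """
    arr = _require_image(image)
    if mode == "exhaustive":
        return [dihedral_transform(arr, k, flip) for k in range(4) for flip in (False, True)]
    if mode == "random":
        rng = np.random.default_rng(seed)
        k = int(rng.integers(0, 4))
        flip = bool(rng.integers(0, 2))
        return [dihedral_transform(arr, k, flip)]
    raise InvalidInputError(f"unknown augmentation mode: {mode!r}")


def split_dataset(
    ids: list,
    labels: list,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratified: bool = False,
) -> SplitPartition:
    """Seeded train/test split with |train| = floor(train_fraction * n).

    In stratified mode each class contributes floor(train_fraction * n_c)
    training samples first, and the remainder needed to reach the global floor
    count is assigned to the classes with the largest fractional parts.
    """
    ids = list(ids)
    labels = list(labels)
    n = len(ids)
    if n < 2:
        raise InvalidInputError("need at least 2 samples to split")
    if len(labels) != n:
        raise InvalidInputError("ids and labels must be aligned")
    if not (0.0 < train_fraction < 1.0):
        raise InvalidInputError("train_fraction must be in (0, 1)")
    n_train = math.floor(train_fraction * n)
    rng = np.random.default_rng(seed)

    if not stratified:
        order = rng.permutation(n)
        train_idx = set(order[:n_train].tolist())
    else:
        classes: dict = {}
        for i, lab in enumerate(labels):
            classes.setdefault(lab, []).append(i)
        quota: dict = {}
        fracs: list[tuple[float, object]] = []
        for lab in sorted(classes, key=str):
            exact = train_fraction * len(classes[lab])
            quota[lab] = math.floor(exact)
            fracs.append((exact - math.floor(exact), lab))
        short = n_train - sum(quota.values())
        for _, lab in sorted(fracs, key=lambda t: (-t[0], str(t[1])))[:short]:
            quota[lab] += 1
        train_idx = set()
        for lab, members in classes.items():
            perm = rng.permutation(len(members))
            train_idx.update(members[j] for j in perm[: quota[lab]])

    train_ids = tuple(ids[i] for i in range(n) if i in train_idx)
    test_ids = tuple(ids[i] for i in range(n) if i not in train_idx)
    return SplitPartition(train_ids, test_ids, train_fraction, seed, stratified)
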