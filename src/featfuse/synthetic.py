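"""Synthetic phantoms and feature banks for pipeline testing.

Two generators stand in for the brain-MR benchmark datasets:

* **Phantoms** — grayscale images with a dark border, a mid-intensity filled
  ellipse for the "brain" at a jittered center, an optional hyperintense
  "tumor" blob, and additive Gaussian noise.  A 2-class scheme (normal/tumor)
  and a 4-class scheme (normal/glioma/meningioma/pituitary) are provided; the
  blob-regime-to-class mapping is an artifact convention (one large off-center
  blob, one blob near the brain rim, one small central blob) with no claim of
  radiological realism.  The dark border guarantees the extreme-point crop
  stage has work to do.

* **Feature banks** — per-extractor tables of class-conditional Gaussian
  features.  Each extractor has a set of informative axes on which the means
  of its *separated* classes differ by a controllable effect size; all other
  axes are pure noise.  Extractors sharing an architecture family share their
  informative subspace (drawn from a family-level stream), emulating the
  redundancy of same-lineage networks, so the family-exclusion rule of the
  selection stage has a measurable signal to act on.

Every generator is a pure function of its configuration and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import rng_for, substream_seed
from .errors import InvalidInputError
from .features import FeatureTable, family_of

__all__ = [
    "PhantomConfig",
    "BankExtractorSpec",
    "FeatureBankConfig",
    "generate_phantom",
    "generate_phantom_dataset",
    "generate_feature_bank",
    "TWO_CLASS_LABELS",
    "FOUR_CLASS_LABELS",
]

TWO_CLASS_LABELS = ("normal", "tumor")
FOUR_CLASS_LABELS = ("normal", "glioma", "meningioma", "pituitary")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and noise of the phantom generator.

    Intensities are on the 8-bit 0-255 scale: background ~10, brain ellipse
    120, tumor blob brain + ``tumor_intensity``.
    """

    image_size: tuple[int, int] = (128, 128)
    classes: tuple[str, ...] = TWO_CLASS_LABELS
    background: float = 10.0
    brain_intensity: float = 120.0
    brain_axes: tuple[tuple[float, float], tuple[float, float]] = ((30.0, 42.0), (24.0, 36.0))
    tumor_intensity: float = 80.0
    tumor_radius_range: tuple[float, float] = (8.0, 14.0)
    noise_sd: float = 4.0
    border_pad: int = 16
    center_jitter: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        (a_lo, a_hi), (b_lo, b_hi) = self.brain_axes
        r_lo, r_hi = self.tumor_radius_range
        if r_hi >= min(a_lo, b_lo):
            raise InvalidInputError("tumor radius range does not fit inside the brain ellipse")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        h, w = self.image_size
        if a_hi + self.border_pad >= w / 2 or b_hi + self.border_pad >= h / 2:
            raise InvalidInputError("brain ellipse plus border padding exceeds the image")
        for c in self.classes:
            if c not in TWO_CLASS_LABELS + FOUR_CLASS_LABELS:
                raise InvalidInputError(f"unknown phantom class {c!r}")


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_phantom(config: PhantomConfig, class_label: str, instance_seed: int) -> np.ndarray:
    """One phantom image; deterministic per (config, label, instance_seed)."""
    config.validate()
    if class_label not in config.classes:
        raise InvalidInputError(f"class {class_label!r} not in config.classes")
    h, w = config.image_size
    rng = rng_for(config.seed, "phantom", class_label, instance_seed)

    (a_lo, a_hi), (b_lo, b_hi) = config.brain_axes
    rx = rng.uniform(a_lo, a_hi)
    ry = rng.uniform(b_lo, b_hi)
    cy = h / 2 + rng.uniform(-config.center_jitter, config.center_jitter)
    cx = w / 2 + rng.uniform(-config.center_jitter, config.center_jitter)

    img = np.full((h, w), config.background, dtype=float)
    brain = _ellipse_mask(h, w, cy, cx, ry, rx)
    img[brain] = config.brain_intensity

    r_lo, r_hi = config.tumor_radius_range
    blobs: list[tuple[float, float, float]] = []  # (cy, cx, r)
    if class_label == "tumor" or class_label == "glioma":
        # one large off-center blob
        r = rng.uniform(max(r_lo, 0.7 * r_hi), r_hi)
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.2, 0.45)
        blobs.append((cy + rad * ry * np.sin(ang), cx + rad * rx * np.cos(ang), r))
    elif class_label == "meningioma":
        # blob hugging the brain rim
        r = rng.uniform(r_lo, 0.8 * r_hi)
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.6, 0.75)
        blobs.append((cy + rad * ry * np.sin(ang), cx + rad * rx * np.cos(ang), r))
    elif class_label == "pituitary":
        # small central blob
        r = rng.uniform(r_lo, max(r_lo + 1e-6, 0.55 * r_hi))
        blobs.append((cy + rng.uniform(-2, 2), cx + rng.uniform(-2, 2), r))

    for by, bx, br in blobs:
        blob = _ellipse_mask(h, w, by, bx, br, br) & brain
        img[blob] = config.brain_intensity + config.tumor_intensity

    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    # keep the guaranteed-dark border so cropping always has margin to remove
    pad = config.border_pad
    img[:pad, :] = config.background
    img[-pad:, :] = config.background
    img[:, :pad] = config.background
    img[:, -pad:] = config.background
    return np.clip(img, 0.0, 255.0)


def generate_phantom_dataset(
    config: PhantomConfig, n_per_class: int
) -> tuple[list[np.ndarray], list[str], list[str]]:
    """Balanced phantom dataset: n_per_class images for every class."""
    if n_per_class < 1:
        raise InvalidInputError("n_per_class must be >= 1")
    config.validate()
    images, ids, labels = [], [], []
    for label in config.classes:
        for i in range(n_per_class):
            inst = substream_seed(config.seed, "instance", label, i)
            images.append(generate_phantom(config, label, inst))
            ids.append(f"{label}_{i:04d}")
            labels.append(label)
    return images, ids, labels


@dataclass(frozen=True)
class BankExtractorSpec:
    """One synthetic extractor of a feature bank.

    ``separated_classes`` lists the class indices whose means are pulled apart
    on the informative axes; classes outside the set share the zero mean, so
    this extractor alone cannot distinguish them.  ``None`` separates all
    classes (a globally informative extractor).
    """

    extractor_id: str
    family: str | None = None
    dim: int = 16
    n_informative: int = 4
    class_separation: float = 2.0
    noise_sd: float = 1.0
    separated_classes: tuple[int, ...] | None = None

    def resolved_family(self) -> str:
        return self.family if self.family is not None else family_of(self.extractor_id)


@dataclass(frozen=True)
class FeatureBankConfig:
    """A bank of row-aligned synthetic feature tables."""

    n_samples: int = 400
    n_classes: int = 2
    extractors: tuple[BankExtractorSpec, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < self.n_classes:
            raise InvalidInputError("need at least one sample per class")
        if not self.extractors:
            raise InvalidInputError("feature bank needs at least one extractor")
        for ex in self.extractors:
            if not (1 <= ex.n_informative <= ex.dim):
                raise InvalidInputError(f"{ex.extractor_id}: informative axes must be in 1..dim")
            if ex.class_separation < 0:
                raise InvalidInputError(f"{ex.extractor_id}: class_separation must be >= 0")
            if ex.separated_classes is not None and any(
                not (0 <= c < self.n_classes) for c in ex.separated_classes
            ):
                raise InvalidInputError(f"{ex.extractor_id}: separated class index out of range")


def _class_mean_directions(
    config: FeatureBankConfig, family: str, n_informative: int
) -> np.ndarray:
    """Per-class unit directions on the informative axes, shared per family.

    When the informative subspace is wide enough the directions are
    orthonormal (QR of a seeded Gaussian draw), so any two separated classes
    sit a full sqrt(2) x separation apart; otherwise they are independent
    unit vectors.
    """
    rng = rng_for(config.seed, "family-subspace", family)
    if n_informative >= config.n_classes:
        g = rng.standard_normal((n_informative, config.n_classes))
        q, _ = np.linalg.qr(g)
        return q.T
    dirs = rng.standard_normal((config.n_classes, n_informative))
    norms = np.linalg.norm(dirs, axis=1, keepdims=True)
    return dirs / np.where(norms == 0, 1.0, norms)


def generate_feature_bank(config: FeatureBankConfig) -> list[FeatureTable]:
    """Generate all extractor tables, row-aligned on one balanced label draw.

    Labels are balanced by construction (round-robin over classes).  For every
    extractor, samples are drawn as ``mean[class] + noise_sd * N(0, I)`` with
    ``mean[class] = class_separation * direction[class]`` on the informative
    axes for separated classes and zero elsewhere.  Family mates use the same
    per-class directions, so their informative-axis class means are collinear.
    """
    config.validate()
    n = config.n_samples
    labels = np.arange(n) % config.n_classes
    ids = [f"s{i:05d}" for i in range(n)]

    tables = []
    for ex in config.extractors:
        fam = ex.resolved_family()
        dirs = _class_mean_directions(config, fam, ex.n_informative)
        means = np.zeros((config.n_classes, ex.dim))
        sep = (
            set(ex.separated_classes)
            if ex.separated_classes is not None
            else set(range(config.n_classes))
        )
        for c in sep:
            means[c, : ex.n_informative] = ex.class_separation * dirs[c]
        rng = rng_for(config.seed, "bank", ex.extractor_id)
        X = means[labels] + ex.noise_sd * rng.standard_normal((n, ex.dim))
        tables.append(
            FeatureTable(
                values=X,
                extractor_id=ex.extractor_id,
                family=fam,
                sample_ids=ids,
                labels=labels.copy(),
            )
        )
    return tables
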