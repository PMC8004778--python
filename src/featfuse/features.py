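"""Feature tables and the pluggable extractor interface.

A :class:`FeatureTable` is the unit passed between extraction, selection, and
ensembling: an ``n_samples x d`` matrix plus the extractor id, its
architecture-family label, and the aligned sample ids and class labels.

Extractors are deterministic functions of (spec, images).  Three toy
extractors ship with the package — an intensity histogram, a block-mean grid,
and a seeded random projection — so every downstream stage is testable without
pretrained network weights.  Frozen-backbone extractors plug in through the
same :class:`ExtractorSpec` interface via ``register_extractor``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import h5py
import numpy as np
import pandas as pd

from .errors import DataError, InvalidInputError

__all__ = [
    "FeatureTable",
    "ExtractorSpec",
    "extract_features",
    "register_extractor",
    "family_of",
    "write_feature_table",
    "read_feature_table",
    "KNOWN_FAMILY_PREFIXES",
]

# Architecture lineages: an id maps to the first (longest-match) prefix it
# carries after normalization. resnext must precede resnet.
KNOWN_FAMILY_PREFIXES: tuple[str, ...] = (
    "resnext",
    "resnet",
    "densenet",
    "vgg",
    "alexnet",
    "inception",
    "shufflenet",
    "mobilenet",
    "mnasnet",
)


def family_of(extractor_id: str) -> str:
    """Architecture family of an extractor id, stripping depth/size suffixes.

    ``"densenet121"`` and ``"DenseNet-169 feature"`` both map to
    ``"densenet"``.  Unknown ids fall back to the normalized id itself as a
    singleton family.
    """
    if not extractor_id:
        raise InvalidInputError("extractor_id must be non-empty")
    norm = re.sub(r"[^a-z0-9]", "", extractor_id.lower())
    norm = re.sub(r"feature$", "", norm)
    for prefix in KNOWN_FAMILY_PREFIXES:
        if norm.startswith(prefix):
            return prefix
    # singleton family: strip trailing version/depth digits so e.g. toy ids
    # with numeric suffixes still group by stem
    stem = re.sub(r"[v]?\d+$", "", norm)
    return stem or norm


@dataclass
class FeatureTable:
    """Aligned feature matrix with extractor provenance."""

    values: np.ndarray
    extractor_id: str
    family: str
    sample_ids: list
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise InvalidInputError("feature values must be a 2-D matrix")
        n = self.values.shape[0]
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise InvalidInputError("sample_ids and labels must align with rows")
        if self.values.shape[1] < 1:
            raise InvalidInputError("feature dimension must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("feature values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def rows_for(self, ids: list) -> tuple[np.ndarray, np.ndarray]:
        """(X, y) restricted to the given sample ids, in the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[s] for s in ids]
        except KeyError as exc:
            raise InvalidInputError(f"unknown sample id {exc.args[0]!r}") from exc
        return self.values[rows], self.labels[rows]

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.extractor_id == other.extractor_id
            and self.family == other.family
            and list(self.sample_ids) == list(other.sample_ids)
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class ExtractorSpec:
    """Recipe for one deterministic feature extractor.

    ``input_size`` is enforced when set (backbone-style extractors have fixed
    input geometry); the toy extractors accept any image size when it is None.
    ``dim`` is the output dimension where the kind needs one (histogram bins,
    block grid cells, projection width).
    """

    extractor_id: str
    kind: str = "toy_histogram"
    family: str | None = None
    input_size: tuple[int, int] | None = None
    dim: int = 16
    seed: int = 0

    def resolved_family(self) -> str:
        return self.family if self.family is not None else family_of(self.extractor_id)


def _toy_histogram(spec: ExtractorSpec, images: list[np.ndarray]) -> np.ndarray:
    bins = spec.dim
    rows = []
    for im in images:
        lo, hi = float(im.min()), float(im.max())
        if hi <= lo:
            hi = lo + 1.0
        h, _ = np.histogram(im, bins=bins, range=(lo, hi))
        rows.append(h / im.size)
    return np.asarray(rows, dtype=float)


def _toy_blockmean(spec: ExtractorSpec, images: list[np.ndarray]) -> np.ndarray:
    g = max(int(round(np.sqrt(spec.dim))), 1)
    rows = []
    for im in images:
        blocks = [
            float(np.mean(colchunk))
            for rowchunk in np.array_split(im, g, axis=0)
            for colchunk in np.array_split(rowchunk, g, axis=1)
        ]
        rows.append(blocks)
    return np.asarray(rows, dtype=float)


def _toy_randproj(spec: ExtractorSpec, images: list[np.ndarray]) -> np.ndarray:
    if spec.input_size is None:
        raise InvalidInputError("toy_randproj requires a fixed input_size")
    d_in = spec.input_size[0] * spec.input_size[1]
    rng = np.random.default_rng(spec.seed)
    proj = rng.standard_normal((d_in, spec.dim)) / np.sqrt(d_in)
    flat = np.stack([np.asarray(im, dtype=float).ravel() for im in images])
    return flat @ proj


_EXTRACTOR_KINDS: dict[str, Callable[[ExtractorSpec, list[np.ndarray]], np.ndarray]] = {
    "toy_histogram": _toy_histogram,
    "toy_blockmean": _toy_blockmean,
    "toy_randproj": _toy_randproj,
}


def register_extractor(kind: str, fn: Callable[[ExtractorSpec, list[np.ndarray]], np.ndarray]) -> None:
    """Register an extractor kind (e.g. a frozen-backbone adapter)."""
    _EXTRACTOR_KINDS[kind] = fn


def extract_features(
    spec: ExtractorSpec, images: list[np.ndarray], ids: list, labels: list
) -> FeatureTable:
    """Run one extractor over a list of images, one feature row per image."""
    if len(images) == 0:
        raise InvalidInputError("no images given")
    if len(ids) != len(images) or len(labels) != len(images):
        raise InvalidInputError("ids and labels must align with images")
    if spec.input_size is not None:
        for i, im in enumerate(images):
            if tuple(np.asarray(im).shape) != tuple(spec.input_size):
                raise InvalidInputError(
                    f"image {ids[i]!r} has shape {np.asarray(im).shape}, "
                    f"extractor expects {spec.input_size}"
                )
    try:
        fn = _EXTRACTOR_KINDS[spec.kind]
    except KeyError as exc:
        raise InvalidInputError(f"unknown extractor kind {spec.kind!r}") from exc
    values = fn(spec, [np.asarray(im, dtype=float) for im in images])
    return FeatureTable(
        values=values,
        extractor_id=spec.extractor_id,
        family=spec.resolved_family(),
        sample_ids=list(ids),
        labels=np.asarray(labels),
    )


def zscore_table(table: FeatureTable, eps: float = 1e-12) -> FeatureTable:
    """Per-feature z-scoring of a table (off by default everywhere).

    Constant features map to zero rather than dividing by zero.
    """
    mu = table.values.mean(axis=0)
    sd = table.values.std(axis=0)
    scaled = (table.values - mu) / np.where(sd < eps, 1.0, sd)
    return FeatureTable(
        values=scaled,
        extractor_id=table.extractor_id,
        family=table.family,
        sample_ids=list(table.sample_ids),
        labels=table.labels.copy(),
    )


# ---------------------------------------------------------------------------
# persistence: CSV (text, metadata in comment header) and HDF5 (large d)
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a table to ``.csv`` (text) or ``.h5``/``.hdf5`` (binary)."""
    path = Path(path)
    if path.suffix == ".csv":
        with open(path, "w") as fh:
            fh.write(f"# extractor_id={table.extractor_id}\n")
            fh.write(f"# family={table.family}\n")
            fh.write(f"# dim={table.dim}\n")
            df = pd.DataFrame(table.values, columns=[f"f{i}" for i in range(table.dim)])
            df.insert(0, "sample_id", table.sample_ids)
            df.insert(1, "label", table.labels)
            df.to_csv(fh, index=False, float_format="%.17g")
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("values", data=table.values)
            fh.create_dataset(
                "sample_ids", data=np.asarray([str(s) for s in table.sample_ids], dtype="S")
            )
            fh.create_dataset("labels", data=np.asarray([str(x) for x in table.labels], dtype="S"))
            fh.attrs["extractor_id"] = table.extractor_id
            fh.attrs["family"] = table.family
    else:
        raise InvalidInputError(f"unsupported feature-table extension: {path.suffix!r}")


def _maybe_int_labels(raw: list[str]) -> np.ndarray:
    try:
        return np.asarray([int(x) for x in raw])
    except ValueError:
        return np.asarray(raw)


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a table written by :func:`write_feature_table`; exact round-trip."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such feature table: {path}")
    if path.suffix == ".csv":
        meta: dict[str, str] = {}
        body = io.StringIO()
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key.strip()] = val.strip()
                else:
                    body.write(line)
        for required in ("extractor_id", "family"):
            if required not in meta:
                raise DataError(f"feature table {path} is missing metadata field {required!r}")
        body.seek(0)
        df = pd.read_csv(body, dtype={"sample_id": str}, float_precision="round_trip")
        if "sample_id" not in df.columns or "label" not in df.columns:
            raise DataError(f"feature table {path} is missing the sample_id/label columns")
        feat_cols = [c for c in df.columns if c not in ("sample_id", "label")]
        return FeatureTable(
            values=df[feat_cols].to_numpy(dtype=float),
            extractor_id=meta["extractor_id"],
            family=meta["family"],
            sample_ids=df["sample_id"].tolist(),
            labels=_maybe_int_labels([str(x) for x in df["label"].tolist()]),
        )
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            if "extractor_id" not in fh.attrs:
                raise DataError(f"feature table {path} is missing metadata field 'extractor_id'")
            return FeatureTable(
                values=np.asarray(fh["values"], dtype=float),
                extractor_id=str(fh.attrs["extractor_id"]),
                family=str(fh.attrs["family"]),
                sample_ids=[s.decode() for s in fh["sample_ids"][()]],
                labels=_maybe_int_labels([s.decode() for s in fh["labels"][()]]),
            )
    raise InvalidInputError(f"unsupported feature-table extension: {path.suffix!r}")
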