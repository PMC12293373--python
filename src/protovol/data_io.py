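"""Volumes, label manifests and deterministic preprocessing.

Axis convention throughout the package: ``(depth, height, width)`` with depth
as the slice axis, matching the per-exam array layout of MRNet-style knee MRI
exports (one 3D array per exam-series, slices stacked first).

A manifest is a CSV with header columns ``exam_id, patient_id, label, path``;
labels are strictly binary (0 = negative/intact, 1 = positive/injured).
Volumes load from NIfTI-1 (``.nii``/``.nii.gz``, via nibabel) or single 3D
``.npy`` arrays.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, FormatError

MANIFEST_COLUMNS = ("exam_id", "patient_id", "label", "path")


@dataclass
class Volume:
    """One 3D grayscale series of one exam.

    ``voxels`` has shape (depth, height, width); intensities are arbitrary
    reals and must be finite.
    """

    voxels: np.ndarray
    exam_id: str
    patient_id: str
    series_label: str = "sagittal"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise FormatError(
                f"volume {self.exam_id!r}: expected 3 dimensions, "
                f"got {self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise DataError(f"volume {self.exam_id!r} contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]


@dataclass
class LabeledSample:
    """A volume with its binary label; the volume may be lazily loadable."""

    label: int
    exam_id: str
    patient_id: str
    _volume: Volume | None = None
    _loader: Callable[[], Volume] | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise DataError(
                f"sample {self.exam_id!r}: label must be 0 or 1, got {self.label!r}")

    @property
    def volume(self) -> Volume:
        if self._volume is None:
            if self._loader is None:
                raise DataError(f"sample {self.exam_id!r} has no volume attached")
            self._volume = self._loader()
        return self._volume


class SampleSet:
    """An ordered collection of labeled samples with unique exam ids."""

    def __init__(self, samples: Sequence[LabeledSample], name: str = ""):
        seen: set[str] = set()
        for s in samples:
            if s.exam_id in seen:
                raise DataError(f"duplicate exam_id {s.exam_id!r} in sample set")
            seen.add(s.exam_id)
        self.samples = list(samples)
        self.name = name

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[LabeledSample]:
        return iter(self.samples)

    def __getitem__(self, i: int) -> LabeledSample:
        return self.samples[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    @property
    def patient_ids(self) -> list[str]:
        return [s.patient_id for s in self.samples]

    @property
    def exam_ids(self) -> list[str]:
        return [s.exam_id for s in self.samples]

    def by_label(self, label: int) -> "SampleSet":
        return SampleSet([s for s in self.samples if s.label == label],
                         name=f"{self.name}/label{label}")

    def class_counts(self) -> dict[int, int]:
        labels = self.labels
        return {0: int((labels == 0).sum()), 1: int((labels == 1).sum())}


@dataclass(frozen=True)
class PreprocessSpec:
    """Deterministic mapping of an arbitrary volume to a fixed-shape tensor.

    ``depth_policy`` applies to every axis whose size differs from the target:
    ``center_crop_pad`` symmetrically crops or zero-pads; ``linear_resample``
    interpolates along each axis. ``zscore`` normalises each volume to zero
    mean and unit population SD (a constant volume maps to all-zeros).
    """

    target_shape: tuple[int, int, int] = (16, 32, 32)
    normalization: Literal["zscore", "minmax", "none"] = "zscore"
    depth_policy: Literal["center_crop_pad", "linear_resample"] = "center_crop_pad"

    def __post_init__(self) -> None:
        if len(self.target_shape) != 3 or any(t < 1 for t in self.target_shape):
            raise ConfigurationError(
                f"target_shape must be three positive ints, got {self.target_shape}")
        if self.normalization not in ("zscore", "minmax", "none"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")
        if self.depth_policy not in ("center_crop_pad", "linear_resample"):
            raise ConfigurationError(f"unknown depth_policy {self.depth_policy!r}")


def read_manifest(path: str | Path,
                  schema: dict[str, str] | None = None,
                  name: str | None = None) -> SampleSet:
    """Read a label manifest CSV into a :class:`SampleSet`.

    ``schema`` optionally maps canonical column names (``exam_id``,
    ``patient_id``, ``label``, ``path``) to the file's actual column names.
    Volumes are attached lazily: reading the manifest touches no volume file.
    Relative volume paths resolve against the manifest's directory.
    """
    path = Path(path)
    schema = schema or {}
    colmap = {c: schema.get(c, c) for c in MANIFEST_COLUMNS}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ConfigurationError(
            f"manifest {path} missing column(s) {missing}; found {list(df.columns)}")
    samples = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        rec = {c: getattr(row, colmap[c]) for c in MANIFEST_COLUMNS}
        if rec["label"] not in ("0", "1"):
            raise DataError(
                f"manifest {path} row {idx}: label must be 0 or 1, "
                f"got {rec['label']!r}")
        vpath = Path(rec["path"])
        if not vpath.is_absolute():
            vpath = path.parent / vpath
        loader = _make_loader(vpath, rec["exam_id"], rec["patient_id"])
        samples.append(LabeledSample(label=int(rec["label"]),
                                     exam_id=rec["exam_id"],
                                     patient_id=rec["patient_id"],
                                     _loader=loader))
    return SampleSet(samples, name=name or path.stem)


def write_manifest(sample_set: SampleSet, path: str | Path,
                   paths: Sequence[str] | None = None) -> None:
    """Write a manifest CSV; ``paths`` supplies the volume path column."""
    if paths is None:
        paths = ["" for _ in sample_set]
    pd.DataFrame({
        "exam_id": sample_set.exam_ids,
        "patient_id": sample_set.patient_ids,
        "label": sample_set.labels,
        "path": list(paths),
    }).to_csv(path, index=False)


def _make_loader(vpath: Path, exam_id: str, patient_id: str) -> Callable[[], Volume]:
    def load() -> Volume:
        fmt = "nifti" if "".join(vpath.suffixes).endswith((".nii", ".nii.gz")) \
            else "npy_stack"
        v = load_volume(vpath, fmt)
        return dataclasses.replace(v, exam_id=exam_id, patient_id=patient_id)
    return load


def load_volume(path: str | Path, format: Literal["nifti", "npy_stack"] = "npy_stack",
                exam_id: str = "", patient_id: str = "") -> Volume:
    """Load one volume file.

    Arrays are returned unmodified in (slice, row, column) order; a 2D array
    is promoted to depth 1. Anything with more than 3 dimensions is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"volume file not found: {path}")
    if format == "nifti":
        import nibabel as nib
        arr = np.asanyarray(nib.load(path).dataobj)
    elif format == "npy_stack":
        try:
            arr = np.load(path, allow_pickle=False)
        except ValueError as e:
            raise FormatError(f"{path}: not a plain numeric array ({e})") from e
    else:
        raise ConfigurationError(f"unknown volume format {format!r}")
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path}: non-numeric payload of dtype {arr.dtype}")
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 2D or 3D array, got {arr.ndim}D")
    return Volume(voxels=arr.astype(np.float64),
                  exam_id=exam_id or path.stem, patient_id=patient_id)


def _crop_pad_axis(arr: np.ndarray, axis: int, target: int) -> np.ndarray:
    size = arr.shape[axis]
    if size == target:
        return arr
    if size > target:
        lo = (size - target) // 2
        sl = [slice(None)] * arr.ndim
        sl[axis] = slice(lo, lo + target)
        return arr[tuple(sl)]
    before = (target - size) // 2
    after = target - size - before
    pad = [(0, 0)] * arr.ndim
    pad[axis] = (before, after)
    return np.pad(arr, pad)


def _resample_axis(arr: np.ndarray, axis: int, target: int) -> np.ndarray:
    size = arr.shape[axis]
    if size == target:
        return arr
    old = np.arange(size, dtype=float)
    new = np.linspace(0.0, size - 1.0, target)
    moved = np.moveaxis(arr, axis, 0)
    flat = moved.reshape(size, -1)
    out = np.empty((target, flat.shape[1]))
    for j in range(flat.shape[1]):
        out[:, j] = np.interp(new, old, flat[:, j])
    return np.moveaxis(out.reshape((target,) + moved.shape[1:]), 0, axis)


def preprocess(v: Volume, spec: PreprocessSpec) -> Volume:
    """Reshape and normalize a volume to ``spec.target_shape``.

    Deterministic; idempotent on input that already conforms.
    """
    arr = v.voxels
    reshaper = (_crop_pad_axis if spec.depth_policy == "center_crop_pad"
                else _resample_axis)
    for axis, target in enumerate(spec.target_shape):
        arr = reshaper(arr, axis, target)
    if spec.normalization == "zscore":
        sd = arr.std()
        arr = (arr - arr.mean()) / sd if sd > 0 else np.zeros_like(arr)
    elif spec.normalization == "minmax":
        lo, hi = arr.min(), arr.max()
        arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    return Volume(voxels=arr, exam_id=v.exam_id, patient_id=v.patient_id,
                  series_label=v.series_label)
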