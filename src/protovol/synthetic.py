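"""Synthetic two-class 3D volume datasets with known ground truth.

The generator emulates the shape of an MRNet-style knee-MRI task at desk
scale: each exam is a small grayscale volume of Gaussian background noise,
and positive exams additionally carry a localized lesion-like intensity
elevation. Two lesion geometries stand in for two related-but-distinct
injury tasks, so transfer experiments (pre-train on one geometry, few-shot
on the other) are testable offline:

- ``ellipsoid_A`` — a compact anisotropic ellipsoid near the volume centre
  (an ACL-tear-like focal lesion);
- ``band_B`` — a through-plane slab of elevated slices (a meniscus-like
  extended lesion).

Exams group under patients; all exams of one patient share the patient's
class, so patient-level splits carry real leakage risk if violated. All
randomness flows from one seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .data_io import LabeledSample, SampleSet, Volume, write_manifest
from .errors import ConfigurationError, DataError


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated dataset.

    ``lesion_contrast`` is the added intensity inside the lesion in units of
    the background noise SD; ``lesion_radius_voxels`` sets the in-plane
    semi-axis of the ellipsoid (through-plane semi-axis is half of it) and
    the slab half-thickness of the band. Lesion centres jitter by at most
    10% of each dimension so the task stays learnable by a tiny encoder.
    """

    n_patients: int = 80
    exams_per_patient: int = 1
    volume_shape: tuple[int, int, int] = (16, 32, 32)
    lesion_contrast: float = 3.0
    lesion_radius_voxels: float = 5.0
    lesion_kind: Literal["ellipsoid_A", "band_B"] = "ellipsoid_A"
    noise_sd: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.exams_per_patient < 1:
            raise ConfigurationError("n_patients and exams_per_patient must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.lesion_contrast < 0:
            raise ConfigurationError("lesion_contrast must be >= 0")
        if not 0 < self.class_balance < 1:
            raise ConfigurationError("class_balance must lie in (0, 1)")
        if self.lesion_radius_voxels <= 0:
            raise ConfigurationError("lesion_radius_voxels must be > 0")
        d, h, w = self.volume_shape
        r = self.lesion_radius_voxels
        if 2 * r >= min(h, w) or r >= d:
            raise ConfigurationError(
                f"lesion radius {r} does not fit inside volume {self.volume_shape}")


def lesion_mask(cfg: SyntheticConfig, center: tuple[float, float, float]
                ) -> np.ndarray:
    """Boolean ground-truth lesion mask for a lesion centred at ``center``."""
    d, h, w = cfg.volume_shape
    zz, yy, xx = np.mgrid[0:d, 0:h, 0:w].astype(float)
    r = cfg.lesion_radius_voxels
    cz, cy, cx = center
    if cfg.lesion_kind == "ellipsoid_A":
        # anisotropic: through-plane semi-axis r/2, in-plane r
        return ((zz - cz) ** 2 / (r / 2) ** 2
                + (yy - cy) ** 2 / r ** 2
                + (xx - cx) ** 2 / r ** 2) <= 1.0
    if cfg.lesion_kind == "band_B":
        return np.abs(zz - cz) <= r / 2
    raise ConfigurationError(f"unknown lesion_kind {cfg.lesion_kind!r}")


def _lesion_center(cfg: SyntheticConfig, rng: np.random.Generator
                   ) -> tuple[float, float, float]:
    d, h, w = cfg.volume_shape
    return tuple(dim / 2.0 + rng.uniform(-0.1, 0.1) * dim for dim in (d, h, w))


def simulate_dataset(cfg: SyntheticConfig, with_masks: bool = False
                     ) -> SampleSet | tuple[SampleSet, list[np.ndarray | None]]:
    """Generate ``n_patients × exams_per_patient`` labeled volumes.

    Positive volumes are ``N(0, noise_sd²)`` noise plus
    ``lesion_contrast × noise_sd`` added inside the lesion mask; negatives are
    noise only. Identical config (including seed) gives bit-identical output.
    With ``with_masks=True`` also returns each sample's ground-truth lesion
    mask (``None`` for negatives), for oracle classifiers in tests.
    """
    rng = np.random.default_rng(cfg.seed)
    n_pos_patients = int(round(cfg.n_patients * cfg.class_balance))
    if cfg.n_patients >= 2:
        n_pos_patients = min(max(n_pos_patients, 1), cfg.n_patients - 1)
    samples: list[LabeledSample] = []
    masks: list[np.ndarray | None] = []
    for p in range(cfg.n_patients):
        label = 1 if p < n_pos_patients else 0
        patient_id = f"P{p:04d}"
        for e in range(cfg.exams_per_patient):
            vox = rng.normal(0.0, cfg.noise_sd, size=cfg.volume_shape)
            mask = None
            if label == 1:
                mask = lesion_mask(cfg, _lesion_center(cfg, rng))
                vox = vox + cfg.lesion_contrast * cfg.noise_sd * mask
            exam_id = f"{patient_id}E{e:02d}"
            samples.append(LabeledSample(
                label=label, exam_id=exam_id, patient_id=patient_id,
                _volume=Volume(vox, exam_id=exam_id, patient_id=patient_id,
                               series_label="synthetic")))
            masks.append(mask)
    sset = SampleSet(samples, name=f"synthetic-{cfg.lesion_kind}-seed{cfg.seed}")
    return (sset, masks) if with_masks else sset


def split_by_patient(s: SampleSet, fractions: tuple[float, float],
                     seed: int) -> tuple[SampleSet, SampleSet]:
    """Partition a sample set into two patient-disjoint subsets.

    Patients are shuffled with the given seed and assigned so the first
    output receives ``round(fractions[0] × n_patients)`` patients (at least
    one patient on each side). Every exam of a patient lands on one side.
    """
    f_train, f_test = fractions
    if f_train <= 0 or f_test <= 0 or abs(f_train + f_test - 1.0) > 1e-9:
        raise ConfigurationError(
            f"fractions must be positive and sum to 1, got {fractions}")
    patients = sorted(set(s.patient_ids))
    if len(patients) < 2:
        raise DataError(f"need >= 2 patients to split, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_train = int(round(f_train * len(patients)))
    n_train = min(max(n_train, 1), len(patients) - 1)
    train_patients = {patients[i] for i in order[:n_train]}
    train = [x for x in s if x.patient_id in train_patients]
    test = [x for x in s if x.patient_id not in train_patients]
    return (SampleSet(train, name=f"{s.name}/train"),
            SampleSet(test, name=f"{s.name}/test"))


def simulate_to_disk(cfg: SyntheticConfig, out_dir: str | Path) -> Path:
    """Write a simulated dataset as .npy volumes plus a manifest CSV.

    Returns the manifest path; the manifest is readable by
    :func:`protovol.data_io.read_manifest`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sset = simulate_dataset(cfg)
    paths = []
    for sample in sset:
        rel = f"{sample.exam_id}.npy"
        np.save(out_dir / rel, sample.volume.voxels)
        paths.append(rel)
    manifest = out_dir / "manifest.csv"
    write_manifest(sset, manifest, paths=paths)
    return manifest
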