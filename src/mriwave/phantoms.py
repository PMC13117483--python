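"""Synthetic brain-like phantom volumes, preprocessing, and leakage-free splits.

The phantoms stand in for high-resolution T1-weighted brain volumes: a small
number of piecewise-near-constant tissue classes (CSF/GM/WM-like) arranged as
nested smooth ellipsoidal blobs inside an exactly-zero background, modulated
by a smooth low-frequency bias field, plus additive Gaussian noise.  Class
mean intensities live on a raw scale of roughly 0-300 so that the raw-unit
zipper noise intensities (15-50) are a meaningful relative perturbation.

Preprocessing follows the training pipeline: per-volume z-score
normalization, 2D slicing along a chosen axis, and subject-level stratified
train/validation splitting (all slices of a subject land in exactly one
partition).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import nibabel as nib

MIN_SIDE = 32  # network minimum slice side

#: Raw-intensity class means used for the nested tissue shells, ordered from
#: the outermost shell inward (CSF-like bright rim, GM, WM, then extras).
TISSUE_MEANS = (90.0, 160.0, 250.0, 120.0, 200.0, 60.0, 280.0, 140.0)


@dataclass
class Volume:
    """A real-valued 3D image with subject identity and provenance."""

    voxels: np.ndarray
    subject_id: str
    axis_labels: tuple = ("z", "y", "x")
    provenance: str = "clean"  # "clean" | "corrupted"
    applied_specs: list = field(default_factory=list)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"Volume expects a 3D array, got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("Volume contains non-finite values")
        if self.provenance not in ("clean", "corrupted"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def with_voxels(self, voxels, provenance=None, extra_specs=()) -> "Volume":
        return Volume(
            voxels=voxels,
            subject_id=self.subject_id,
            axis_labels=self.axis_labels,
            provenance=provenance or self.provenance,
            applied_specs=list(self.applied_specs) + list(extra_specs),
        )

    def to_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.voxels.astype(np.float32), affine=np.eye(4)), str(path))

    @classmethod
    def from_nifti(cls, path, subject_id: str, **kw) -> "Volume":
        img = nib.load(str(path))
        return cls(voxels=np.asarray(img.dataobj, dtype=float), subject_id=subject_id, **kw)


@dataclass
class SubjectSplit:
    """Subject-level train/validation partition with per-subject strata."""

    train_ids: set
    val_ids: set
    stratum_of: dict

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.val_ids)
        if overlap:
            raise ValueError(f"subjects in both partitions: {sorted(overlap)}")

    def partition_of(self, subject_id: str) -> str:
        if subject_id in self.train_ids:
            return "train"
        if subject_id in self.val_ids:
            return "val"
        raise KeyError(subject_id)


def _smooth_field(rng: np.random.Generator, shape, smoothness: float) -> np.ndarray:
    """Smooth unit-scale random field built from low-order 3D cosine modes."""
    coords = [np.linspace(0.0, 1.0, s) for s in shape]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    out = np.zeros(shape)
    n_modes = 4
    for _ in range(n_modes):
        f = rng.uniform(0.5, smoothness)
        ph = rng.uniform(0, 2 * np.pi, size=3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        out += rng.normal() * np.cos(2 * np.pi * f * (d[0] * zz + d[1] * yy + d[2] * xx) + ph[0])
    sd = out.std()
    return out / sd if sd > 0 else out


def generate_phantom_volume(
    seed: int,
    shape=(64, 64, 64),
    n_tissues: int = 3,
    noise_sd: float = 4.0,
    bias_amp: float = 0.1,
) -> Volume:
    """Deterministic brain-like phantom: nested ellipsoidal tissue shells.

    Parameters
    ----------
    seed : int
        Sole source of randomness; identical seeds give bit-identical volumes.
    shape : triple of int, each >= 32
        Volume dimensions (z, y, x).
    n_tissues : int in [2, 8]
        Number of distinct tissue intensity classes (plus zero background).
    noise_sd : float >= 0
        Additive Gaussian noise standard deviation, raw intensity units.
    bias_amp : float >= 0
        Relative amplitude of the smooth multiplicative bias field.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise ValueError("shape must be a triple")
    if min(shape) < MIN_SIDE:
        raise ValueError(
            f"every dimension must be >= {MIN_SIDE} (network minimum slice side); got {shape}"
        )
    if not 2 <= n_tissues <= len(TISSUE_MEANS):
        raise ValueError(f"n_tissues must be in [2, {len(TISSUE_MEANS)}], got {n_tissues}")
    if noise_sd < 0 or bias_amp < 0:
        raise ValueError("noise_sd and bias_amp must be non-negative")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9E3779B9]))
    zz, yy, xx = np.meshgrid(*[np.linspace(-1.0, 1.0, s) for s in shape], indexing="ij")

    # Head support: one big ellipsoid, slightly randomized, with a wavy
    # boundary so edges are not axis-aligned everywhere.
    semi = rng.uniform(0.75, 0.9, size=3)
    wobble = 0.04 * _smooth_field(rng, shape, smoothness=1.5)
    r2 = (zz / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (xx / semi[2]) ** 2
    head = r2 + wobble <= 1.0

    raw = np.zeros(shape)
    # Nested shells: each successive tissue occupies a smaller deformed
    # ellipsoid; later shells overwrite earlier ones, yielding sharp
    # high-contrast boundaries (piecewise constant intensities).
    scale = 1.0
    support = head
    for t in range(n_tissues):
        raw[support] = TISSUE_MEANS[t]
        scale *= rng.uniform(0.6, 0.8)
        center = rng.uniform(-0.15, 0.15, size=3)
        semi_t = semi * scale * rng.uniform(0.9, 1.1, size=3)
        wob = 0.05 * _smooth_field(rng, shape, smoothness=2.0)
        r2t = (
            ((zz - center[0]) / semi_t[0]) ** 2
            + ((yy - center[1]) / semi_t[1]) ** 2
            + ((xx - center[2]) / semi_t[2]) ** 2
        )
        support = head & (r2t + wob <= 1.0)

    if bias_amp > 0:
        bias = 1.0 + bias_amp * _smooth_field(rng, shape, smoothness=1.0)
        raw = raw * np.clip(bias, 0.1, None)
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd, size=shape)

    return Volume(voxels=raw, subject_id=f"sub-{int(seed):06d}")


def zscore_normalize(v: Volume) -> Volume:
    """Per-volume standardization Z = (X - mu) / sigma over all voxels."""
    mu = float(v.voxels.mean())
    sd = float(v.voxels.std())
    if sd == 0:
        raise ValueError("cannot z-score a constant volume (sigma = 0)")
    return v.with_voxels((v.voxels - mu) / sd)


def slice_volume(v: Volume, axis: int = 0) -> list[np.ndarray]:
    """Split a volume into ordered 2D slices along ``axis`` (0, 1 or 2)."""
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    vox = v.voxels if isinstance(v, Volume) else np.asarray(v, dtype=float)
    in_plane = tuple(s for i, s in enumerate(vox.shape) if i != axis)
    if min(in_plane) < MIN_SIDE:
        raise ValueError(f"in-plane dimensions {in_plane} below the {MIN_SIDE}-pixel minimum")
    return [np.take(vox, i, axis=axis) for i in range(vox.shape[axis])]

def stack_slices(slices, axis: int = 0) -> np.ndarray:
    """Inverse of :func:`slice_volume` on the voxel array."""
    return np.stack(slices, axis=axis)


def split_subjects(subject_ids, strata: dict, train_frac: float, seed: int) -> SubjectSplit:
    """Stratified subject-level split; per-stratum sizes are round(frac*n).

    Every stratum must contain at least 2 subjects so both partitions are
    inhabited per stratum.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    subject_ids = list(subject_ids)
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids")
    missing = [s for s in subject_ids if s not in strata]
    if missing:
        raise ValueError(f"subjects without a stratum label: {missing}")

    by_stratum: dict = {}
    for s in subject_ids:
        by_stratum.setdefault(strata[s], []).append(s)
    for label, members in by_stratum.items():
        if len(members) < 2:
            raise ValueError(
                f"stratum {label!r} has {len(members)} subject(s); need at least 2 "
                "so both partitions receive one — add subjects or merge strata"
            )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    train, val = set(), set()
    for label in sorted(by_stratum, key=str):
        members = sorted(by_stratum[label])
        perm = rng.permutation(len(members))
        n_train = int(round(train_frac * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)  # both sides non-empty
        for idx in perm[:n_train]:
            train.add(members[idx])
        for idx in perm[n_train:]:
            val.add(members[idx])
    return SubjectSplit(train_ids=train, val_ids=val, stratum_of={s: strata[s] for s in subject_ids})
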