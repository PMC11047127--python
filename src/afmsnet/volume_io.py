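"""NIfTI volume I/O and preprocessing transforms.

Volumes are held channel-last as (H, W, D, C) float arrays with an
optional (H, W, D) integer label map, per-axis voxel spacing in mm and
an opaque affine carried through unchanged.  All transforms are pure:
they return new records and never mutate their input.

The preprocessing toolbox covers: central cropping, resampling
(trilinear for images, nearest-neighbour for labels), per-channel
z-score normalization over the nonzero (brain) support, isotropic
Gaussian smoothing, modality fusion + one-hot label encoding with
raw-label remapping, filtering of volumes with under 1 % foreground,
and seeded train/validation/test splitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage


class IOValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Record
# ---------------------------------------------------------------------------

@dataclass
class VolumeRecord:
    """One volume: image (H, W, D, C), optional labels, spacing, affine."""

    image: np.ndarray
    labels: np.ndarray | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    identifier: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.ndim == 3:
            self.image = self.image[..., None]
        if self.image.ndim != 4:
            raise IOValidationError("image must be 3-D or 4-D (H, W, D[, C])")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.image.shape[:3]:
                raise IOValidationError(
                    f"labels {self.labels.shape} not congruent with image "
                    f"{self.image.shape[:3]}")
        if any(s <= 0 for s in self.spacing):
            raise IOValidationError("spacing must be positive per axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.image.shape[:3]

    @property
    def n_channels(self) -> int:
        return self.image.shape[3]

    def foreground_fraction(self) -> float:
        if self.labels is None:
            raise IOValidationError("record has no labels")
        return float(np.count_nonzero(self.labels)) / self.labels.size


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(image_path, label_path=None, identifier: str = "") -> VolumeRecord:
    """Load a 3-D/4-D NIfTI image (and optional label map)."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise IOValidationError(
            f"{image_path}: expected 3-D or 4-D data, got {data.ndim}-D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    labels = None
    if label_path is not None:
        lab = nib.load(str(label_path))
        labels = np.asarray(lab.dataobj).astype(np.int64)
    return VolumeRecord(image=data, labels=labels, spacing=spacing,
                        affine=np.asarray(img.affine),
                        identifier=identifier or str(image_path))


def write_volume(record: VolumeRecord, image_path, label_path=None) -> None:
    """Write a record back to NIfTI; C=1 images are squeezed to 3-D."""
    affine = record.affine if record.affine is not None else _spacing_affine(record.spacing)
    data = record.image
    if data.shape[3] == 1:
        data = data[..., 0]
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(record.spacing[:3] if data.ndim == 3
                         else (*record.spacing, 1.0))
    nib.save(img, str(image_path))
    if label_path is not None:
        if record.labels is None:
            raise IOValidationError("record has no labels to write")
        lab = nib.Nifti1Image(record.labels.astype(np.int16), affine)
        lab.header.set_zooms(record.spacing)
        nib.save(lab, str(label_path))


def _spacing_affine(spacing) -> np.ndarray:
    return np.diag([*spacing, 1.0])


# ---------------------------------------------------------------------------
# Spatial transforms
# ---------------------------------------------------------------------------

def central_crop(record: VolumeRecord, target_shape) -> VolumeRecord:
    """Centered crop; an odd size difference drops the extra high-index voxel.

    Windows are half-open [lo, lo + target) with lo = (source - target) // 2.
    """
    target = tuple(int(t) for t in target_shape)
    src = record.shape
    if any(t > s for t, s in zip(target, src)):
        raise IOValidationError(f"crop target {target} exceeds source {src}")
    lo = [(s - t) // 2 for s, t in zip(src, target)]
    sl = tuple(slice(l, l + t) for l, t in zip(lo, target))
    labels = record.labels[sl] if record.labels is not None else None
    return replace(record, image=record.image[sl], labels=labels)


def pad_to(record: VolumeRecord, target_shape, value: float = 0.0) -> VolumeRecord:
    """Symmetric zero-pad to ``target_shape`` (extra voxel on the high side)."""
    target = tuple(int(t) for t in target_shape)
    src = record.shape
    if any(t < s for t, s in zip(target, src)):
        raise IOValidationError(f"pad target {target} smaller than source {src}")
    lo = [(t - s) // 2 for s, t in zip(src, target)]
    pads = [(l, t - s - l) for l, s, t in zip(lo, src, target)]
    image = np.pad(record.image, pads + [(0, 0)], constant_values=value)
    labels = (np.pad(record.labels, pads, constant_values=0)
              if record.labels is not None else None)
    return replace(record, image=image, labels=labels)


def resample(record: VolumeRecord, target_spacing=None,
             target_shape=None) -> VolumeRecord:
    """Resample to a new spacing or shape.

    Images are interpolated trilinearly, label maps nearest-neighbour.
    Output voxel i samples the input at i * (in - 1) / (out - 1)
    (endpoints aligned); the recorded spacing is updated accordingly.
    """
    if (target_spacing is None) == (target_shape is None):
        raise IOValidationError(
            "specify exactly one of target_spacing / target_shape")
    src = record.shape
    if target_spacing is not None:
        ts = np.asarray(target_spacing, dtype=float)
        if np.any(ts <= 0):
            raise IOValidationError("target spacing must be positive")
        out_shape = tuple(max(1, int(round(s * sp / t)))
                          for s, sp, t in zip(src, record.spacing, ts))
        new_spacing = tuple(float(t) for t in ts)
    else:
        out_shape = tuple(int(t) for t in target_shape)
        if any(t < 1 for t in out_shape):
            raise IOValidationError("target shape must be positive")
        new_spacing = tuple(sp * s / t
                            for sp, s, t in zip(record.spacing, src, out_shape))
    if out_shape == src:
        return replace(record, spacing=new_spacing)
    grids = [np.linspace(0.0, s - 1.0, t) if t > 1 else np.array([(s - 1) / 2.0])
             for s, t in zip(src, out_shape)]
    coords = np.stack(np.meshgrid(*grids, indexing="ij"))
    image = np.stack(
        [ndimage.map_coordinates(record.image[..., c].astype(float), coords,
                                 order=1, mode="nearest")
         for c in range(record.n_channels)], axis=-1)
    labels = None
    if record.labels is not None:
        labels = ndimage.map_coordinates(record.labels, coords, order=0,
                                         mode="nearest").astype(record.labels.dtype)
    return replace(record, image=image, labels=labels, spacing=new_spacing)


# ---------------------------------------------------------------------------
# Intensity transforms
# ---------------------------------------------------------------------------

def normalize(record: VolumeRecord) -> VolumeRecord:
    """Per-channel z-score over the nonzero (brain) support.

    Background zeros stay zero, making the transform idempotent on the
    support.  A constant channel is zeroed with a warning.
    """
    image = record.image.astype(float).copy()
    for c in range(record.n_channels):
        ch = image[..., c]
        support = ch != 0
        if not support.any():
            warnings.warn(f"channel {c} is all zero; left unchanged", stacklevel=2)
            continue
        vals = ch[support]
        sd = vals.std()
        if sd == 0:
            warnings.warn(f"channel {c} is constant on its support; zeroed",
                          stacklevel=2)
            ch[support] = 0.0
            continue
        ch[support] = (vals - vals.mean()) / sd
    return replace(record, image=image)


def gaussian_smooth(record: VolumeRecord, sigma: float = 0.5) -> VolumeRecord:
    """Isotropic per-channel Gaussian filter (sigma in voxels); labels untouched."""
    if sigma < 0:
        raise IOValidationError("sigma must be >= 0")
    if sigma == 0:
        return replace(record)
    image = np.stack(
        [ndimage.gaussian_filter(record.image[..., c].astype(float), sigma)
         for c in range(record.n_channels)], axis=-1)
    return replace(record, image=image)


# ---------------------------------------------------------------------------
# Label handling
# ---------------------------------------------------------------------------

#: Raw brain-tumor labels are {0, 1, 2, 4}; the enhancing-tumor label 4
#: is remapped to the contiguous class index 3 for one-hot encoding.
DEFAULT_LABEL_REMAP = {0: 0, 1: 1, 2: 2, 4: 3}


def remap_labels(labels: np.ndarray, remap: dict[int, int]) -> np.ndarray:
    out = labels.copy()
    for raw, new in remap.items():
        out[labels == raw] = new
    return out


def inverse_remap_labels(labels: np.ndarray, remap: dict[int, int]) -> np.ndarray:
    inv = {v: k for k, v in remap.items()}
    return remap_labels(labels, inv)


def one_hot_and_fuse(modalities: list[VolumeRecord], labels: np.ndarray,
                     n_classes: int,
                     remap: dict[int, int] | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Stack modality images on the channel axis; one-hot encode labels.

    Modalities are concatenated in the declared order.  Raw labels are
    remapped to contiguous indices (default: 4 -> 3) before encoding.
    """
    if not modalities:
        raise IOValidationError("no modalities given")
    base = modalities[0].shape
    for m in modalities[1:]:
        if m.shape != base:
            raise IOValidationError(
                f"modality shapes differ: {m.shape} vs {base}")
    labels = np.asarray(labels)
    if labels.shape != base:
        raise IOValidationError(
            f"labels {labels.shape} not congruent with image {base}")
    image = np.concatenate([m.image for m in modalities], axis=-1)
    mapped = remap_labels(labels, remap if remap is not None else DEFAULT_LABEL_REMAP)
    if mapped.min() < 0 or mapped.max() >= n_classes:
        raise IOValidationError(
            f"remapped labels must lie in [0, {n_classes}), got "
            f"[{mapped.min()}, {mapped.max()}]")
    one_hot = np.eye(n_classes, dtype=np.float32)[mapped]
    return image, one_hot


def low_label_filter(records, fraction: float = 0.01):
    """Keep records whose foreground fraction is >= ``fraction``.

    A volume with under 1 % labelled voxels carries little training
    signal and is discarded; exactly at the boundary it is kept.
    """
    return [r for r in records if r.foreground_fraction() >= fraction]


# ---------------------------------------------------------------------------
# Dataset splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """Train/validation/test fractions (must sum to 1) plus a shuffle seed."""

    train: float = 0.8
    validation: float = 0.1
    test: float = 0.1
    seed: int = 0

    def __post_init__(self):
        fr = (self.train, self.validation, self.test)
        if any(f <= 0 for f in fr):
            raise IOValidationError("split fractions must be positive")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise IOValidationError("split fractions must sum to 1")


def dataset_split(ids, spec: SplitSpec) -> tuple[list, list, list]:
    """Seeded shuffle, then floor-sized partitions with the remainder to train."""
    ids = list(ids)
    if len(ids) < 3:
        raise IOValidationError("need at least 3 ids to split three ways")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n = len(ids)
    n_val = int(n * spec.validation)
    n_test = int(n * spec.test)
    n_train = n - n_val - n_test
    train = shuffled[:n_train]
    val = shuffled[n_train:n_train + n_val]
    test = shuffled[n_train + n_val:]
    return train, val, test
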