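"""Seeded 3-D lesion phantoms for end-to-end testing without clinical data.

A phantom emulates the statistical structure of multi-modal brain-lesion
MRI: a mostly-background volume (few-percent foreground), one to a few
ellipsoidal lesions of varying size and position, optionally with nested
class shells (whole > intermediate > core, mirroring nested tumor
sub-regions), multi-channel images with per-class mean contrast and
additive Gaussian noise.  Axis-aligned ellipsoids are used so lesion
volume has a closed form ((4/3) pi a b c), giving an analytic oracle for
foreground fractions.  An optional "lumpy" mode warps shapes through a
seeded smooth displacement field for more organic boundaries (at the
cost of the analytic volume).

It deliberately does not model MRI physics: no bias fields, no partial
volume, no anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume_io import VolumeRecord, write_volume


class PhantomSpecError(ValueError):
    pass


@dataclass
class PhantomSpec:
    """Parameters of the synthetic lesion-volume generator.

    grid: volume shape (H, W, D) in voxels.
    n_channels: image channels (pseudo-modalities).
    n_lesions: inclusive (min, max) lesion count per volume.
    radii: inclusive (min, max) semi-axis length in voxels, drawn
        independently per axis per lesion.
    nested_classes: label values outer -> inner (e.g. (2, 1, 4) for
        edema > necrotic core > enhancing tumor); a single entry gives
        single-class lesions.
    shell_fractions: radius scale of each shell relative to the outer
        ellipsoid, strictly decreasing, same length as nested_classes.
    class_intensity: mean image intensity per (class, channel); keys
        are label values, values are length-n_channels sequences.
        Classes absent from the mapping fall back to background + label.
    background_intensity: mean intensity outside lesions.
    noise_sd: additive Gaussian noise standard deviation.
    spacing: voxel size in mm per axis.
    seed: master random seed.
    lumpy: warp lesions with a seeded smooth displacement field.
    """

    grid: tuple[int, int, int] = (64, 64, 64)
    n_channels: int = 2
    n_lesions: tuple[int, int] = (1, 3)
    radii: tuple[float, float] = (4.0, 12.0)
    nested_classes: tuple[int, ...] = (2, 1, 4)
    shell_fractions: tuple[float, ...] = (1.0, 0.6, 0.3)
    class_intensity: dict[int, tuple[float, ...]] | None = None
    background_intensity: float = 1.0
    noise_sd: float = 0.1
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0
    lumpy: bool = False

    def validate(self) -> None:
        if any(g < 4 for g in self.grid):
            raise PhantomSpecError("grid dims must be >= 4")
        if self.n_channels < 1:
            raise PhantomSpecError("n_channels must be >= 1")
        lo, hi = self.n_lesions
        if lo < 0 or hi < lo:
            raise PhantomSpecError("n_lesions range invalid")
        rlo, rhi = self.radii
        if rlo <= 0 or rhi < rlo:
            raise PhantomSpecError("radii range invalid")
        if rhi >= min(self.grid) / 2:
            raise PhantomSpecError(
                f"max radius {rhi} does not fit inside grid {self.grid} "
                "(must be < grid/2)")
        if len(self.shell_fractions) != len(self.nested_classes):
            raise PhantomSpecError(
                "shell_fractions and nested_classes must have equal length")
        fr = self.shell_fractions
        if any(b >= a for a, b in zip(fr, fr[1:])) or any(f <= 0 for f in fr):
            raise PhantomSpecError(
                "shell_fractions must be positive and strictly decreasing")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be >= 0")

    def intensity(self, label: int) -> np.ndarray:
        if self.class_intensity and label in self.class_intensity:
            v = np.asarray(self.class_intensity[label], dtype=float)
            if v.shape != (self.n_channels,):
                raise PhantomSpecError(
                    f"class_intensity[{label}] must have {self.n_channels} entries")
            return v
        if label == 0:
            return np.full(self.n_channels, self.background_intensity)
        # default contrast ladder: one unit per raw label value
        return np.full(self.n_channels, self.background_intensity + float(label))


def ellipsoid_volume(semi_axes) -> float:
    """Analytic ellipsoid volume (4/3) pi a b c."""
    a, b, c = semi_axes
    return 4.0 / 3.0 * np.pi * a * b * c


def _ellipsoid_mask(grid, center, semi_axes) -> np.ndarray:
    coords = np.ogrid[tuple(slice(0, g) for g in grid)]
    q = sum(((x - c) / r) ** 2 for x, c, r in zip(coords, center, semi_axes))
    return q <= 1.0


def generate_phantom(spec: PhantomSpec, seed: int | None = None) -> VolumeRecord:
    """Generate one phantom volume; deterministic for a fixed seed.

    Lesions are placed fully inside the grid; overlapping lesions are
    resolved by later lesions overwriting earlier labels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = np.zeros(spec.grid, dtype=np.int64)
    n = int(rng.integers(spec.n_lesions[0], spec.n_lesions[1] + 1))
    for _ in range(n):
        semi = rng.uniform(spec.radii[0], spec.radii[1], size=3)
        center = np.array([rng.uniform(r, g - 1 - r)
                           for r, g in zip(semi, spec.grid)])
        for frac, label in zip(spec.shell_fractions, spec.nested_classes):
            mask = _ellipsoid_mask(spec.grid, center, semi * frac)
            labels[mask] = label
    if spec.lumpy and labels.any():
        labels = _lumpy_warp(labels, rng)
    image = np.empty((*spec.grid, spec.n_channels), dtype=np.float32)
    for ch in range(spec.n_channels):
        plane = np.full(spec.grid, spec.intensity(0)[ch], dtype=np.float32)
        for label in spec.nested_classes:
            plane[labels == label] = spec.intensity(label)[ch]
        if spec.noise_sd > 0:
            plane = plane + rng.normal(0.0, spec.noise_sd,
                                       size=spec.grid).astype(np.float32)
        image[..., ch] = plane
    return VolumeRecord(image=image, labels=labels, spacing=spec.spacing,
                        identifier=f"phantom-{spec.seed if seed is None else seed}")


def _lumpy_warp(labels: np.ndarray, rng: np.random.Generator,
                amplitude: float = 2.0, smoothness: float = 6.0) -> np.ndarray:
    """Nearest-neighbour resample through a smooth random displacement."""
    disp = [ndimage.gaussian_filter(rng.normal(size=labels.shape), smoothness)
            for _ in range(3)]
    disp = [amplitude * d / (np.abs(d).max() + 1e-12) for d in disp]
    coords = np.meshgrid(*[np.arange(g) for g in labels.shape], indexing="ij")
    warped = [np.clip(c + d, 0, g - 1)
              for c, d, g in zip(coords, disp, labels.shape)]
    return ndimage.map_coordinates(labels, warped, order=0)


def child_seed(master_seed: int, index: int) -> int:
    """Reproducible per-volume seed below 2**31."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0]
               % (2 ** 31))


def generate_dataset(spec: PhantomSpec, n_volumes: int, out_dir) -> pd.DataFrame:
    """Write ``n_volumes`` phantom image/label NIfTI pairs plus a manifest.

    The manifest CSV (one row per volume: id, image path, label path,
    seed) is written to ``out_dir/manifest.csv`` and returned.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_volumes):
        s = child_seed(spec.seed, i)
        rec = generate_phantom(spec, seed=s)
        ident = f"phantom_{i:04d}"
        img_path = out / f"{ident}_image.nii.gz"
        lab_path = out / f"{ident}_labels.nii.gz"
        write_volume(replace(rec, identifier=ident), img_path, lab_path)
        rows.append({"id": ident, "image": str(img_path),
                     "labels": str(lab_path), "seed": s})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
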