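"""Segmentation evaluation: overlap metrics, average Hausdorff distance,
and nested evaluation-region masks.

All probability maps are binarized at threshold 0.5 (a tie at exactly
0.5 counts as positive).  Overlap metrics follow the usual confusion
definitions; AHD is the symmetric mean of nearest-neighbour distances
between the foreground voxel sets, in physical units (voxel spacing in
mm scales distances).

Division-by-zero conventions: precision, recall, DSC, and IoU return 1
when the corresponding denominator is zero *and* both masks are empty
(vacuous agreement); 0 when only one mask is empty.  Degenerate cases
are flagged in the report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


class MetricsValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Binarization and confusion counts
# ---------------------------------------------------------------------------

def binarize(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary mask: positive iff probability >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise MetricsValidationError(
            f"threshold must lie in (0, 1), got {threshold}")
    p = np.asarray(p)
    if p.min() < 0 or p.max() > 1:
        raise MetricsValidationError("probabilities must lie in [0, 1]")
    return p >= threshold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact voxel confusion counts between two binary masks."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise MetricsValidationError(
            f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(pred.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_ratio(num: int, den: int, other_side_empty_agrees: bool) -> float:
    if den > 0:
        return num / den
    return 1.0 if other_side_empty_agrees else 0.0


def overlap_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, DSC and IoU from confusion counts."""
    if min(c.tp, c.tn, c.fp, c.fn) < 0:
        raise MetricsValidationError("confusion counts must be non-negative")
    if c.total == 0:
        raise MetricsValidationError("no voxels evaluated (all counts zero)")
    both_empty = c.tp == 0 and c.fp == 0 and c.fn == 0
    return {
        "accuracy": (c.tp + c.tn) / c.total,
        "precision": _safe_ratio(c.tp, c.tp + c.fp, c.fn == 0),
        "recall": _safe_ratio(c.tp, c.tp + c.fn, c.fp == 0),
        "dsc": _safe_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, both_empty),
        "iou": _safe_ratio(c.tp, c.tp + c.fp + c.fn, both_empty),
    }


# ---------------------------------------------------------------------------
# Average Hausdorff distance
# ---------------------------------------------------------------------------

def _as_points(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.dtype == bool or x.ndim == 3:
        return np.argwhere(np.asarray(x, dtype=bool))
    if x.ndim == 2 and x.shape[1] == 3:
        return x
    raise MetricsValidationError(
        "point set must be a 3-D binary mask or an (N, 3) coordinate array")


def average_hausdorff(pred, truth, spacing=(1.0, 1.0, 1.0),
                      empty_penalty: float | None = None,
                      surface_only: bool = False) -> float:
    """Average Hausdorff distance between two voxel point sets.

    AHD = 1/2 [ mean_p min_l d(p,l) + mean_l min_p d(p,l) ]

    ``pred`` and ``truth`` are binary 3-D masks or (N, 3) voxel
    coordinate arrays; ``spacing`` converts voxel offsets to physical
    distances.  Both point sets are all foreground voxels by default;
    ``surface_only=True`` erodes each mask to its boundary voxels first
    (masks only).  Empty-set conventions: both empty -> 0 with a
    warning; one empty -> ``empty_penalty`` (defaults to the mask's
    physical diagonal) with a warning.
    """
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise MetricsValidationError("spacing must be 3 positive values")
    if surface_only:
        pred = _surface(np.asarray(pred, dtype=bool))
        truth = _surface(np.asarray(truth, dtype=bool))
    diag = None
    for m in (pred, truth):
        m = np.asarray(m)
        if m.ndim == 3:
            diag = float(np.linalg.norm((np.array(m.shape) - 1) * spacing))
    p = _as_points(pred) * spacing
    l = _as_points(truth) * spacing
    if len(p) == 0 and len(l) == 0:
        warnings.warn("AHD of two empty point sets defined as 0", stacklevel=2)
        return 0.0
    if len(p) == 0 or len(l) == 0:
        warnings.warn("AHD with one empty point set: returning penalty",
                      stacklevel=2)
        if empty_penalty is not None:
            return float(empty_penalty)
        if diag is not None:
            return diag
        raise MetricsValidationError(
            "one point set empty and no empty_penalty configured")
    d_pl = cKDTree(l).query(p)[0]
    d_lp = cKDTree(p).query(l)[0]
    return 0.5 * (float(d_pl.mean()) + float(d_lp.mean()))


def _surface(mask: np.ndarray) -> np.ndarray:
    from scipy.ndimage import binary_erosion
    return mask & ~binary_erosion(mask)


# ---------------------------------------------------------------------------
# Evaluation regions (nested lesion sub-regions built from raw labels)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSpec:
    """Mapping from region name to the set of raw labels it unions."""

    regions: dict[str, frozenset[int]]

    def __post_init__(self):
        for name, labels in self.regions.items():
            if not labels:
                raise MetricsValidationError(f"region {name!r} has no labels")

    @property
    def domain(self) -> frozenset[int]:
        out: set[int] = {0}
        for labels in self.regions.values():
            out |= labels
        return frozenset(out)


#: Standard nested brain-tumor regions over raw labels
#: 1 = necrotic core (NCR), 2 = peritumoral edema (ED), 4 = enhancing
#: tumor (ET): whole tumor = union of all three, tumor core = NCR + ET.
BRATS_REGIONS = RegionSpec({
    "WT": frozenset({1, 2, 4}),
    "TC": frozenset({1, 4}),
    "ET": frozenset({4}),
})

#: Alternative tumor-core reading (ED + NCR) kept available via config.
BRATS_REGIONS_TC_EDEMA = RegionSpec({
    "WT": frozenset({1, 2, 4}),
    "TC": frozenset({1, 2}),
    "ET": frozenset({4}),
})


def region_binary_masks(labels: np.ndarray,
                        regions: RegionSpec = BRATS_REGIONS) -> dict[str, np.ndarray]:
    """One binary mask per named region (union of its raw labels)."""
    labels = np.asarray(labels)
    present = set(np.unique(labels).tolist())
    unknown = sorted(present - set(regions.domain))
    if unknown:
        raise MetricsValidationError(
            f"label values {unknown} not covered by the region specification")
    return {name: np.isin(labels, sorted(lab))
            for name, lab in regions.regions.items()}


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-class / per-region metric rows plus aggregate mean IoU."""

    rows: list[dict] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def add(self, name: str, metrics: dict[str, float], **extra):
        self.rows.append({"name": name, **metrics, **extra})

    @property
    def mean_iou(self) -> float:
        """Unweighted mean IoU over foreground classes/regions."""
        ious = [r["iou"] for r in self.rows if "iou" in r]
        return float(np.mean(ious)) if ious else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_json(self) -> str:
        return json.dumps({"rows": self.rows, "mean_iou": self.mean_iou,
                           "flags": self.flags}, indent=2, default=float)

    def save(self, json_path=None, csv_path=None):
        if json_path:
            with open(json_path, "w") as fh:
                fh.write(self.to_json())
        if csv_path:
            self.to_frame().to_csv(csv_path, index=False)
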