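"""Training, inference and evaluation driver.

Optimization follows the reference recipe: Adam at learning rate 1e-4
with weight decay 5e-4 applied as an L2 penalty on convolution kernels
added to the loss, minimizing the Dice + categorical focal compound
loss on whole volumes (batch size 1 by default).  The best checkpoint
by validation loss is kept; training stops early when validation loss
has not improved for ``patience`` epochs.

Checkpoints are NumPy ``.npz`` archives embedding a JSON record of the
architecture and the label remap, so a checkpoint is self-describing.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .losses import LossConfig, total_loss
from .metrics import (MetricsReport, RegionSpec, average_hausdorff, binarize,
                      confusion_counts, overlap_metrics, region_binary_masks)
from .net_blocks import Network, NetworkSpec, ValidationError, build_network
from .volume_io import (DEFAULT_LABEL_REMAP, VolumeRecord, inverse_remap_labels,
                        normalize, read_volume, remap_labels)

log = logging.getLogger("afmsnet")


@dataclass
class TrainConfig:
    """Optimization settings (defaults follow the reference recipe)."""

    learning_rate: float = 1e-4
    weight_decay: float = 5e-4
    epochs: int = 100
    batch_size: int = 1
    seed: int = 0
    patience: int = 20
    normalize_images: bool = True
    label_remap: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_REMAP))
    loss: LossConfig = field(default_factory=LossConfig)
    network: NetworkSpec = field(default_factory=NetworkSpec)

    def validate(self):
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if self.weight_decay < 0:
            raise ValidationError("weight_decay must be >= 0")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        self.network.validate()


# ---------------------------------------------------------------------------
# Data plumbing
# ---------------------------------------------------------------------------

def _load_manifest(manifest) -> pd.DataFrame:
    if isinstance(manifest, pd.DataFrame):
        return manifest
    return pd.read_csv(manifest)


def _load_case(row, config: TrainConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (image (1,H,W,D,C), one-hot (H,W,D,K), raw labels)."""
    rec = read_volume(row["image"], row.get("labels"), identifier=str(row["id"]))
    return prepare_case(rec, config)


def prepare_case(rec: VolumeRecord, config: TrainConfig):
    if config.normalize_images:
        rec = normalize(rec)
    k = config.network.n_classes
    mapped = remap_labels(rec.labels, config.label_remap)
    if mapped.max() >= k:
        raise ValidationError(
            f"remapped label {mapped.max()} >= n_classes {k}")
    one_hot = np.eye(k, dtype=np.float32)[mapped]
    image = rec.image[None].astype(np.float32)
    div = 2 ** config.network.n_stages
    for ax in image.shape[1:4]:
        if ax % div:
            raise ValidationError(
                f"volume dim {ax} not divisible by 2^n_stages = {div}")
    return image, one_hot, rec.labels


def _foreground_dsc(pred_classes: np.ndarray, true_classes: np.ndarray,
                    n_classes: int) -> float:
    """Mean Dice over foreground class indices present in the truth."""
    scores = []
    for c in range(1, n_classes):
        t = true_classes == c
        if not t.any():
            continue
        p = pred_classes == c
        scores.append(overlap_metrics(confusion_counts(p, t))["dsc"])
    return float(np.mean(scores)) if scores else float("nan")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(config: TrainConfig, manifest, checkpoint_path=None,
          max_steps: int | None = None,
          target_dsc: float | None = None) -> tuple[Network, dict]:
    """Train a network on the manifest's training split.

    The manifest needs columns ``id``, ``image``, ``labels`` and
    optionally ``split`` (train/validation/test); without a split
    column every volume is used for both training and validation.
    ``max_steps`` caps the total number of optimizer steps;
    ``target_dsc`` stops training once the epoch training Dice reaches
    it (an overfit-to-target budget).

    Returns the network restored to its best-validation state, plus a
    history dict with per-epoch train/validation loss and Dice.
    """
    config.validate()
    df = _load_manifest(manifest)
    if "split" in df.columns:
        train_rows = df[df["split"] == "train"]
        val_rows = df[df["split"] == "validation"]
        if val_rows.empty:
            val_rows = train_rows
    else:
        train_rows = val_rows = df
    if train_rows.empty:
        raise ValidationError("manifest has no training volumes")

    cases = [_load_case(row, config) for _, row in train_rows.iterrows()]
    val_cases = ([_load_case(row, config) for _, row in val_rows.iterrows()]
                 if val_rows is not train_rows else cases)

    net = build_network(config.network, config.seed)
    opt = Adam(net.params(), lr=config.learning_rate)
    kernels = net.kernel_params()
    rng = np.random.default_rng(config.seed)

    history = {"train_loss": [], "train_dsc": [], "val_loss": [], "val_dsc": []}
    best_val = np.inf
    best_state = None
    stale = 0
    steps = 0
    k = config.network.n_classes

    for epoch in range(config.epochs):
        order = rng.permutation(len(cases))
        ep_loss, ep_dsc = [], []
        for idx in order:
            image, one_hot, _ = cases[idx]
            opt.zero_grad()
            probs = net.forward(image, training=True)
            loss = total_loss(Tensor(one_hot), ad.reshape(probs, one_hot.shape),
                              config.loss)
            if config.weight_decay > 0:
                penalty = None
                for w in kernels:
                    term = ad.sum_(w * w)
                    penalty = term if penalty is None else penalty + term
                loss = loss + config.weight_decay * penalty
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {steps}: "
                    f"{float(loss.data)}")
            loss.backward()
            opt.step()
            steps += 1
            ep_loss.append(float(loss.data))
            pred = np.argmax(probs.data[0], axis=-1)
            ep_dsc.append(_foreground_dsc(pred, np.argmax(one_hot, -1), k))
            if max_steps is not None and steps >= max_steps:
                break
        history["train_loss"].append(float(np.mean(ep_loss)))
        history["train_dsc"].append(float(np.nanmean(ep_dsc)))

        vl, vd = _evaluate_loss(net, val_cases, config)
        history["val_loss"].append(vl)
        history["val_dsc"].append(vd)
        log.info("epoch %d: train loss %.4f dsc %.4f | val loss %.4f dsc %.4f",
                 epoch, history["train_loss"][-1], history["train_dsc"][-1], vl, vd)

        if vl < best_val:
            best_val = vl
            best_state = {key: arr.copy()
                          for key, arr in net.state_arrays().items()}
            stale = 0
        else:
            stale += 1
        if max_steps is not None and steps >= max_steps:
            break
        if target_dsc is not None and history["train_dsc"][-1] >= target_dsc:
            log.info("training Dice target %.3f reached at epoch %d",
                     target_dsc, epoch)
            break
        if stale > config.patience:
            log.info("early stopping at epoch %d", epoch)
            break

    if best_state is not None:
        net.load_state_arrays(best_state)
    if checkpoint_path is not None:
        save_checkpoint(net, checkpoint_path, label_remap=config.label_remap)
    return net, history


def _evaluate_loss(net: Network, cases, config: TrainConfig) -> tuple[float, float]:
    losses, dscs = [], []
    k = config.network.n_classes
    for image, one_hot, _ in cases:
        probs = net.forward(image, training=False)
        losses.append(float(total_loss(one_hot, probs.data.reshape(one_hot.shape),
                                       config.loss)))
        pred = np.argmax(probs.data[0], axis=-1)
        dscs.append(_foreground_dsc(pred, np.argmax(one_hot, -1), k))
    return float(np.mean(losses)), float(np.nanmean(dscs))


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(net: Network, path, label_remap=None) -> None:
    meta = {"spec": asdict(net.spec),
            "label_remap": {str(kk): vv for kk, vv in
                            (label_remap or DEFAULT_LABEL_REMAP).items()}}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **net.state_arrays())


def load_checkpoint(path) -> tuple[Network, dict[int, int]]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {kk: data[kk] for kk in data.files if kk != "__meta__"}
    spec = NetworkSpec(**meta["spec"])
    net = build_network(spec, seed=0)
    net.load_state_arrays(arrays)
    remap = {int(kk): int(vv) for kk, vv in meta["label_remap"].items()}
    return net, remap


# ---------------------------------------------------------------------------
# Inference and evaluation
# ---------------------------------------------------------------------------

def predict(net: Network, image: np.ndarray,
            label_remap: dict[int, int] | None = None
            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel class probabilities and hard labels in the raw scheme.

    ``image`` is (H, W, D, C) or batched (1, H, W, D, C).
    """
    if image.ndim == 4:
        image = image[None]
    probs = net.forward(image, training=False).data[0]
    hard = np.argmax(probs, axis=-1)
    remap = label_remap if label_remap is not None else DEFAULT_LABEL_REMAP
    return probs, inverse_remap_labels(hard, remap)


def evaluate(net: Network, manifest, config: TrainConfig,
             regions: RegionSpec | None = None,
             threshold: float = 0.5) -> tuple[MetricsReport, dict]:
    """Per-case and aggregate metrics on the manifest's labelled volumes.

    Per foreground class (and per named region when ``regions`` is
    given) the report carries accuracy, precision, recall, DSC, IoU and
    AHD per case; the aggregate dict holds macro mean +- sd over cases
    and micro (voxel-pooled) overlap metrics.
    """
    df = _load_manifest(manifest)
    if "labels" not in df.columns or df["labels"].isna().any():
        raise ValidationError("evaluation requires labels for every case")
    report = MetricsReport()
    pooled: dict[str, np.ndarray] = {}
    k = config.network.n_classes
    inv = {v: kk for kk, v in config.label_remap.items()}  # class idx -> raw label

    for _, row in df.iterrows():
        image, one_hot, raw_labels = _load_case(row, config)
        probs = net.forward(image, training=False).data[0]
        pos = binarize(probs, threshold)
        case = str(row["id"])
        targets: list[tuple[str, np.ndarray, np.ndarray]] = []
        for c in range(1, k):
            name = f"class_{inv.get(c, c)}"
            targets.append((name, pos[..., c], one_hot[..., c] > 0.5))
        if regions is not None:
            hard_raw = inverse_remap_labels(np.argmax(probs, -1),
                                            config.label_remap)
            pred_regions = region_binary_masks(hard_raw, regions)
            true_regions = region_binary_masks(raw_labels, regions)
            for name in regions.regions:
                targets.append((name, pred_regions[name], true_regions[name]))
        for name, pmask, tmask in targets:
            cc = confusion_counts(pmask, tmask)
            m = overlap_metrics(cc)
            m["ahd"] = average_hausdorff(pmask, tmask)
            if (pmask.any() != tmask.any()):
                report.flags.append(f"{case}/{name}: one mask empty")
            report.add(name, m, case=case)
            key = name
            counts = np.array([cc.tp, cc.tn, cc.fp, cc.fn])
            pooled[key] = pooled.get(key, np.zeros(4, dtype=np.int64)) + counts

    frame = report.to_frame()
    aggregate: dict[str, dict] = {"macro": {}, "micro": {}}
    for name, grp in frame.groupby("name"):
        aggregate["macro"][name] = {
            col: {"mean": float(grp[col].mean()), "sd": float(grp[col].std(ddof=0))}
            for col in ("accuracy", "precision", "recall", "dsc", "iou", "ahd")}
        tp, tn, fp, fn = (int(x) for x in pooled[name])
        from .metrics import ConfusionCounts
        aggregate["micro"][name] = overlap_metrics(
            ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
    aggregate["mean_iou_macro"] = float(np.mean(
        [v["iou"]["mean"] for v in aggregate["macro"].values()]))
    return report, aggregate
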