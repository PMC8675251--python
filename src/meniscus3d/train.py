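"""Training loops for the three detection approaches.

The pipeline mirrors the intended clinical workflow: per-volume min-max
normalisation, population standardisation with statistics fitted on the
training split only, approach-specific spatial preparation (whole-volume
resampling or RoI cropping), on-the-fly augmentation, and ADAM optimisation
with separate learning rates for the encoder and the MLP heads.  The
learning rate is halved every 50 epochs and the returned checkpoint is the
epoch with the lowest validation loss.

Approaches:

* ``full_scale`` — ResNet50-3D on the whole volume, weighted BCE only.
* ``bb_crop``   — DRN-C-26-3D on the 5%-margined crop around both menisci
  (crop shape fixed from the training set, multiples of 16), weighted BCE.
* ``bb_loss``   — ResNet50-3D on the whole volume with a second head
  regressing both meniscal boxes; loss = BCE + L1 + GIoU.

Checkpoints are single ``.npz`` files with the weights, the configuration
and the fitted normalisation statistics embedded, so evaluation and saliency
need nothing but the checkpoint and new volumes.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentationSpec, augment
from .autodiff import Tensor, no_grad
from .losses import class_weights, total_loss, weighted_bce
from .nets import EncoderConfig, HeadConfig, MultiTaskModel, assemble_model
from .preprocess import (NormalizationStats, box_from_mask, crop_to_rois,
                         fit_stats, minmax_normalize, resample_nearest,
                         resample_trilinear, standardize, training_crop_shape)

__all__ = [
    "TrainConfig", "Adam", "split_cohort", "train_model", "finetune",
    "save_checkpoint", "load_checkpoint", "model_from_checkpoint",
    "prepare_sample", "preprocess_cohort",
]

_ENCODER_FOR = {"full_scale": "resnet50", "bb_crop": "drn_c_26", "bb_loss": "resnet50"}


@dataclass
class TrainConfig:
    """Hyper-parameters of one training run.

    Defaults are the desk-scale configuration: quarter-width encoders on a
    32 x 64 x 64 grid with batch size 4 — an architecturally faithful
    miniature that trains on a single CPU.
    """

    approach: str = "bb_loss"
    width_multiplier: float = 0.25
    input_shape: tuple = (32, 64, 64)        # full-volume approaches
    hidden_units: int = 512                  # 2048 x width at desk scale
    dropout: float = 0.3
    lr_encoder: float = 1e-3
    lr_heads: float = 1e-3
    batch_size: int = 4
    adam_betas: tuple = (0.9, 0.999)
    adam_eps: float = 1e-8
    lr_decay: float = 0.5
    lr_decay_every: int = 50
    max_epochs: int = 36
    seed: int = 0
    split_fractions: tuple = (0.50, 0.15, 0.35)
    roi_margin: float = 0.05
    augmentation: AugmentationSpec | None = field(default_factory=AugmentationSpec)

    def __post_init__(self):
        if self.approach not in _ENCODER_FOR:
            raise ValueError(f"unknown approach {self.approach!r}")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not (1e-5 <= self.lr_encoder <= 0.01 and 1e-5 <= self.lr_heads <= 0.01):
            raise ValueError("learning rates must lie in [1e-5, 0.01]")
        if not 0.1 <= self.dropout <= 0.9:
            raise ValueError("dropout must lie in [0.1, 0.9]")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if self.augmentation is not None:
            d["augmentation"] = dataclasses.asdict(self.augmentation)
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "TrainConfig":
        d = json.loads(text)
        aug = d.pop("augmentation", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        cfg.augmentation = (AugmentationSpec(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in aug.items()})
            if aug is not None else None)
        return cfg


class Adam(object):
    """ADAM with per-group learning rates, a global decay factor and
    global-norm gradient clipping (guards the sigmoid-activated box head
    against early saturation)."""

    def __init__(self, groups, betas=(0.9, 0.999), eps=1e-8, clip_norm: float = 5.0):
        # groups: list of (params, lr)
        self.groups = [(list(params), float(lr)) for params, lr in groups]
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [[np.zeros_like(p.data) for p in params] for params, _ in self.groups]
        self.v = [[np.zeros_like(p.data) for p in params] for params, _ in self.groups]

    def _clip(self) -> None:
        if self.clip_norm is None:
            return
        sq = 0.0
        for params, _ in self.groups:
            for p in params:
                if p.grad is not None:
                    sq += float((p.grad.astype(np.float64) ** 2).sum())
        norm = np.sqrt(sq)
        if norm > self.clip_norm:
            scale = self.clip_norm / norm
            for params, _ in self.groups:
                for p in params:
                    if p.grad is not None:
                        p.grad *= scale

    def step(self, lr_scale: float = 1.0) -> None:
        self._clip()
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for gi, (params, lr) in enumerate(self.groups):
            for pi, p in enumerate(params):
                if p.grad is None:
                    continue
                g = p.grad
                m = self.m[gi][pi]
                v = self.v[gi][pi]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * (g * g)
                p.data -= (lr * lr_scale) * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for params, _ in self.groups:
            for p in params:
                p.grad = None


def split_cohort(manifest: pd.DataFrame, fractions, seed: int):
    """Random, disjoint, exhaustive train/val/test id split.

    Counts: train = round(f_train * N), val = round(f_val * N), test = rest.
    """
    ids = list(manifest["id"])
    if len(ids) == 0:
        raise ValueError("empty cohort")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(fractions[0] * len(ids)))
    n_val = int(round(fractions[1] * len(ids)))
    train = [ids[i] for i in order[:n_train]]
    val = [ids[i] for i in order[n_train:n_train + n_val]]
    test = [ids[i] for i in order[n_train + n_val:]]
    return train, val, test


# ---------------------------------------------------------------------------
# sample preparation
# ---------------------------------------------------------------------------

def _safe_class_weights(labels: np.ndarray) -> np.ndarray:
    """Inverse-frequency weights, with weight 1 for classes a small training
    split leaves single-valued (no positives or no negatives)."""
    try:
        return class_weights(labels)
    except ValueError:
        n = labels.shape[0]
        n_pos = labels.sum(axis=0).astype(np.float64)
        w = np.ones(6, dtype=np.float32)
        ok = (n_pos > 0) & (n_pos < n)
        w[ok] = (n / (2.0 * n_pos[ok])).astype(np.float32)
        return w


def _boxes_array(mask) -> np.ndarray:
    """Ground-truth (2, 6) relative box array [medial; lateral] from a mask."""
    return np.stack([box_from_mask(mask, s).to_array() for s in (1, 2)])


def prepare_sample(image, mask, labels, cfg: TrainConfig, crop_shape=None):
    """Spatially prepare one standardised sample for the network.

    `image` must already be min-max normalised and standardised.  Returns
    ``(input volume, labels, target boxes (2,6) or None)``; boxes are
    expressed in the network-input frame.
    """
    img = np.asarray(image, dtype=np.float32)
    if cfg.approach == "bb_crop":
        if crop_shape is None:
            raise ValueError("bb_crop needs the training crop shape")
        boxes = [box_from_mask(mask, s) for s in (1, 2)]
        img = crop_to_rois(img, boxes, cfg.roi_margin, crop_shape)
        return img, np.asarray(labels), None
    if tuple(img.shape) != tuple(cfg.input_shape):
        img = resample_trilinear(img, cfg.input_shape)
        mask = resample_nearest(mask, cfg.input_shape)
    target = _boxes_array(mask) if cfg.approach == "bb_loss" else None
    return img, np.asarray(labels), target


def preprocess_cohort(samples, cfg: TrainConfig, train_ids):
    """Min-max normalise all volumes, fit population statistics on the
    training split, and standardise; returns (standardised images dict,
    stats, crop_shape or None)."""
    by_id = {s.sample_id: s for s in samples}
    normalized = {sid: minmax_normalize(s.image) for sid, s in by_id.items()}
    stats = fit_stats([normalized[sid] for sid in train_ids])
    standardized = {sid: standardize(img, stats) for sid, img in normalized.items()}
    crop_shape = None
    if cfg.approach == "bb_crop":
        pairs = [by_id[sid].boxes for sid in train_ids]
        shape = by_id[train_ids[0]].image.shape
        crop_shape = training_crop_shape(pairs, shape, cfg.roi_margin)
    return standardized, stats, crop_shape


def _batch_forward_loss(model: MultiTaskModel, batch, cfg: TrainConfig, w):
    imgs, labels, boxes = batch
    x = Tensor(imgs[:, None, :, :, :])
    if cfg.approach == "bb_loss":
        cls_logits, box_out = model.logits(x)
        pred_boxes = box_out.sigmoid()
        loss, comps = total_loss(cls_logits, labels, pred_boxes,
                                 boxes.reshape(len(imgs), 12), w)
    else:
        cls_logits = model.logits(x)
        loss = weighted_bce(cls_logits, labels, w)
        comps = {"bce": loss.item(), "l1": 0.0, "giou": 0.0, "total": loss.item()}
    return loss, comps


def _collect_batch(entries):
    imgs = np.stack([e[0] for e in entries]).astype(np.float32)
    labels = np.stack([e[1] for e in entries]).astype(np.float32)
    boxes = (np.stack([e[2] for e in entries]).astype(np.float32)
             if entries[0][2] is not None else None)
    return imgs, labels, boxes


def _build_model(cfg: TrainConfig, input_shape) -> MultiTaskModel:
    enc_cfg = EncoderConfig(kind=_ENCODER_FOR[cfg.approach],
                            width_multiplier=cfg.width_multiplier,
                            input_shape=tuple(input_shape))
    model = assemble_model(cfg.approach, enc_cfg, None, seed=cfg.seed)
    # rebuild heads with the configured hidden width / dropout
    n_feat = model.encoder.feature_length
    rng = np.random.default_rng(cfg.seed + 1)
    from .nets import build_head
    model.cls_head = build_head(HeadConfig(n_feat, cfg.hidden_units, 6,
                                           cfg.dropout), rng)
    if cfg.approach == "bb_loss":
        model.box_head = build_head(HeadConfig(n_feat, cfg.hidden_units, 12,
                                               cfg.dropout), rng)
    return model


def train_model(cfg: TrainConfig, samples, manifest: pd.DataFrame,
                initial_state: dict | None = None, split=None):
    """Train one model on a phantom cohort; returns a checkpoint dict.

    The checkpoint carries the best-validation-loss weights, the config,
    normalisation statistics, class weights, the split and the per-epoch
    training log.
    """
    if split is None:
        split = split_cohort(manifest, cfg.split_fractions, cfg.seed)
    train_ids, val_ids, test_ids = split
    if len(train_ids) == 0 or len(val_ids) == 0:
        raise ValueError("train and validation splits must be nonempty")
    by_id = {s.sample_id: s for s in samples}
    standardized, stats, crop_shape = preprocess_cohort(samples, cfg, train_ids)

    labels_train = np.stack([by_id[sid].labels for sid in train_ids])
    w = _safe_class_weights(labels_train)

    input_shape = crop_shape if cfg.approach == "bb_crop" else cfg.input_shape
    model = _build_model(cfg, input_shape)
    if initial_state is not None:
        model.load_state_dict(initial_state)

    enc_params = model.encoder.parameters()
    head_params = model.cls_head.parameters() + (
        model.box_head.parameters() if model.box_head is not None else [])
    opt = Adam([(enc_params, cfg.lr_encoder), (head_params, cfg.lr_heads)],
               betas=cfg.adam_betas, eps=cfg.adam_eps)

    # fixed (non-augmented) validation inputs
    val_batches = [prepare_sample(standardized[sid], by_id[sid].mask,
                                  by_id[sid].labels, cfg, crop_shape)
                   for sid in val_ids]

    rng = np.random.default_rng(cfg.seed + 1000)
    log_rows = []
    best = (np.inf, -1, None)
    for epoch in range(cfg.max_epochs):
        lr_scale = cfg.lr_decay ** (epoch // cfg.lr_decay_every)
        model.train()
        order = rng.permutation(len(train_ids))
        epoch_losses = []
        epoch_comps = []
        for start in range(0, len(order), cfg.batch_size):
            chunk = [train_ids[i] for i in order[start:start + cfg.batch_size]]
            entries = []
            for sid in chunk:
                s = by_id[sid]
                img, mask, labels = standardized[sid], s.mask, s.labels
                if cfg.augmentation is not None:
                    img, mask, labels = augment(img, mask, labels,
                                                cfg.augmentation, cfg.approach, rng)
                entries.append(prepare_sample(img, mask, labels, cfg, crop_shape))
            batch = _collect_batch(entries)
            loss, comps = _batch_forward_loss(model, batch, cfg, w)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step(lr_scale)
            epoch_losses.append(loss.item())
            epoch_comps.append(comps)

        val_loss, val_comps = _evaluate_loss(model, val_batches, cfg, w)
        train_loss = float(np.mean(epoch_losses))
        row = {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss,
               "lr_scale": lr_scale}
        for key in ("bce", "l1", "giou"):
            row[f"train_{key}"] = float(np.mean([c[key] for c in epoch_comps]))
            row[f"val_{key}"] = val_comps[key]
        log_rows.append(row)
        if val_loss < best[0]:
            best = (val_loss, epoch, model.state_dict())

    if best[2] is not None:
        model.load_state_dict(best[2])
    return {
        "state": model.state_dict(),
        "config": cfg,
        "stats": stats,
        "crop_shape": crop_shape,
        "class_weights": w,
        "split": {"train": train_ids, "val": val_ids, "test": test_ids},
        "log": pd.DataFrame(log_rows),
        "best_epoch": int(best[1]),
        "best_val_loss": float(best[0]),
        "rng_state": rng.bit_generator.state,  # training stream after the run
    }


def _evaluate_loss(model, prepared, cfg, w):
    model.eval()
    losses = []
    comps_all = []
    with no_grad():
        for start in range(0, len(prepared), cfg.batch_size):
            batch = _collect_batch(prepared[start:start + cfg.batch_size])
            loss, comps = _batch_forward_loss(model, batch, cfg, w)
            n = len(batch[0])
            losses.append((loss.item(), n))
            comps_all.append((comps, n))
    total_n = sum(n for _, n in losses)
    val = sum(v * n for v, n in losses) / total_n
    merged = {k: sum(c[k] * n for c, n in comps_all) / total_n
              for k in ("bce", "l1", "giou", "total")}
    return float(val), merged


def finetune(checkpoint: dict, samples, manifest: pd.DataFrame,
             cfg: TrainConfig | None = None):
    """Continue optimisation from a checkpoint on a new cohort.

    Emulates sequence transfer: both encoder and head weights are loaded and
    then fine-tuned end-to-end.  Architecture (approach, width, head sizes)
    must match the checkpoint; normalisation statistics are refitted on the
    new cohort's training split.  ``max_epochs = 0`` returns the loaded
    weights unchanged (selection still runs on the new validation split).
    """
    base_cfg: TrainConfig = checkpoint["config"]
    if cfg is None:
        cfg = dataclasses.replace(base_cfg)
    for attr in ("approach", "width_multiplier", "hidden_units"):
        if getattr(cfg, attr) != getattr(base_cfg, attr):
            raise ValueError(f"architecture mismatch on {attr!r}")
    if cfg.max_epochs == 0:
        out = dict(checkpoint)
        out["config"] = cfg
        out["log"] = pd.DataFrame([])
        return out
    return train_model(cfg, samples, manifest, initial_state=checkpoint["state"])


# ---------------------------------------------------------------------------
# checkpoint I/O
# ---------------------------------------------------------------------------

def save_checkpoint(checkpoint: dict, path) -> Path:
    """Serialise a checkpoint to a single .npz with config embedded."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"state/{k}": v for k, v in checkpoint["state"].items()}
    meta = {
        "config": checkpoint["config"].to_json(),
        "stats": checkpoint["stats"].to_json(),
        "crop_shape": list(checkpoint["crop_shape"]) if checkpoint.get("crop_shape") else None,
        "split": checkpoint.get("split"),
        "best_epoch": checkpoint.get("best_epoch", -1),
        "best_val_loss": checkpoint.get("best_val_loss", float("nan")),
        "rng_state": checkpoint.get("rng_state"),
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    arrays["class_weights"] = checkpoint["class_weights"]
    log: pd.DataFrame = checkpoint.get("log", pd.DataFrame([]))
    buf = io.StringIO()
    log.to_csv(buf, index=False)
    arrays["log_csv"] = np.frombuffer(buf.getvalue().encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_checkpoint(path) -> dict:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        state = {k[len("state/"):]: data[k] for k in data.files if k.startswith("state/")}
        log_text = bytes(data["log_csv"]).decode()
        cw = data["class_weights"]
    cfg = TrainConfig.from_json(meta["config"])
    return {
        "state": state,
        "config": cfg,
        "stats": NormalizationStats.from_json(meta["stats"]),
        "crop_shape": tuple(meta["crop_shape"]) if meta["crop_shape"] else None,
        "class_weights": cw,
        "split": meta.get("split"),
        "log": pd.read_csv(io.StringIO(log_text)) if log_text.strip() else pd.DataFrame([]),
        "best_epoch": meta.get("best_epoch", -1),
        "best_val_loss": meta.get("best_val_loss", float("nan")),
        "rng_state": meta.get("rng_state"),
    }


def model_from_checkpoint(checkpoint: dict) -> MultiTaskModel:
    cfg: TrainConfig = checkpoint["config"]
    input_shape = (checkpoint["crop_shape"] if cfg.approach == "bb_crop"
                   else cfg.input_shape)
    model = _build_model(cfg, input_shape)
    model.load_state_dict(checkpoint["state"])
    model.eval()
    return model
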