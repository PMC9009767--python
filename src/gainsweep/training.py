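"""Backbone pre-training and per-condition head fine-tuning.

The protocol mirrors the arousal experiments: a backbone representation
is learned once, at neutral gain (delta = 1), on a generic synthetic
category task; each experimental condition (difficulty level or
answer-option set) then gets its own sigmoidal output head fine-tuned on
the *pooled final-block features* of the frozen backbone, again at
delta = 1, once per model instance (seed). Heads are plain affine maps
on the features, so a trained head can be evaluated at any gain state by
re-extracting features with the desired delta and applying the head.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .backbone import (BackboneConfig, BackboneModel, adapt_norm_stats,
                       batched_features, set_gain_state, set_global_gain)
from .images import LabeledDataset
from .nn import F32


class TrainingError(RuntimeError):
    pass


class IntegrityError(RuntimeError):
    """Raised when the frozen-backbone contract is violated."""


@dataclass(frozen=True)
class PretrainConfig:
    epochs: int = 15
    batch_size: int = 32
    lr: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 1e-4
    seed: int = 0
    # input augmentation: pixel noise and contrast/brightness jitter give the
    # representation some tolerance to response-magnitude shifts, so gain
    # sweeps degrade gradually instead of cliff-dropping
    noise_sd: float = 0.1
    contrast_jitter: float = 0.3
    brightness_jitter: float = 0.1
    # mixup: convex image blends with soft labels force deep features to
    # encode mixture proportions — the cue the fine-grained blend
    # discrimination rests on (large-scale natural-image training confers
    # this sensitivity on its own; mixup restores it at desk scale)
    mixup_alpha: float = 0.4
    mixup_prob: float = 0.5
    # per-channel colour jitter makes raw colour means an unreliable cue,
    # pushing the representation toward texture/structure — which image
    # averaging destroys, as large-scale natural-image features do
    color_jitter: float = 0.3


def _augment(x: np.ndarray, rng: np.random.Generator, cfg: "PretrainConfig") -> np.ndarray:
    n = len(x)
    out = x
    if cfg.contrast_jitter or cfg.brightness_jitter:
        c = rng.uniform(1 - cfg.contrast_jitter, 1 + cfg.contrast_jitter, size=(n, 1, 1, 1))
        b = rng.uniform(-cfg.brightness_jitter, cfg.brightness_jitter, size=(n, 1, 1, 1))
        mean = out.mean(axis=(1, 2, 3), keepdims=True)
        out = (out - mean) * c + mean + b
    if cfg.color_jitter:
        # x is NCHW: scale each image's channels independently
        cj = rng.uniform(1 - cfg.color_jitter, 1 + cfg.color_jitter,
                         size=(n, out.shape[1], 1, 1))
        out = out * cj
    if cfg.noise_sd:
        out = out + rng.normal(0.0, cfg.noise_sd, size=out.shape)
    return out.astype(F32)


@dataclass(frozen=True)
class HeadConfig:
    n_instances: int = 10
    epochs: int = 15
    batch_size: int = 32
    lr: float = 0.5
    seed: int = 0
    # each instance fine-tunes on its own random subsample of the training
    # set, giving instances the independent-run variability that a shared
    # frozen backbone otherwise suppresses
    subsample: float = 0.8


@dataclass
class TaskHead:
    """Sigmoidal output node for one condition, one model instance.

    ``w`` and ``b`` act on raw pooled features (feature standardisation
    is folded in after training), so the head is a fixed affine readout
    across gain states.
    """

    condition: object
    instance: int
    w: np.ndarray
    b: float
    backbone_hash: str
    delta_trained: float = 1.0
    val_accuracy: Optional[float] = None

    def logits(self, features: np.ndarray) -> np.ndarray:
        return features @ self.w + self.b

    def predict(self, features: np.ndarray) -> np.ndarray:
        return (self.logits(features) > 0).astype(np.int64)

    def weight_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.w, dtype=F32).tobytes())
        h.update(np.float32(self.b).tobytes())
        return h.hexdigest()


@dataclass
class CategoryHead:
    """Multi-unit sigmoid head over a category subset (one per option set)."""

    condition: object
    instance: int
    classes: Tuple[int, ...]
    w: np.ndarray  # (n_features, n_classes)
    b: np.ndarray  # (n_classes,)
    backbone_hash: str
    delta_trained: float = 1.0

    def scores(self, features: np.ndarray) -> np.ndarray:
        return nn.sigmoid(features @ self.w + self.b)


# ------------------------------------------------------------------ pretraining

def _accuracy_from_logits(logits: np.ndarray, labels: np.ndarray) -> float:
    return float((logits.argmax(axis=1) == labels).mean())


def pretrain_backbone(
    data: Dict[str, LabeledDataset],
    config: PretrainConfig,
    backbone_config: Optional[BackboneConfig] = None,
) -> Tuple[BackboneModel, List[Dict[str, float]]]:
    """Train a backbone (and its category head) from scratch at delta = 1.

    ``data`` must provide 'train' and 'val' splits of a category
    dataset. Returns the trained model and a per-epoch history of loss
    and held-out accuracy. Raises :class:`TrainingError` on divergence.
    """
    train, val = data["train"], data["val"]
    n_classes = int(train.labels.max()) + 1
    bc = backbone_config or BackboneConfig(
        image_size=train.images.shape[1], n_classes=n_classes
    )
    if bc.n_classes != n_classes:
        bc = replace(bc, n_classes=n_classes)
    model = BackboneModel(bc, seed=config.seed)
    set_global_gain(model, 1.0)

    x_train = train.as_nchw()
    y_train = train.labels
    x_val = val.as_nchw()
    rng = np.random.default_rng(config.seed)
    opt = nn.SGD(model.params(), lr=config.lr, momentum=config.momentum,
                 weight_decay=config.weight_decay)
    history: List[Dict[str, float]] = []
    for epoch in range(config.epochs):
        lr = nn.cosine_lr(config.lr, epoch, config.epochs)
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = _augment(np.ascontiguousarray(x_train[idx]), rng, config)
            yb = np.eye(n_classes, dtype=F32)[y_train[idx]]
            if config.mixup_alpha > 0 and rng.uniform() < config.mixup_prob:
                lam = rng.beta(config.mixup_alpha, config.mixup_alpha)
                perm = rng.permutation(len(xb))
                xb = lam * xb + (1.0 - lam) * xb[perm]
                yb = lam * yb + (1.0 - lam) * yb[perm]
            _, logits = model.forward(xb.astype(F32), train=True)
            loss, glogits = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(glogits)
            opt.step(lr)
            losses.append(loss)
        val_logits = _eval_logits(model, x_val)
        history.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "val_accuracy": _accuracy_from_logits(val_logits, val.labels),
            }
        )
    # enter the canonical neutral gain state: statistics re-estimated at
    # delta = 1 on the training images (deterministic, order-fixed)
    adapt_norm_stats(model, x_train)
    model.meta["delta_trained"] = 1.0
    model.meta["pretrain_final_loss"] = history[-1]["loss"]
    return model, history


def _eval_logits(model: BackboneModel, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
    parts = []
    for start in range(0, len(x), batch_size):
        _, logits = model.forward(
            np.ascontiguousarray(x[start : start + batch_size]), train=False
        )
        parts.append(logits)
    return np.concatenate(parts)


# ------------------------------------------------------------- head fine-tuning

def _train_affine_head(
    feats: np.ndarray,
    targets: np.ndarray,
    config: HeadConfig,
    seed: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """SGD logistic fit on standardised features; returns the affine map
    folded back onto raw feature space. ``targets`` may be a vector
    (binary head) or (n, m) matrix (multi-unit sigmoid head)."""
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0) + 1e-6
    z = (feats - mu) / sd
    t2 = targets[:, None] if targets.ndim == 1 else targets
    m = t2.shape[1]
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, 0.01, size=(z.shape[1], m)).astype(F32)
    b = np.zeros(m, dtype=F32)
    n = len(z)
    for epoch in range(config.epochs):
        lr = nn.cosine_lr(config.lr, epoch, config.epochs)
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            p = nn.sigmoid(z[idx] @ w + b)
            g = (p - t2[idx]) / len(idx)
            w -= lr * (z[idx].T @ g).astype(F32)
            b -= lr * g.sum(axis=0).astype(F32)
    # fold standardisation into the affine readout
    w_raw = (w / sd[:, None]).astype(F32)
    b_raw = (b - (mu / sd) @ w).astype(F32)
    if targets.ndim == 1:
        return w_raw[:, 0], b_raw[0]
    return w_raw, b_raw


def finetune_head(
    backbone: BackboneModel,
    data: Dict[str, LabeledDataset],
    config: HeadConfig,
    condition: object = None,
    calib: Optional[np.ndarray] = None,
) -> List[TaskHead]:
    """Fine-tune ``n_instances`` independent binary heads for one
    difficulty condition at delta = 1; the backbone stays frozen
    (verified by checkpoint hash).

    By default the neutral gain state is calibrated on the condition's
    own training images, defining the baseline the gain sweep of that
    condition is compared against."""
    if calib is None:
        calib = data["train"].as_nchw()
    set_gain_state(backbone, 1.0, calib)
    hash_before = backbone.weight_hash()
    feats_train = batched_features(backbone, data["train"].as_nchw())
    feats_val = batched_features(backbone, data["val"].as_nchw())
    heads = []
    labels_train = data["train"].labels.astype(F32)
    for instance in range(config.n_instances):
        seed = int(np.random.SeedSequence([config.seed, instance]).generate_state(1)[0] % (2**31))
        inst_rng = np.random.default_rng(seed)
        n_sub = max(2, int(round(config.subsample * len(feats_train))))
        sub = inst_rng.permutation(len(feats_train))[:n_sub]
        w, b = _train_affine_head(feats_train[sub], labels_train[sub],
                                  config, seed)
        head = TaskHead(
            condition=condition, instance=instance, w=w, b=float(b),
            backbone_hash=hash_before, delta_trained=1.0,
        )
        head.val_accuracy = float(
            (head.predict(feats_val) == data["val"].labels).mean()
        )
        heads.append(head)
    if backbone.weight_hash() != hash_before:
        raise IntegrityError("backbone weights changed during head fine-tuning")
    return heads


def finetune_category_head(
    backbone: BackboneModel,
    data: Dict[str, LabeledDataset],
    classes: Sequence[int],
    config: HeadConfig,
    instance: int = 0,
    condition: object = None,
) -> CategoryHead:
    """One multi-unit sigmoid head restricted to a category subset,
    trained one-vs-all on images of those categories only."""
    classes = tuple(int(c) for c in classes)
    set_gain_state(backbone, 1.0, data["train"].as_nchw())
    hash_before = backbone.weight_hash()
    train = data["train"]
    mask = np.isin(train.labels, classes)
    feats = batched_features(backbone, train.as_nchw()[mask])
    labels = train.labels[mask]
    targets = np.stack([(labels == c).astype(F32) for c in classes], axis=1)
    seed = int(
        np.random.SeedSequence(
            [config.seed, instance, len(classes), hash(classes) % (2**31)]
        ).generate_state(1)[0] % (2**31)
    )
    w, b = _train_affine_head(feats, targets, config, seed)
    if backbone.weight_hash() != hash_before:
        raise IntegrityError("backbone weights changed during head fine-tuning")
    return CategoryHead(
        condition=condition, instance=instance, classes=classes,
        w=w, b=b, backbone_hash=hash_before,
    )


def subsample_answer_options(
    categories: Sequence[int],
    sizes: Sequence[int] = (2, 4, 8),
    n_iterations: int = 20,
    seed: int = 0,
) -> Dict[int, List[Tuple[int, ...]]]:
    """Random answer-option subsets per set size.

    For each size below the full category count, ``n_iterations``
    independent draws (duplicate subsets across iterations allowed,
    categories within a draw distinct); the full size yields the single
    complete set.
    """
    categories = [int(c) for c in categories]
    rng = np.random.default_rng(seed)
    out: Dict[int, List[Tuple[int, ...]]] = {}
    for size in sizes:
        if size > len(categories):
            raise ValueError(f"size {size} exceeds {len(categories)} categories")
        if size == len(categories):
            out[size] = [tuple(categories)]
        else:
            out[size] = [
                tuple(sorted(rng.choice(categories, size=size, replace=False)))
                for _ in range(n_iterations)
            ]
    return out
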