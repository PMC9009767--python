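"""Residual convolutional backbone with a single global-gain parameter.

The architecture mirrors the block structure of a first-generation
ResNet18 — a convolutional stem followed by ``B`` residual blocks
(default 8), each holding a residual branch (conv-bn-act-conv-bn) and a
skip branch (identity, or 1x1 projection on down-sampling) whose sum is
passed through a final activation. That final activation is the block's
*tap point*: the tensor recorded for decoding probes and mean-activation
profiles, and the tensor whose residual-branch input can be spatially
scrambled.

Every activation site — the stem activation and both activations of
every block — shares one :class:`GlobalGainState`, so a single scalar
``delta`` shifts the gain of the whole hierarchy at once.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .activations import ActivationSpec, GlobalGainState
from . import nn
from .nn import F32


@dataclass(frozen=True)
class BackboneConfig:
    image_size: int = 64
    in_channels: int = 3
    stem_width: int = 16
    widths: Tuple[int, ...] = (16, 16, 32, 32, 64, 64, 128, 128)
    strides: Tuple[int, ...] = (1, 1, 2, 1, 2, 1, 2, 1)
    n_classes: int = 8
    norm: str = "batch"  # "batch" (statistics recalibrated per gain state)
                         # or "none" (biased convolutions, no normalisation)
    activation: ActivationSpec = field(default_factory=ActivationSpec)

    def __post_init__(self):
        if len(self.widths) != len(self.strides):
            raise ValueError("widths and strides must have equal length")

    @property
    def n_blocks(self) -> int:
        return len(self.widths)

    def to_json(self) -> str:
        d = {
            "image_size": self.image_size,
            "in_channels": self.in_channels,
            "stem_width": self.stem_width,
            "widths": list(self.widths),
            "strides": list(self.strides),
            "n_classes": self.n_classes,
            "norm": self.norm,
            "activation_kind": self.activation.kind,
            "a_max": self.activation.a_max,
        }
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "BackboneConfig":
        d = json.loads(s)
        return cls(
            image_size=d["image_size"],
            in_channels=d["in_channels"],
            stem_width=d["stem_width"],
            widths=tuple(d["widths"]),
            strides=tuple(d["strides"]),
            n_classes=d["n_classes"],
            norm=d.get("norm", "batch"),
            activation=ActivationSpec(kind=d["activation_kind"], a_max=d["a_max"]),
        )


class ResidualBlock:
    """conv[-norm]-act-conv[-norm] residual branch, skip branch, merged
    activation. With ``norm="none"`` convolutions carry biases and the
    residual branch is scaled at init to keep forward variance bounded."""

    def __init__(self, c_in: int, c_out: int, stride: int,
                 spec: ActivationSpec, gain: GlobalGainState,
                 rng: np.random.Generator, norm: str = "batch"):
        if norm not in ("batch", "none"):
            raise ValueError(f"unknown norm {norm!r}")
        self.norm = norm
        use_bias = norm == "none"
        self.conv1 = nn.Conv2d(c_in, c_out, 3, stride, bias=use_bias, rng=rng)
        self.bn1 = nn.BatchNorm2d(c_out) if norm == "batch" else None
        self.act1 = nn.GainedActivation(spec, gain)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, 1, bias=use_bias, rng=rng)
        self.bn2 = nn.BatchNorm2d(c_out) if norm == "batch" else None
        if norm == "none":
            # temper residual growth across depth
            self.conv2.w.value *= 0.5
        self.act2 = nn.GainedActivation(spec, gain)
        self.project = stride != 1 or c_in != c_out
        if self.project:
            self.proj = nn.Conv2d(c_in, c_out, 1, stride, bias=use_bias, rng=rng)
            self.bnp = nn.BatchNorm2d(c_out) if norm == "batch" else None

    def sublayers(self):
        layers = [("conv1", self.conv1), ("conv2", self.conv2)]
        if self.project:
            layers.append(("proj", self.proj))
        if self.norm == "batch":
            layers += [("bn1", self.bn1), ("bn2", self.bn2)]
            if self.project:
                layers.append(("bnp", self.bnp))
        return layers

    def params(self):
        for lname, layer in self.sublayers():
            for pname, p in layer.params():
                yield f"{lname}.{pname}", p

    def forward(self, x: np.ndarray, train: bool = False,
                scramble=None) -> np.ndarray:
        """``scramble``: optional callable applied to the residual-branch
        output before it is merged with the skip branch."""
        r = self.conv1.forward(x, train)
        if self.bn1 is not None:
            r = self.bn1.forward(r, train)
        r = self.act1.forward(r, train)
        r = self.conv2.forward(r, train)
        if self.bn2 is not None:
            r = self.bn2.forward(r, train)
        if scramble is not None:
            r = scramble(r)
        if self.project:
            s = self.proj.forward(x, train)
            if self.bnp is not None:
                s = self.bnp.forward(s, train)
        else:
            s = x
        return self.act2.forward(r + s, train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.act2.backward(gy)
        gr = self.bn2.backward(g) if self.bn2 is not None else g
        gr = self.conv2.backward(gr)
        gr = self.act1.backward(gr)
        if self.bn1 is not None:
            gr = self.bn1.backward(gr)
        gx = self.conv1.backward(gr)
        if self.project:
            gp = self.bnp.backward(g) if self.bnp is not None else g
            gx = gx + self.proj.backward(gp)
        else:
            gx = gx + g
        return gx


class BackboneModel:
    """Gain-augmented residual backbone with an attached pre-training head.

    The pre-training head (global average pool + dense) is only used to
    learn the backbone representation; the task heads of the arousal
    experiments are trained separately on the pooled final-block
    features (see :mod:`gainsweep.training`).
    """

    def __init__(self, config: BackboneConfig, seed: int = 0):
        self.config = config
        self.gain = GlobalGainState(1.0)
        rng = np.random.default_rng(seed)
        spec = config.activation
        self.stem_conv = nn.Conv2d(config.in_channels, config.stem_width, 3, 1,
                                   bias=config.norm == "none", rng=rng)
        self.stem_bn = nn.BatchNorm2d(config.stem_width) if config.norm == "batch" else None
        self.stem_act = nn.GainedActivation(spec, self.gain)
        self.blocks: List[ResidualBlock] = []
        c_in = config.stem_width
        for w, s in zip(config.widths, config.strides):
            self.blocks.append(
                ResidualBlock(c_in, w, s, spec, self.gain, rng, norm=config.norm)
            )
            c_in = w
        self.pool = nn.GlobalAvgPool()
        self.head = nn.Dense(c_in, config.n_classes, rng=rng)
        self.meta: Dict[str, object] = {"delta_trained": 1.0}

    # ------------------------------------------------------------------ params
    def params(self, include_head: bool = True):
        for pname, p in self.stem_conv.params():
            yield f"stem_conv.{pname}", p
        if self.stem_bn is not None:
            for pname, p in self.stem_bn.params():
                yield f"stem_bn.{pname}", p
        for i, block in enumerate(self.blocks):
            for pname, p in block.params():
                yield f"block{i + 1}.{pname}", p
        if include_head:
            for pname, p in self.head.params():
                yield f"head.{pname}", p

    def _stateful_layers(self):
        yield "stem_conv", self.stem_conv
        if self.stem_bn is not None:
            yield "stem_bn", self.stem_bn
        for i, block in enumerate(self.blocks):
            for lname, layer in block.sublayers():
                yield f"block{i + 1}.{lname}", layer
        yield "head", self.head

    def state_dict(self) -> Dict[str, np.ndarray]:
        out = {}
        for lname, layer in self._stateful_layers():
            for sname, arr in layer.state().items():
                out[f"{lname}.{sname}"] = arr
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for lname, layer in self._stateful_layers():
            sub = {
                sname: state[f"{lname}.{sname}"]
                for sname in layer.state()
            }
            layer.load_state(sub)

    def weight_hash(self) -> str:
        """SHA-256 over all learned parameters, in fixed order.

        The gain scalar and the normalisation statistics are deliberately
        excluded: entering a gain state (delta plus recalibrated
        statistics) must leave the checkpoint identity untouched.
        """
        h = hashlib.sha256()
        params = dict(self.params())
        for name in sorted(params):
            h.update(name.encode())
            h.update(np.ascontiguousarray(params[name].value, dtype=F32).tobytes())
        return h.hexdigest()

    # ----------------------------------------------------------------- forward
    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        return_taps: bool = False,
        scramble_fns: Optional[Dict[int, object]] = None,
    ):
        """Forward pass on an NCHW float32 batch.

        Returns ``(features, logits)`` or, with ``return_taps``,
        ``(taps, features, logits)`` where ``taps`` maps block index
        (1-based) to that block's output tensor. ``scramble_fns`` maps
        block index to a callable perturbing that block's residual
        branch.
        """
        if x.ndim != 4 or x.shape[1:] != (
            self.config.in_channels, self.config.image_size, self.config.image_size
        ):
            raise ValueError(
                f"input shape {x.shape} does not match model input "
                f"(N, {self.config.in_channels}, {self.config.image_size}, "
                f"{self.config.image_size})"
            )
        scramble_fns = scramble_fns or {}
        h = self.stem_conv.forward(x, train)
        if self.stem_bn is not None:
            h = self.stem_bn.forward(h, train)
        h = self.stem_act.forward(h, train)
        taps: Dict[int, np.ndarray] = {}
        for i, block in enumerate(self.blocks, start=1):
            h = block.forward(h, train=train, scramble=scramble_fns.get(i))
            if return_taps:
                taps[i] = h
        feats = self.pool.forward(h, train)
        logits = self.head.forward(feats, train)
        if return_taps:
            return taps, feats, logits
        return feats, logits

    def backward(self, glogits: np.ndarray) -> None:
        g = self.head.backward(glogits)
        g = self.pool.backward(g)
        for block in reversed(self.blocks):
            g = block.backward(g)
        g = self.stem_act.backward(g)
        if self.stem_bn is not None:
            g = self.stem_bn.backward(g)
        self.stem_conv.backward(g)

    # -------------------------------------------------------------- checkpoint
    def save(self, path) -> None:
        state = self.state_dict()
        meta = dict(self.meta)
        meta["config"] = self.config.to_json()
        meta["weight_hash"] = self.weight_hash()
        np.savez(path, __meta__=json.dumps(meta), **state)

    @classmethod
    def load(cls, path) -> "BackboneModel":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["__meta__"]))
            state = {k: f[k] for k in f.files if k != "__meta__"}
        model = cls(BackboneConfig.from_json(meta["config"]))
        model.load_state_dict(state)
        model.meta = {k: v for k, v in meta.items() if k not in ("config",)}
        return model


def set_global_gain(model: BackboneModel, delta: float) -> BackboneModel:
    """Set the shared gain scalar of every activation site; weights untouched."""
    model.gain.set(delta)
    return model


def _norm_layers(model: BackboneModel):
    for _, layer in model._stateful_layers():
        if isinstance(layer, nn.BatchNorm2d):
            yield layer


def adapt_norm_stats(
    model: BackboneModel,
    calib: np.ndarray,
    batch_size: int = 128,
    passes: int = 2,
) -> BackboneModel:
    """Re-estimate normalisation statistics under the current gain state.

    Cortical normalisation is homeostatic: it tracks the prevailing
    level of drive rather than staying pinned to the statistics of the
    neutral state. Operationally, each pass forwards the calibration
    images (NCHW) in batch-statistics mode while the running mean and
    variance of every normalisation layer are replaced by the
    equal-weight average over batches; a second pass refines the
    estimates under the already-updated upstream statistics. The
    procedure is deterministic given the calibration array and batch
    size. Learned weights are untouched. No-op for norm-free models.
    """
    norm_layers = list(_norm_layers(model))
    if not norm_layers:
        return model
    for _ in range(passes):
        for layer in norm_layers:
            layer.begin_adapt()
        for start in range(0, len(calib), batch_size):
            xb = np.ascontiguousarray(calib[start : start + batch_size], dtype=F32)
            model.forward(xb, train=True)
        for layer in norm_layers:
            layer.end_adapt()
    return model


def set_gain_state(
    model: BackboneModel,
    delta: float,
    calib: Optional[np.ndarray] = None,
    batch_size: int = 128,
    passes: int = 2,
) -> BackboneModel:
    """Enter a gain state: set delta and recalibrate normalisation.

    With ``calib`` images the normalisation statistics are re-estimated
    under the new gain (see :func:`adapt_norm_stats`); without them only
    the gain scalar changes (frozen-statistics mode)."""
    set_global_gain(model, delta)
    if calib is not None:
        adapt_norm_stats(model, calib, batch_size=batch_size, passes=passes)
    return model


def snapshot_norm_stats(model: BackboneModel) -> List[Tuple[np.ndarray, np.ndarray]]:
    return [
        (layer.running_mean.copy(), layer.running_var.copy())
        for layer in _norm_layers(model)
    ]


def restore_norm_stats(model: BackboneModel, snap) -> None:
    for layer, (mean, var) in zip(_norm_layers(model), snap):
        layer.running_mean[...] = mean
        layer.running_var[...] = var


class GainStateCache:
    """Pre-computed normalisation statistics for every gain state of a grid.

    Re-estimating statistics is the expensive part of entering a gain
    state; since they depend only on (delta, calibration set), they are
    computed once per grid point and restored on demand — e.g. across
    the repetitions and stages of a scrambling experiment.
    """

    def __init__(self, model: BackboneModel, deltas, calib: Optional[np.ndarray],
                 batch_size: int = 128, passes: int = 2):
        self.model = model
        self.snapshots: Dict[float, object] = {}
        if calib is not None and list(_norm_layers(model)):
            for delta in deltas:
                set_gain_state(model, float(delta), calib,
                               batch_size=batch_size, passes=passes)
                self.snapshots[float(delta)] = snapshot_norm_stats(model)

    def enter(self, delta: float) -> BackboneModel:
        set_global_gain(self.model, delta)
        snap = self.snapshots.get(float(delta))
        if snap is not None:
            restore_norm_stats(self.model, snap)
        return self.model

    def neutral(self) -> BackboneModel:
        return self.enter(1.0)


def forward_with_taps(
    model: BackboneModel,
    batch: np.ndarray,
    batch_size: int = 128,
    scramble_fns: Optional[Dict[int, object]] = None,
) -> Tuple[Dict[int, np.ndarray], np.ndarray, np.ndarray]:
    """Evaluate a batch in eval mode, returning per-block taps, pooled
    features and head scores. Minibatched to bound memory."""
    taps_parts: Dict[int, List[np.ndarray]] = {}
    feat_parts, logit_parts = [], []
    for start in range(0, len(batch), batch_size):
        xb = np.ascontiguousarray(batch[start : start + batch_size], dtype=F32)
        taps, feats, logits = model.forward(
            xb, train=False, return_taps=True, scramble_fns=scramble_fns
        )
        for i, t in taps.items():
            taps_parts.setdefault(i, []).append(t)
        feat_parts.append(feats)
        logit_parts.append(logits)
    taps_full = {i: np.concatenate(parts) for i, parts in taps_parts.items()}
    return taps_full, np.concatenate(feat_parts), np.concatenate(logit_parts)


def batched_features(model: BackboneModel, batch: np.ndarray,
                     batch_size: int = 128,
                     scramble_fns: Optional[Dict[int, object]] = None) -> np.ndarray:
    """Pooled final-block features in eval mode (no tap retention)."""
    parts = []
    for start in range(0, len(batch), batch_size):
        xb = np.ascontiguousarray(batch[start : start + batch_size], dtype=F32)
        feats, _ = model.forward(xb, train=False, scramble_fns=scramble_fns)
        parts.append(feats)
    return np.concatenate(parts)
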