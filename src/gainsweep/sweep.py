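"""Performance-gain profiles: sweeping delta and summarising peaks.

A profile is a tidy long-format DataFrame with one row per
(condition, instance, delta, metric): the building block behind
inverted-U ("Yerkes-Dodson") analyses. Peaks are extracted per model
instance; ties across gain states are summarised by their median, and
the across-instance summary is the median peak with a Student-t 95 %
interval on the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .backbone import (BackboneModel, GainStateCache, batched_features,
                       set_gain_state, set_global_gain)
from .images import LabeledDataset
from .metrics import SDTCounts, auc_score, sdt_measures, summarize_ci
from .training import CategoryHead, TaskHead

__all__ = ["GainGrid", "PeakEstimate", "sweep", "sweep_category", "find_peak"]


@dataclass(frozen=True)
class GainGrid:
    """Strictly increasing gain values, always containing exactly 1.0."""

    values: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.size == 0 or np.any(v <= 0):
            raise ValueError("gain values must be positive")
        if np.any(np.diff(v) <= 0):
            raise ValueError("gain values must be strictly increasing")
        if not np.any(v == 1.0):
            raise ValueError("gain grid must contain the neutral state 1.0")

    @classmethod
    def geometric(cls, lo: float = 0.125, hi: float = 8.0, n: int = 60) -> "GainGrid":
        """Geometrically spaced grid (gain acts multiplicatively), with
        the point nearest 1.0 snapped to exactly 1.0."""
        if not (0 < lo < 1.0 < hi):
            raise ValueError("need lo < 1 < hi")
        v = np.geomspace(lo, hi, n)
        v[np.argmin(np.abs(np.log(v)))] = 1.0
        return cls(tuple(float(x) for x in v))

    def lower_half(self) -> "GainGrid":
        """The sub-grid of gains <= 1 (the limited-range analysis)."""
        return GainGrid(tuple(v for v in self.values if v <= 1.0))

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


@dataclass
class PeakEstimate:
    """Best-performing gain per instance and its across-instance summary."""

    per_instance: pd.DataFrame  # columns: instance, peak_delta
    median: float
    mean: float
    ci_low: float
    ci_high: float
    metric: str

    @property
    def peaks(self) -> np.ndarray:
        return self.per_instance["peak_delta"].to_numpy()


def _binary_rows(head: TaskHead, feats: np.ndarray, labels: np.ndarray,
                 delta: float, condition) -> List[dict]:
    preds = head.predict(feats)
    signal = labels == 1
    counts = SDTCounts(
        hits=int((preds[signal] == 1).sum()),
        misses=int((preds[signal] == 0).sum()),
        fa=int((preds[~signal] == 1).sum()),
        cr=int((preds[~signal] == 0).sum()),
    )
    dprime, criterion = sdt_measures(counts)
    base = {"condition": condition, "instance": head.instance, "delta": delta}
    vals = {
        "accuracy": float((preds == labels).mean()),
        "hit_rate": counts.hits / counts.n_signal,
        "fa_rate": counts.fa / counts.n_noise,
        "dprime": dprime,
        "criterion": criterion,
    }
    return [dict(base, metric=m, value=v) for m, v in vals.items()]


def sweep(
    backbone: BackboneModel,
    heads: Sequence[TaskHead],
    dataset: LabeledDataset,
    grid: GainGrid,
    scramble_fns: Optional[Dict[int, object]] = None,
    condition: object = None,
    calib: Optional[np.ndarray] = None,
    states: Optional[GainStateCache] = None,
) -> pd.DataFrame:
    """Evaluate binary heads over the gain grid on a held-out set.

    Entering a gain state sets delta and, when calibration images (or a
    pre-computed :class:`GainStateCache`) are supplied, re-estimates the
    normalisation statistics under that gain. The backbone forward is
    shared across heads at each delta (heads are affine readouts of the
    pooled features); the backbone is restored to the neutral state
    afterwards.
    """
    x = dataset.as_nchw()
    if states is None:
        states = GainStateCache(backbone, grid, calib)
    rows: List[dict] = []
    try:
        for delta in grid:
            states.enter(delta)
            feats = batched_features(backbone, x, scramble_fns=scramble_fns)
            for head in heads:
                cond = condition if condition is not None else head.condition
                rows.extend(_binary_rows(head, feats, dataset.labels, delta, cond))
    finally:
        states.neutral()
    return pd.DataFrame(rows)


def sweep_category(
    backbone: BackboneModel,
    heads: Sequence[CategoryHead],
    dataset: LabeledDataset,
    grid: GainGrid,
    calib: Optional[np.ndarray] = None,
    states: Optional[GainStateCache] = None,
) -> pd.DataFrame:
    """AUC-vs-gain profiles for answer-option heads.

    Each head is scored only on test images of its own category subset,
    with the one-vs-rest AUC averaged over the subset's categories.
    """
    x = dataset.as_nchw()
    if states is None:
        states = GainStateCache(backbone, grid, calib)
    rows: List[dict] = []
    try:
        for delta in grid:
            states.enter(delta)
            feats = batched_features(backbone, x)
            for head in heads:
                mask = np.isin(dataset.labels, head.classes)
                scores = head.scores(feats[mask])
                remap = {c: j for j, c in enumerate(head.classes)}
                labels = np.array([remap[int(l)] for l in dataset.labels[mask]])
                rows.append(
                    {
                        "condition": head.condition,
                        "instance": head.instance,
                        "delta": delta,
                        "metric": "auc",
                        "value": auc_score(scores, labels),
                    }
                )
    finally:
        states.neutral()
    return pd.DataFrame(rows)


def find_peak(
    profile: pd.DataFrame,
    metric: str = "accuracy",
    mode: Optional[str] = None,
    instance_col: str = "instance",
) -> PeakEstimate:
    """Best-gain summary of a performance profile.

    Per instance, the set of deltas attaining the best value of the
    metric (maximum, or minimum |value| for the criterion, where "best"
    means bias closest to zero) is summarised by its median; across
    instances the median and a Student-t 95 % CI on the mean are
    reported.
    """
    if profile.empty:
        raise ValueError("empty profile")
    sub = profile[profile["metric"] == metric] if "metric" in profile else profile
    if sub.empty:
        raise ValueError(f"metric {metric!r} not present in profile")
    if mode is None:
        mode = "absmin" if metric == "criterion" else "max"

    peaks = []
    for instance, g in sub.groupby(instance_col):
        v = g["value"].to_numpy()
        d = g["delta"].to_numpy()
        key = -np.abs(v) if mode == "absmin" else v
        best = key == key.max()
        peaks.append({"instance": instance, "peak_delta": float(np.median(d[best]))})
    per_instance = pd.DataFrame(peaks)
    arr = per_instance["peak_delta"].to_numpy()
    if arr.size >= 2:
        mean, lo, hi = summarize_ci(arr)
    else:
        mean = lo = hi = float(arr[0])
    return PeakEstimate(
        per_instance=per_instance,
        median=float(np.median(arr)),
        mean=mean,
        ci_low=lo,
        ci_high=hi,
        metric=metric,
    )
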