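"""Spatial scrambling: a causal perturbation of residual-branch features.

Scrambling permutes the spatial positions within a chosen proportion
``p`` of a block's residual-branch feature maps, independently per map
and per image. Each scrambled map keeps its exact value multiset — its
mean, variance, whole distribution — but loses its spatial layout, so
the perturbation removes information without injecting energy (unlike
dropout or lesioning). Importance curves (performance vs ``p`` at
neutral gain) calibrate a per-block rate ``p*`` at which every block
retains the same small fraction of its performance contribution, making
progressive early->late / late->early disruption comparable across
blocks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .backbone import (BackboneModel, GainStateCache, batched_features,
                       set_gain_state, set_global_gain)
from .images import LabeledDataset
from .sweep import GainGrid, find_peak
from .training import TaskHead

__all__ = [
    "ScramblePlan",
    "ImportanceCurve",
    "CalibrationResult",
    "scramble_block",
    "Scrambler",
    "importance_curve",
    "calibrate_rate",
    "progressive_plans",
    "progressive_scramble_sweep",
]


class DegenerateBlockError(ValueError):
    """Raised when a block's unperturbed performance is not above floor."""


def scramble_block(x: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Spatially permute a random subset of ceil(p * channels) feature maps.

    Permutations are independent per selected map and per image;
    untouched maps are returned bit-identical. ``x`` is (N, C, H, W).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p == 0.0:
        return x
    n, c, h, w = x.shape
    m = int(math.ceil(p * c))
    idx = rng.choice(c, size=m, replace=False)
    out = x.copy()
    sub = out[:, idx].reshape(n * m, h * w)
    out[:, idx] = rng.permuted(sub, axis=1).reshape(n, m, h, w)
    return out


class Scrambler:
    """Seeded scrambling callable for one block.

    A fresh instance replays the identical random stream, so the same
    maps and permutations are perturbed when the same data passes
    through again (e.g. across the gain states of one repetition).
    """

    def __init__(self, p: float, seed):
        self.p = float(p)
        self.rng = np.random.default_rng(seed)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return scramble_block(x, self.p, self.rng)


@dataclass(frozen=True)
class ScramblePlan:
    """Which blocks to scramble, at what per-block proportions."""

    rates: Dict[int, float]  # block index -> proportion of maps
    direction: str = "single_block"
    stage: int = 0
    seed: int = 0

    def __post_init__(self):
        for b, p in self.rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"rate for block {b} outside [0, 1]")
        if self.direction not in ("late_to_early", "early_to_late", "single_block"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def scramblers(self, rep: int) -> Dict[int, Scrambler]:
        return {
            b: Scrambler(p, [self.seed, rep, b])
            for b, p in self.rates.items()
            if p > 0
        }


@dataclass
class ImportanceCurve:
    """Mean accuracy (with repetition SD) vs scrambling proportion for
    one block, measured at neutral gain."""

    block: int
    p_grid: np.ndarray
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    baseline: float
    chance: float = 0.5

    def smoothed(self) -> np.ndarray:
        """Isotonic non-increasing fit, taming repetition noise."""
        iso = IsotonicRegression(increasing=False)
        return iso.fit_transform(self.p_grid, self.mean_accuracy)


@dataclass(frozen=True)
class CalibrationResult:
    p_star: float
    threshold: float
    reached: bool  # False -> retention never dropped to threshold; p*=1


def importance_curve(
    backbone: BackboneModel,
    head: TaskHead,
    block: int,
    test_data: LabeledDataset,
    p_grid: Sequence[float] = tuple(np.round(np.arange(0, 1.01, 0.1), 2)),
    n_rep: int = 10,
    seed: int = 0,
    chance: float = 0.5,
    calib: Optional[np.ndarray] = None,
) -> ImportanceCurve:
    """Accuracy vs scrambling proportion for one block at delta = 1.

    ``p = 0`` is evaluated without any perturbation, anchoring the curve
    at the exact unperturbed baseline; every other point is the mean
    over ``n_rep`` repetitions differing only in permutation seed.
    """
    p_grid = np.asarray(sorted(float(p) for p in p_grid))
    if p_grid[0] != 0.0 or p_grid[-1] != 1.0:
        raise ValueError("p grid must include 0 and 1")
    set_gain_state(backbone, 1.0, calib)
    x = test_data.as_nchw()
    labels = test_data.labels
    base_feats = batched_features(backbone, x)
    baseline = float((head.predict(base_feats) == labels).mean())
    means, sds = [], []
    for p in p_grid:
        if p == 0.0:
            means.append(baseline)
            sds.append(0.0)
            continue
        accs = []
        for rep in range(n_rep):
            fns = {block: Scrambler(p, [seed, rep, block, int(p * 1000)])}
            feats = batched_features(backbone, x, scramble_fns=fns)
            accs.append(float((head.predict(feats) == labels).mean()))
        means.append(float(np.mean(accs)))
        sds.append(float(np.std(accs, ddof=1)) if n_rep > 1 else 0.0)
    return ImportanceCurve(
        block=block,
        p_grid=p_grid,
        mean_accuracy=np.asarray(means),
        sd_accuracy=np.asarray(sds),
        baseline=baseline,
        chance=chance,
    )


def calibrate_rate(curve: ImportanceCurve, threshold: float = 0.2) -> CalibrationResult:
    """Scrambling rate ``p*`` at which the block retains ``threshold``
    of its performance contribution.

    Retention is r(p) = (perf(p) - floor) / (perf(0) - floor) on the
    isotonically smoothed curve, with floor = min(perf(1), chance);
    ``p*`` is the smallest p with r(p) <= threshold, linearly
    interpolated between grid points. If retention never reaches the
    threshold the block is flagged and ``p* = 1``.
    """
    perf = curve.smoothed()
    floor = min(float(perf[-1]), curve.chance)
    top = float(perf[0])
    if top <= floor:
        raise DegenerateBlockError(
            f"block {curve.block}: unperturbed performance {top} not above floor {floor}"
        )
    r = (perf - floor) / (top - floor)
    p = curve.p_grid
    for i in range(len(p)):
        if r[i] <= threshold:
            if i == 0:
                return CalibrationResult(float(p[0]), threshold, True)
            p_star = p[i - 1] + (p[i] - p[i - 1]) * (r[i - 1] - threshold) / (
                r[i - 1] - r[i]
            )
            return CalibrationResult(float(p_star), threshold, True)
    warnings.warn(
        f"block {curve.block}: retention never reached {threshold}; using p* = 1"
    )
    return CalibrationResult(1.0, threshold, False)


def progressive_plans(
    n_blocks: int,
    direction: str,
    rates: Dict[int, float],
    seed: int = 0,
    stages: Optional[Sequence[int]] = None,
) -> List[ScramblePlan]:
    """Stage-wise block sets for progressive disruption.

    ``late_to_early`` stage s scrambles the last s blocks,
    ``early_to_late`` the first s; s runs 1..n_blocks-1 by default.
    """
    if direction not in ("late_to_early", "early_to_late"):
        raise ValueError(f"unknown direction {direction!r}")
    stages = list(stages) if stages is not None else list(range(1, n_blocks))
    plans = []
    for s in stages:
        if not 1 <= s <= n_blocks:
            raise ValueError(f"stage {s} outside 1..{n_blocks}")
        blocks = (
            range(n_blocks - s + 1, n_blocks + 1)
            if direction == "late_to_early"
            else range(1, s + 1)
        )
        plans.append(
            ScramblePlan(
                rates={b: rates[b] for b in blocks},
                direction=direction,
                stage=s,
                seed=seed,
            )
        )
    return plans


def progressive_scramble_sweep(
    backbone: BackboneModel,
    heads: Sequence[TaskHead],
    plans: Sequence[ScramblePlan],
    dataset: LabeledDataset,
    grid: GainGrid,
    n_rep: int = 10,
    calib: Optional[np.ndarray] = None,
    states: Optional[GainStateCache] = None,
) -> pd.DataFrame:
    """Gain sweep under each progressive-scrambling stage.

    For every stage plan, repetition and gain state, the scrambled model
    is evaluated on the held-out set with each instance head; a
    repetition reuses its permutation stream across gain states so the
    perturbation is paired within repetition. Long-format rows:
    direction, stage, rep, instance, delta, metric, value.
    """
    x = dataset.as_nchw()
    labels = dataset.labels
    if states is None:
        states = GainStateCache(backbone, grid, calib)
    rows: List[dict] = []
    try:
        for plan in plans:
            for rep in range(n_rep):
                for delta in grid:
                    states.enter(delta)
                    feats = batched_features(
                        backbone, x, scramble_fns=plan.scramblers(rep)
                    )
                    for head in heads:
                        acc = float((head.predict(feats) == labels).mean())
                        rows.append(
                            {
                                "direction": plan.direction,
                                "stage": plan.stage,
                                "blocks": ",".join(str(b) for b in sorted(plan.rates)),
                                "rep": rep,
                                "instance": head.instance,
                                "delta": delta,
                                "metric": "accuracy",
                                "value": acc,
                            }
                        )
    finally:
        states.neutral()
    return pd.DataFrame(rows)


def stage_peaks(profile: pd.DataFrame) -> pd.DataFrame:
    """Peak gain per stage, one peak per repetition (instances averaged
    within repetition before the median-tie peak rule)."""
    rows = []
    for (stage, rep), g in profile.groupby(["stage", "rep"]):
        mean_by_delta = g.groupby("delta", as_index=False)["value"].mean()
        v = mean_by_delta["value"].to_numpy()
        d = mean_by_delta["delta"].to_numpy()
        best = v == v.max()
        rows.append(
            {"stage": stage, "rep": rep, "peak_delta": float(np.median(d[best]))}
        )
    return pd.DataFrame(rows)
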