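"""Linear decoding probes and activation read-outs at block tap points.

A logistic-regression probe on a block's (flattened) tap activations
measures how much task information is *linearly* available at that
stage of the hierarchy, for a given gain state and difficulty. Probes
are fit on random train draws and scored on disjoint test draws;
repeated draws give the iteration spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

__all__ = [
    "decode_block",
    "mean_activation",
    "decoding_peak_gain",
    "most_informative_block",
    "InformativeBlockSummary",
]


def _flatten_and_project(
    features: np.ndarray, max_dim: int, seed: int
) -> np.ndarray:
    """Flatten per-image tap tensors; apply a seeded Gaussian random
    projection when the dimensionality exceeds ``max_dim`` (distances,
    hence probe accuracy, are preserved to first order)."""
    flat = features.reshape(len(features), -1)
    d = flat.shape[1]
    if d <= max_dim:
        return flat
    rng = np.random.default_rng(seed)
    proj = rng.standard_normal((d, max_dim)).astype(np.float32) / np.sqrt(max_dim)
    return flat @ proj


def decode_block(
    taps: np.ndarray,
    labels: np.ndarray,
    n_train: int = 1000,
    n_test: int = 1000,
    n_iter: int = 5,
    seed: int = 0,
    max_dim: int = 4096,
) -> pd.DataFrame:
    """Logistic-regression decoding of the stimulus class from one
    block's activations.

    Each iteration draws disjoint train and test sets at random from
    the supplied pool, fits a probe with default regularisation, and
    records the held-out accuracy. Draws that miss a class are redrawn
    (and counted in the ``redraws`` column).
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n_train + n_test > n:
        raise ValueError(f"pool of {n} images cannot supply {n_train}+{n_test} draws")
    feats = _flatten_and_project(np.asarray(taps, dtype=np.float32), max_dim, seed)
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iter):
        redraws = 0
        while True:
            order = rng.permutation(n)
            tr, te = order[:n_train], order[n_train : n_train + n_test]
            if (
                np.unique(labels[tr]).size >= 2
                and np.unique(labels[te]).size >= 2
            ):
                break
            redraws += 1
            if redraws > 50:
                raise ValueError("could not draw both classes; degenerate labels")
        clf = LogisticRegression(max_iter=1000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(feats[tr], labels[tr])
        acc = float(clf.score(feats[te], labels[te]))
        rows.append(
            {
                "iteration": it,
                "accuracy": acc,
                "n_train": n_train,
                "n_test": n_test,
                "redraws": redraws,
            }
        )
    return pd.DataFrame(rows)


def mean_activation(taps: Dict[int, np.ndarray]) -> Dict[int, float]:
    """Mean activation over images x channels x space, per block."""
    return {int(b): float(np.mean(t)) for b, t in taps.items()}


def _peak_delta(deltas: np.ndarray, values: np.ndarray) -> float:
    """Median of the gain states attaining the maximum value."""
    best = values == values.max()
    return float(np.median(deltas[best]))


def decoding_peak_gain(
    records: pd.DataFrame,
    ceiling_threshold: float = 0.99,
) -> Tuple[pd.DataFrame, pd.DataFrame, List[object]]:
    """Gain state of best decoding accuracy per block and difficulty.

    ``records`` needs columns block, delta, level, iteration, accuracy.
    Difficulty levels whose mean accuracy exceeds ``ceiling_threshold``
    for every block and gain state are excluded (a task solved at
    ceiling everywhere carries no peak information). Remaining peaks use
    the median tie rule on the iteration-mean accuracy; the per-block
    summary averages peaks across difficulties.
    """
    required = {"block", "delta", "level", "accuracy"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    cell = (
        records.groupby(["level", "block", "delta"], as_index=False)["accuracy"]
        .mean()
    )
    excluded = [
        level
        for level, g in cell.groupby("level")
        if (g["accuracy"] > ceiling_threshold).all()
    ]
    kept = cell[~cell["level"].isin(excluded)]
    if kept.empty:
        raise ValueError("all difficulty levels are at ceiling; nothing to summarise")
    peak_rows = [
        {
            "level": level,
            "block": block,
            "peak_delta": _peak_delta(g["delta"].to_numpy(), g["accuracy"].to_numpy()),
        }
        for (level, block), g in kept.groupby(["level", "block"])
    ]
    per_level = pd.DataFrame(peak_rows)
    per_level["excluded"] = False
    per_block = (
        per_level.groupby("block", as_index=False)["peak_delta"]
        .mean()
        .rename(columns={"peak_delta": "mean_peak_delta"})
    )
    if excluded:
        per_level = pd.concat(
            [per_level,
             pd.DataFrame([{"level": lv, "block": -1, "peak_delta": np.nan,
                            "excluded": True} for lv in excluded])],
            ignore_index=True,
        )
    return per_level, per_block, excluded


@dataclass(frozen=True)
class InformativeBlockSummary:
    """Block(s) holding the most decodable information; ties reported
    as the first and last tied block index."""

    first_best: int
    last_best: int
    accuracies: Tuple[float, ...]

    def __post_init__(self):
        if self.first_best > self.last_best:
            raise ValueError("first_best must be <= last_best")


def most_informative_block(block_accuracies: Dict[int, float]) -> InformativeBlockSummary:
    """Identify the best-decoding block from per-block mean accuracies."""
    blocks = sorted(block_accuracies)
    accs = np.array([block_accuracies[b] for b in blocks])
    best = accs == accs.max()
    tied = [blocks[i] for i in np.flatnonzero(best)]
    return InformativeBlockSummary(
        first_best=tied[0], last_best=tied[-1], accuracies=tuple(float(a) for a in accs)
    )
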