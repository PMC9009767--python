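"""Signal-detection and summary statistics for performance profiles."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy import stats


__all__ = ["SDTCounts", "sdt_measures", "auc_score", "summarize_ci"]


@dataclass(frozen=True)
class SDTCounts:
    """Trial counts of a yes/no detection experiment.

    ``hits + misses`` is the number of signal (real-image) trials,
    ``fa + cr`` the number of noise (average-image) trials.
    """

    hits: int
    misses: int
    fa: int
    cr: int

    def __post_init__(self):
        for name in ("hits", "misses", "fa", "cr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_signal(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.fa + self.cr


def _corrected_rate(count: int, n: int) -> float:
    """Rate with the 1/(2N) correction for extreme values, keeping the
    normal quantile finite."""
    r = count / n
    if r == 0.0:
        r = 1.0 / (2 * n)
    elif r == 1.0:
        r = 1.0 - 1.0 / (2 * n)
    return r


def sdt_measures(counts: SDTCounts) -> Tuple[float, float]:
    """Sensitivity d' = z(hit rate) - z(FA rate) and response criterion
    c = -0.5 (z(hit rate) + z(FA rate)).

    ``z`` is the standard-normal quantile; extreme rates 0 and 1 are
    nudged by 1/(2N) before the transform.
    """
    if counts.n_signal == 0 or counts.n_noise == 0:
        raise ValueError("need at least one signal and one noise trial")
    zh = stats.norm.ppf(_corrected_rate(counts.hits, counts.n_signal))
    zf = stats.norm.ppf(_corrected_rate(counts.fa, counts.n_noise))
    return float(zh - zf), float(-0.5 * (zh + zf))


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve.

    Binary labels with a score vector give the probability that a random
    positive outscores a random negative (ties counted 1/2). With a
    2-D score matrix (n_samples, n_classes) and integer labels, returns
    the unweighted mean of the one-vs-rest AUCs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("AUC requires at least two classes present")
    if scores.ndim == 1:
        return _binary_auc(scores, labels == labels.max())
    if scores.shape[1] != classes.size:
        # columns address the full class set; restrict to present classes
        per_class = [_binary_auc(scores[:, int(c)], labels == c) for c in classes]
    else:
        per_class = [
            _binary_auc(scores[:, j], labels == c) for j, c in enumerate(classes)
        ]
    return float(np.mean(per_class))


def _binary_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney rank formulation: exactly the pair-counting value
    (ties contribute 1/2 via midranks, which are exact in binary
    floating point)."""
    n_pos = int(positive.sum())
    n_neg = int(len(positive) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def summarize_ci(values: Sequence[float], level: float = 0.95) -> Tuple[float, float, float]:
    """Student-t confidence interval on the mean across model instances."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    if np.all(v == v[0]):
        return float(v[0]), float(v[0]), float(v[0])
    m = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(v.size))
    tcrit = float(stats.t.ppf(0.5 + level / 2, v.size - 1))
    return m, m - tcrit * sem, m + tcrit * sem
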