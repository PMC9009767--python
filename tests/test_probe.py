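"""Linear decoding probes: separability, null calibration, summaries."""

import numpy as np
import pandas as pd
import pytest

from gainsweep.probe import (
    InformativeBlockSummary,
    decode_block,
    decoding_peak_gain,
    mean_activation,
    most_informative_block,
)


class TestDecodeBlock:
    def test_perfectly_separable_features(self, rng):
        labels = rng.integers(0, 2, 400)
        feats = np.repeat(labels[:, None], 8, axis=1).astype(np.float32)
        rec = decode_block(feats, labels, n_train=150, n_test=150, n_iter=2, seed=0)
        assert np.all(rec["accuracy"] == 1.0)

    def test_well_separated_gaussians(self, rng):
        """5-sigma mean separation per dimension: Bayes error is far
        below 5 %, so the probe must clear 0.95."""
        n = 600
        labels = rng.integers(0, 2, n)
        feats = rng.normal(size=(n, 4)).astype(np.float32) + 5.0 * labels[:, None]
        rec = decode_block(feats, labels, n_train=250, n_test=250, n_iter=3, seed=1)
        assert rec["accuracy"].mean() > 0.95

    def test_random_projection_preserves_separability(self, rng):
        n = 400
        labels = rng.integers(0, 2, n)
        feats = rng.normal(size=(n, 6000)).astype(np.float32)
        feats[:, :60] += 2.0 * labels[:, None]
        rec = decode_block(feats, labels, n_train=150, n_test=150, n_iter=2,
                           seed=2, max_dim=512)
        assert rec["accuracy"].mean() > 0.9

    def test_pool_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            decode_block(np.zeros((10, 3), np.float32), np.zeros(10),
                         n_train=8, n_test=8)

    def test_invariance_to_invertible_linear_map(self, rng):
        n = 300
        labels = rng.integers(0, 2, n)
        feats = rng.normal(size=(n, 5)).astype(np.float32) + 2.0 * labels[:, None]
        a = rng.normal(size=(5, 5))
        a = a @ a.T + 5 * np.eye(5)  # well-conditioned invertible map
        rec1 = decode_block(feats, labels, n_train=120, n_test=120, n_iter=3, seed=3)
        rec2 = decode_block((feats @ a).astype(np.float32), labels,
                            n_train=120, n_test=120, n_iter=3, seed=3)
        assert abs(rec1["accuracy"].mean() - rec2["accuracy"].mean()) < 0.05


def test_mean_activation_basic():
    taps = {1: np.zeros((4, 2, 3, 3)), 2: np.full((4, 2, 3, 3), 2.5)}
    out = mean_activation(taps)
    assert out[1] == 0.0
    assert out[2] == 2.5


class TestMostInformativeBlock:
    def test_tie_reports_first_and_last(self):
        info = most_informative_block({1: 0.80, 2: 0.95, 3: 0.95, 4: 0.90})
        assert (info.first_best, info.last_best) == (2, 3)

    def test_strictly_increasing_gives_last_block(self):
        info = most_informative_block({1: 0.6, 2: 0.7, 3: 0.8, 4: 0.9})
        assert (info.first_best, info.last_best) == (4, 4)

    def test_all_equal_spans_full_range(self):
        info = most_informative_block({b: 0.75 for b in range(1, 9)})
        assert (info.first_best, info.last_best) == (1, 8)

    def test_invalid_summary_rejected(self):
        with pytest.raises(ValueError):
            InformativeBlockSummary(first_best=3, last_best=1, accuracies=(0.5,))


class TestDecodingPeakGain:
    def _records(self, level_accs):
        rows = []
        for level, by_delta in level_accs.items():
            for block in (1, 2):
                for delta, acc in by_delta.items():
                    for it in range(2):
                        rows.append({"level": level, "block": block,
                                     "delta": delta, "iteration": it,
                                     "accuracy": acc})
        return pd.DataFrame(rows)

    def test_unimodal_peak_and_tie_median(self):
        rec = self._records({1.25: {0.5: 0.6, 1.0: 0.8, 2.0: 0.6}})
        per_level, per_block, excluded = decoding_peak_gain(rec)
        assert excluded == []
        assert np.all(per_level["peak_delta"] == 1.0)

    def test_ceiling_level_excluded(self):
        rec = self._records({
            40.0: {0.5: 1.0, 1.0: 1.0, 2.0: 1.0},
            1.25: {0.5: 0.55, 1.0: 0.7, 2.0: 0.5},
        })
        per_level, per_block, excluded = decoding_peak_gain(rec, ceiling_threshold=0.99)
        assert excluded == [40.0]
        assert set(per_level[~per_level["excluded"]]["level"]) == {1.25}

    def test_all_ceiling_rejected(self):
        rec = self._records({40.0: {0.5: 1.0, 1.0: 1.0}})
        with pytest.raises(ValueError):
            decoding_peak_gain(rec)

    def test_aggregation_averages_across_levels(self):
        rec = self._records({
            1.25: {0.5: 0.9, 1.0: 0.6},
            20.0: {0.5: 0.6, 1.0: 0.9},
        })
        _, per_block, _ = decoding_peak_gain(rec)
        np.testing.assert_allclose(per_block["mean_peak_delta"], 0.75)
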