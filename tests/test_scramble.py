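"""Spatial scrambling: multiset preservation, selectivity, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gainsweep.scramble import (
    CalibrationResult,
    DegenerateBlockError,
    ImportanceCurve,
    ScramblePlan,
    Scrambler,
    calibrate_rate,
    progressive_plans,
    scramble_block,
    stage_peaks,
)


class TestScrambleBlock:
    def test_p_zero_is_identity(self, rng):
        x = rng.normal(size=(3, 6, 4, 4)).astype(np.float32)
        out = scramble_block(x, 0.0, rng)
        assert np.array_equal(out, x)

    def test_full_scramble_preserves_multiset(self, rng):
        x = np.arange(1, 5, dtype=np.float32).reshape(1, 1, 2, 2)
        out = scramble_block(x, 1.0, rng)
        assert sorted(out.ravel()) == [1, 2, 3, 4]
        assert out.mean() == pytest.approx(2.5)
        assert out.var() == pytest.approx(x.var())

    def test_constant_map_unchanged(self, rng):
        x = np.full((2, 3, 4, 4), 7.0, np.float32)
        out = scramble_block(x, 1.0, rng)
        assert np.array_equal(out, x)

    def test_invalid_p_rejected(self, rng):
        x = np.zeros((1, 2, 2, 2), np.float32)
        with pytest.raises(ValueError):
            scramble_block(x, -0.1, rng)
        with pytest.raises(ValueError):
            scramble_block(x, 1.5, rng)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0))
    def test_multiset_and_selectivity_contract(self, seed, p):
        """Every scrambled map keeps its exact sorted values; untouched
        maps are bit-identical; the number of touched maps is at most
        ceil(p * channels)."""
        rng = np.random.default_rng(seed)
        n, c, h, w = 2, rng.integers(1, 9), rng.integers(2, 6), rng.integers(2, 6)
        x = rng.normal(size=(n, c, h, w)).astype(np.float32)
        out = scramble_block(x, p, np.random.default_rng(seed + 1))
        touched = 0
        for i in range(n):
            for ch in range(c):
                before, after = x[i, ch], out[i, ch]
                np.testing.assert_array_equal(np.sort(before, axis=None),
                                              np.sort(after, axis=None))
                if not np.array_equal(before, after):
                    touched += 1
        assert touched <= int(np.ceil(p * c)) * n

    def test_scrambler_replays_identical_stream(self):
        x = np.random.default_rng(5).normal(size=(4, 8, 3, 3)).astype(np.float32)
        out1 = Scrambler(0.5, [1, 2])(x)
        out2 = Scrambler(0.5, [1, 2])(x)
        assert np.array_equal(out1, out2)
        out3 = Scrambler(0.5, [1, 3])(x)
        assert not np.array_equal(out1, out3)


class TestCalibration:
    def _curve(self, p, perf, chance=0.0):
        p = np.asarray(p, float)
        perf = np.asarray(perf, float)
        return ImportanceCurve(
            block=1, p_grid=p, mean_accuracy=perf,
            sd_accuracy=np.zeros_like(perf), baseline=float(perf[0]),
            chance=chance,
        )

    def test_linear_retention_gives_exactly_08(self):
        p = np.linspace(0, 1, 11)
        cal = calibrate_rate(self._curve(p, 1.0 - p), threshold=0.2)
        assert cal.p_star == pytest.approx(0.8, abs=1e-12)
        assert cal.reached

    def test_step_curve_interpolation(self):
        """Step from 1.0 to 0.1 between p = 0.4 and 0.5: the threshold
        crossing interpolates to 0.4 + 0.1 * 0.8 / 0.9."""
        p = np.linspace(0, 1, 11)
        perf = np.where(p <= 0.4, 1.0, 0.1)
        cal = calibrate_rate(self._curve(p, perf), threshold=0.2)
        expected = 0.4 + 0.1 * (1.0 - 0.2) / (1.0 - 0.1)
        assert cal.p_star == pytest.approx(expected, abs=1e-6)

    def test_flat_curve_warns_and_returns_one(self):
        p = np.linspace(0, 1, 6)
        with pytest.warns(UserWarning):
            cal = calibrate_rate(self._curve(p, np.full(6, 0.9), chance=0.5))
        assert cal.p_star == 1.0
        assert not cal.reached

    def test_degenerate_block_rejected(self):
        p = np.linspace(0, 1, 6)
        with pytest.raises(DegenerateBlockError):
            calibrate_rate(self._curve(p, np.full(6, 0.5), chance=0.5))

    def test_chance_floor_used_when_above_final_performance(self):
        # performance falls to chance (0.5): retention floor is 0.5
        p = np.linspace(0, 1, 11)
        perf = 1.0 - 0.5 * p  # from 1.0 down to 0.5
        cal = calibrate_rate(self._curve(p, perf, chance=0.5), threshold=0.2)
        assert cal.p_star == pytest.approx(0.8, abs=1e-12)

    def test_isotonic_smoothing_tames_noise(self):
        p = np.linspace(0, 1, 11)
        perf = 1.0 - p + np.array([0, 0.02, -0.02, 0, 0.01, -0.01, 0, 0, 0, 0, 0])
        curve = self._curve(p, perf)
        assert np.all(np.diff(curve.smoothed()) <= 1e-12)


class TestProgressivePlans:
    def test_directions_cover_complementary_blocks(self):
        rates = {b: 0.5 for b in range(1, 9)}
        late = progressive_plans(8, "late_to_early", rates)
        early = progressive_plans(8, "early_to_late", rates)
        assert len(late) == len(early) == 7
        final_late = set(late[-1].rates)
        final_early = set(early[-1].rates)
        assert len(final_late) == len(final_early) == 7
        assert final_late == set(range(2, 9))
        assert final_early == set(range(1, 8))

    def test_stage_counts_grow(self):
        rates = {b: 0.3 for b in range(1, 5)}
        plans = progressive_plans(4, "late_to_early", rates)
        assert [len(p.rates) for p in plans] == [1, 2, 3]
        assert set(plans[0].rates) == {4}

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            progressive_plans(4, "sideways", {1: 0.5})

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            ScramblePlan(rates={1: 1.5})


def test_stage_peaks_median_tie_rule():
    import pandas as pd

    rows = []
    for delta, v in zip([0.5, 1.0, 1.5, 2.0], [0.6, 0.9, 0.9, 0.7]):
        rows.append({"stage": 1, "rep": 0, "delta": delta, "value": v})
    peaks = stage_peaks(pd.DataFrame(rows))
    assert peaks.loc[0, "peak_delta"] == pytest.approx(1.25)
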