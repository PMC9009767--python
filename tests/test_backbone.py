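"""Backbone contracts: neutral-gain identity, homogeneity, taps, checkpoints."""

import numpy as np
import pytest

from gainsweep import nn
from gainsweep.activations import ActivationSpec, GlobalGainState
from gainsweep.backbone import (
    BackboneConfig,
    BackboneModel,
    GainStateCache,
    adapt_norm_stats,
    forward_with_taps,
    set_gain_state,
    set_global_gain,
)


@pytest.fixture(scope="module")
def small_model():
    cfg = BackboneConfig(
        image_size=16, stem_width=4, widths=(4, 8, 8, 16), strides=(1, 2, 1, 2),
        n_classes=3,
    )
    return BackboneModel(cfg, seed=0)


@pytest.fixture(scope="module")
def batch():
    rng = np.random.default_rng(3)
    return rng.uniform(0, 1, (6, 3, 16, 16)).astype(np.float32)


class TestGlobalGain:
    def test_neutral_state_bit_identical(self, small_model, batch):
        """delta = 1 must reproduce the baseline outputs exactly."""
        set_global_gain(small_model, 1.0)
        _, base = small_model.forward(batch)
        set_global_gain(small_model, 2.0)
        small_model.forward(batch)
        set_global_gain(small_model, 1.0)
        _, again = small_model.forward(batch)
        assert np.array_equal(base, again)

    def test_setting_gain_twice_is_stateless(self, small_model, batch):
        set_global_gain(small_model, 1.0)
        _, base = small_model.forward(batch)
        set_global_gain(small_model, 0.5)
        set_global_gain(small_model, 1.0)
        _, again = small_model.forward(batch)
        assert np.array_equal(base, again)

    def test_weights_untouched_by_gain_change(self, small_model):
        h0 = small_model.weight_hash()
        set_global_gain(small_model, 3.7)
        assert small_model.weight_hash() == h0
        set_global_gain(small_model, 1.0)

    def test_invalid_delta_rejected(self, small_model):
        with pytest.raises(ValueError):
            set_global_gain(small_model, 0.0)
        with pytest.raises(ValueError):
            set_global_gain(small_model, -2.0)


class TestHomogeneityOracle:
    """On bias-free, normalisation-free sequential rectifier nets, setting
    gain delta scales the output by exactly delta^L (L activation layers)."""

    def _toy(self, L, rng):
        gain = GlobalGainState(1.0)
        relu = ActivationSpec("rectifier")
        layers = []
        c = 3
        for _ in range(L):
            layers += [nn.Conv2d(c, 4, 3, 1, bias=False, rng=rng),
                       nn.GainedActivation(relu, gain)]
            c = 4
        layers += [nn.GlobalAvgPool(), nn.Dense(c, 2, bias=False, rng=rng)]
        return nn.Sequential(layers), gain

    @pytest.mark.parametrize("L,delta", [(1, 2.0), (3, 2.0), (3, 0.5), (4, 1.5)])
    def test_output_scales_as_delta_power_L(self, L, delta):
        rng = np.random.default_rng(L)
        net, gain = self._toy(L, rng)
        x = rng.normal(size=(5, 3, 8, 8)).astype(np.float32)
        gain.set(1.0)
        base = net.forward(x)
        gain.set(delta)
        out = net.forward(x)
        rel = np.abs(out - delta**L * base).max() / (np.abs(base).max() + 1e-12)
        assert rel < 1e-5


class TestTaps:
    def test_one_tap_per_block(self, small_model, batch):
        taps, feats, logits = forward_with_taps(small_model, batch)
        assert sorted(taps) == [1, 2, 3, 4]
        assert logits.shape == (6, 3)
        assert feats.shape == (6, 16)

    def test_taps_deterministic(self, small_model, batch):
        t1, _, _ = forward_with_taps(small_model, batch)
        t2, _, _ = forward_with_taps(small_model, batch)
        for b in t1:
            assert np.array_equal(t1[b], t2[b])

    def test_tap_matches_manual_gain_wiring_oracle(self):
        """Brute-force oracle: on a norm-free single-block model the
        block-1 tap must equal an explicit re-computation that applies
        delta at each activation site by hand."""
        cfg = BackboneConfig(
            image_size=8, stem_width=4, widths=(4,), strides=(1,),
            n_classes=2, norm="none",
            activation=ActivationSpec("rectifier"),
        )
        model = BackboneModel(cfg, seed=1)
        x = np.random.default_rng(0).normal(size=(3, 3, 8, 8)).astype(np.float32)
        delta = 2.0
        set_global_gain(model, delta)
        taps, _, _ = forward_with_taps(model, x)
        set_global_gain(model, 1.0)

        relu = lambda a: np.maximum(a, 0.0)
        block = model.blocks[0]
        h = delta * relu(model.stem_conv.forward(x))
        r = delta * relu(block.conv1.forward(h))
        r = block.conv2.forward(r)
        expected = delta * relu(r + h)
        np.testing.assert_allclose(taps[1], expected, rtol=1e-5, atol=1e-6)

    def test_shape_mismatch_rejected(self, small_model):
        with pytest.raises(ValueError):
            small_model.forward(np.zeros((2, 3, 8, 8), np.float32))


class TestNormAdaptation:
    def test_adaptation_is_deterministic(self, small_model, batch):
        calib = batch
        set_gain_state(small_model, 1.7, calib)
        _, out1 = small_model.forward(batch)
        set_gain_state(small_model, 1.7, calib)
        _, out2 = small_model.forward(batch)
        assert np.array_equal(out1, out2)
        set_gain_state(small_model, 1.0, calib)

    def test_state_cache_matches_direct_adaptation(self, small_model, batch):
        cache = GainStateCache(small_model, [0.5, 1.0, 2.0], batch)
        cache.enter(2.0)
        _, cached = small_model.forward(batch)
        set_gain_state(small_model, 2.0, batch)
        _, direct = small_model.forward(batch)
        assert np.array_equal(cached, direct)
        cache.neutral()

    def test_adaptation_leaves_weights_untouched(self, small_model, batch):
        h0 = small_model.weight_hash()
        adapt_norm_stats(small_model, batch)
        assert small_model.weight_hash() == h0


class TestCheckpoint:
    def test_save_load_roundtrip(self, small_model, batch, tmp_path):
        path = tmp_path / "model.npz"
        small_model.save(path)
        loaded = BackboneModel.load(path)
        assert loaded.weight_hash() == small_model.weight_hash()
        assert loaded.meta["delta_trained"] == 1.0
        _, a = small_model.forward(batch)
        _, b = loaded.forward(batch)
        assert np.array_equal(a, b)
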