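import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wanet.nn as nn
from wanet.model import (
    BlockSpec,
    LasppSpec,
    NetworkConfig,
    SegmentationModel,
    build_laspp,
    build_variant,
    build_wa_net,
    build_wdsr_a,
    leaky_relu,
    original_block_params,
    receptive_field,
    variant_config,
    weight_normalize,
    wide_block_widths,
)


class TestReceptiveField:
    @pytest.mark.parametrize("k,d,expected", [(3, 3, 7), (3, 1, 3), (3, 2, 5),
                                              (3, 4, 9), (3, 8, 17), (5, 1, 5)])
    def test_formula(self, k, d, expected):
        assert receptive_field(k, d) == expected

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            receptive_field(0, 1)
        with pytest.raises(ValueError):
            receptive_field(3, 0)

    @pytest.mark.parametrize("d", [1, 2, 3, 8])
    def test_matches_impulse_response_of_atrous_layer(self, d):
        """The analytic receptive field equals the measured span of the
        impulse response of a real dilated convolution layer."""
        conv = nn.Conv2d(1, 1, 3, dilation=d, bias=False, name="probe",
                         rng=np.random.default_rng(0))
        conv.set_weight(np.ones((1, 1, 3, 3)))
        size = 4 * d + 9
        x = np.zeros((1, size, size, 1), dtype=np.float32)
        x[0, size // 2, size // 2, 0] = 1.0
        y = conv.forward(x)[0, :, :, 0]
        rows = np.nonzero(y.sum(axis=1))[0]
        cols = np.nonzero(y.sum(axis=0))[0]
        span = rows.max() - rows.min() + 1
        assert span == cols.max() - cols.min() + 1 == receptive_field(3, d)


class TestWideBlockWidths:
    def test_table_widths_slim16(self):
        spec = wide_block_widths(16, 4)
        assert spec.expanded_width == 64
        assert spec.equivalent_width == 32
        assert spec.exact

    def test_unit_expansion_degenerates(self):
        spec = wide_block_widths(24, 1)
        assert spec.expanded_width == spec.slim_width == spec.equivalent_width == 24

    @pytest.mark.parametrize("slim", [8, 16, 32])
    def test_complexity_identity_exact_integers(self, slim):
        """Wide-block conv-weight count equals the original residual block
        of width c1 = 2*slim (expansion 4), as exact integers."""
        spec = wide_block_widths(slim, 4)
        assert spec.conv_weight_count() == original_block_params(2 * slim, 3)

    def test_inexact_case_flagged(self):
        spec = wide_block_widths(3, 2)  # sqrt(18) not integral
        assert not spec.exact

    def test_original_block_examples(self):
        assert original_block_params(1, 1) == 2
        assert original_block_params(32, 3) == 18432
        assert original_block_params(16, 3) == 4608


class TestWeightNormalize:
    def test_hand_example(self):
        w = weight_normalize(np.array([3.0, 4.0]), 10.0)
        np.testing.assert_allclose(w, [6.0, 8.0])
        assert np.linalg.norm(w) == pytest.approx(10.0)

    def test_g_equal_norm_is_identity(self, rng):
        n = rng.standard_normal(12)
        np.testing.assert_allclose(weight_normalize(n, np.linalg.norm(n)), n,
                                   rtol=1e-12)

    def test_scale_invariance(self, rng):
        n = rng.standard_normal((3, 3))
        np.testing.assert_allclose(weight_normalize(n, 2.5),
                                   weight_normalize(7.0 * n, 2.5), rtol=1e-12)

    def test_zero_direction_rejected(self):
        with pytest.raises(FloatingPointError):
            weight_normalize(np.zeros(4), 1.0)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2 ** 16))
    def test_norm_contract_property(self, seed):
        r = np.random.default_rng(seed)
        n = r.standard_normal(r.integers(1, 30))
        g = float(r.uniform(0.1, 10))
        assert np.linalg.norm(weight_normalize(n, g)) == pytest.approx(g, rel=1e-9)


class TestLeakyRelu:
    def test_piecewise_values(self):
        assert leaky_relu(2.0) == 2.0
        assert leaky_relu(-1.0, 0.3) == pytest.approx(-0.3)

    def test_zero_slope_is_relu(self, rng):
        x = rng.standard_normal(50)
        np.testing.assert_array_equal(leaky_relu(x, 0.0), np.maximum(x, 0))


class TestBlocks:
    def test_zeroed_residual_path_is_identity(self, rng):
        """With matched channels and zeroed body weights, a wide block
        reduces to the identity map exactly."""
        block = build_wdsr_a(BlockSpec(8), in_channels=8,
                             rng=np.random.default_rng(0))
        block.conv2.set_weight(np.zeros_like(block.conv2.effective_weight()))
        block.conv2.b.val[:] = 0
        x = rng.standard_normal((2, 12, 12, 8)).astype(np.float32)
        np.testing.assert_array_equal(block.forward(x), x)

    def test_parameter_count_matches_closed_form(self):
        block = build_wdsr_a(BlockSpec(16, 4), in_channels=16)
        count = sum(p.val.size for p in block.params() if p.kind == "conv_weight")
        assert count == 2 * 16 * 64 * 9 == 18432

    def test_adapter_present_only_on_channel_mismatch(self):
        assert build_wdsr_a(BlockSpec(8), in_channels=8).adapter is None
        assert build_wdsr_a(BlockSpec(8), in_channels=3).adapter is not None

    def test_output_shape_preserved(self, rng):
        block = build_wdsr_a(BlockSpec(4), in_channels=1)
        x = rng.standard_normal((2, 48, 48, 1)).astype(np.float32)
        assert block.forward(x).shape == (2, 48, 48, 4)

    def test_laspp_zero_weights_give_zero(self, rng):
        laspp = build_laspp(LasppSpec(channels=4), in_channels=3)
        for conv in laspp.branches:
            conv.set_weight(np.zeros_like(conv.effective_weight()))
            conv.b.val[:] = 0
        x = rng.standard_normal((1, 16, 16, 3)).astype(np.float32)
        np.testing.assert_array_equal(laspp.forward(x), np.zeros((1, 16, 16, 4)))

    @pytest.mark.parametrize("d", [1, 2, 4, 8])
    def test_laspp_branch_impulse_offsets(self, d):
        """A single-tap probe kernel on the dilation-d branch responds
        exactly at offsets +-d, matching the atrous definition."""
        spec = LasppSpec(channels=1, dilations=(d,) if d == 1 else (1, d))
        laspp = build_laspp(spec, in_channels=1, weight_norm=False)
        for conv in laspp.branches:
            w = np.zeros((1, 1, 3, 3))
            conv.set_weight(w)
            conv.b.val[:] = 0
        probe = laspp.branches[-1]  # the dilation-d branch
        w = np.zeros((1, 1, 3, 3))
        w[0, 0, 0, 0] = 1.0  # corner tap -> response at offset (-d, -d)...
        probe.set_weight(w)
        size = 2 * 8 + 5
        x = np.zeros((1, size, size, 1), dtype=np.float32)
        c = size // 2
        x[0, c, c, 0] = 1.0
        y = laspp.forward(x)[0, :, :, 0]
        hits = np.argwhere(y != 0)
        assert hits.shape == (1, 2)
        np.testing.assert_array_equal(hits[0], [c + d, c + d])


@pytest.fixture(scope="module")
def small_model():
    cfg = NetworkConfig(encoder_widths=(2, 4, 8),
                        laspp=LasppSpec(channels=8), patch_size=16)
    return build_wa_net(cfg, seed=0)


class TestWaNet:

    def test_probabilities_sum_to_one(self, small_model, rng):
        x = rng.random((3, 16, 16, 1)).astype(np.float32)
        p = small_model.forward(x)
        assert p.shape == (3, 16, 16, 2)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-6)
        assert p.min() >= 0

    def test_eval_forward_deterministic(self, small_model, rng):
        x = rng.random((2, 16, 16, 1)).astype(np.float32)
        np.testing.assert_array_equal(small_model.forward(x),
                                      small_model.forward(x))

    def test_same_seed_same_parameters(self):
        cfg = NetworkConfig(encoder_widths=(2, 4, 8),
                            laspp=LasppSpec(channels=8), patch_size=16)
        m1, m2 = build_wa_net(cfg, seed=5), build_wa_net(cfg, seed=5)
        assert m1.n_parameters() == m2.n_parameters()
        for p1, p2 in zip(m1.params(), m2.params()):
            np.testing.assert_array_equal(p1.val, p2.val)

    def test_indivisible_patch_size_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(patch_size=50)

    def test_weight_norm_contract_after_update(self, small_model, rng):
        """Reconstructing w from (g, N) keeps ||w|| = g after a perturbation
        of N (the LASPP convs are weight-normalized)."""
        conv = small_model.laspp.branches[0]
        conv.V.val += rng.standard_normal(conv.V.val.shape).astype(np.float32) * 0.1
        w = conv.effective_weight()
        norms = np.sqrt((w.reshape(w.shape[0], -1) ** 2).sum(axis=1))
        np.testing.assert_allclose(norms, conv.g.val, rtol=1e-5)

    def test_checkpoint_round_trip(self, small_model, rng, tmp_path):
        x = rng.random((2, 16, 16, 1)).astype(np.float32)
        ref = small_model.forward(x)
        path = str(tmp_path / "ckpt.npz")
        small_model.save(path)
        loaded = SegmentationModel.load(path)
        np.testing.assert_array_equal(loaded.forward(x), ref)


class TestVariants:
    def test_network_3_branch_count(self):
        m = build_variant("network_3")
        assert len(m.laspp.branches) == 3
        assert m.cfg.laspp.dilations == (1, 2, 4)

    def test_network_4_max_dilation(self):
        m = build_variant("network_4")
        assert len(m.laspp.branches) == 5
        assert m.cfg.laspp.dilations[-1] == 16
        assert m.cfg.laspp.receptive_fields()[-1] == 33

    def test_network_2_width_sequence(self):
        cfg = variant_config("network_2")
        assert cfg.encoder_widths == (32, 64, 128)
        assert cfg.laspp.channels == 256
        assert cfg.block_type == "preact"

    def test_network_1_preact_without_wn(self):
        cfg = variant_config("network_1")
        assert cfg.block_type == "preact"
        assert not cfg.wn_laspp

    @pytest.mark.parametrize("name", ["network_1", "network_3", "network_4"])
    def test_variants_build_and_run(self, name, rng):
        base = NetworkConfig(encoder_widths=(2, 4, 8),
                             laspp=LasppSpec(channels=8), patch_size=16)
        m = build_variant(name, base, seed=0)
        x = rng.random((1, 16, 16, 1)).astype(np.float32)
        p = m.forward(x)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-6)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_variant("network_9")


class TestBackprop:
    def test_model_gradient_matches_finite_differences(self):
        """Directional derivative over all parameters agrees with
        backpropagation (float64, smooth direction)."""
        old = nn.DTYPE
        nn.DTYPE = np.float64
        try:
            from wanet.objective import LossConfig, segmentation_loss
            cfg = NetworkConfig(encoder_widths=(2, 3, 4),
                                laspp=LasppSpec(channels=5), patch_size=8)
            m = SegmentationModel(cfg, seed=3)
            r = np.random.default_rng(1)
            x = r.random((2, 8, 8, 1))
            y = (r.random((2, 8, 8)) > 0.8).astype(int)
            lc = LossConfig(reduction="mean")
            probs = m.forward(x, train=True)
            _, dp = segmentation_loss(probs, y, lc)
            m.backward(dp)
            params = m.params()
            dirs = [r.standard_normal(p.val.shape) for p in params]
            ana = sum(float((p.grad * d).sum()) for p, d in zip(params, dirs))
            eps = 1e-6
            for p, d in zip(params, dirs):
                p.val += eps * d
            l1, _ = segmentation_loss(m.forward(x, train=True), y, lc)
            for p, d in zip(params, dirs):
                p.val -= 2 * eps * d
            l2, _ = segmentation_loss(m.forward(x, train=True), y, lc)
            num = (l1 - l2) / (2 * eps)
            assert num == pytest.approx(ana, rel=1e-4)
        finally:
            nn.DTYPE = old
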