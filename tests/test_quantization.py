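import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonosiam import nn
from sonosiam.model import BackboneSpec, SiameseNetwork
from sonosiam.quantization import (SIGNED, UNSIGNED, BatchNormParams,
                                   CalibrationConfig, Observer, QuantParams,
                                   QuantizedTensor, affine_qparams,
                                   calibrate_activations, dequantize,
                                   fold_batchnorm, fuse_conv_bn,
                                   kl_divergence_for_threshold,
                                   kl_optimal_range, quantize_model,
                                   quantize_tensor, quantized_forward,
                                   round_half_away, symmetric_channel_qparams,
                                   QuantizedModel)


class TestRounding:
    def test_half_away_from_zero(self):
        np.testing.assert_array_equal(
            round_half_away(np.array([0.5, 1.5, -0.5, -1.5, 2.4, -2.6])),
            [1, 2, -1, -2, 2, -3],
        )


class TestAffineParams:
    @pytest.mark.parametrize(
        "r_min,r_max,grid,s,z",
        [
            (0.0, 255.0, UNSIGNED, 1.0, 0),
            (0.0, 2.55, UNSIGNED, 0.01, 0),
            (-1.0, 1.0, UNSIGNED, 2 / 255, 128),
        ],
    )
    def test_hand_checked(self, r_min, r_max, grid, s, z):
        p = affine_qparams(r_min, r_max, grid)
        assert p.scale == pytest.approx(s)
        assert p.zero_point == z

    def test_degenerate_range_widened(self):
        p = affine_qparams(0.7, 0.7, UNSIGNED)
        assert p.scale > 0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            affine_qparams(0.0, np.inf)


class TestSymmetricChannelParams:
    def test_scale_is_absmax_over_127(self):
        W = np.zeros((2, 3))
        W[0, 1] = -127.0
        W[1, 2] = 12.7
        p = symmetric_channel_qparams(W)
        np.testing.assert_allclose(p.scale, [1.0, 0.1])
        assert p.zero_point == 0

    def test_single_channel(self):
        p = symmetric_channel_qparams(np.array([[1.27, -0.5]]))
        assert p.scale[0] == pytest.approx(0.01)

    def test_all_zero_channel(self):
        p = symmetric_channel_qparams(np.zeros((1, 4)))
        q = quantize_tensor(np.zeros((1, 4)), p)
        assert (q.q == 0).all()

    def test_zero_maps_to_zero(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(3, 5))
        W[:, 0] = 0.0
        q = quantize_tensor(W, symmetric_channel_qparams(W))
        assert (q.q[:, 0] == 0).all()


class TestQuantizeTensor:
    def test_zero_maps_to_zero_point(self):
        p = affine_qparams(-1.0, 1.0, UNSIGNED)
        q = quantize_tensor(np.array([0.0]), p)
        assert q.q[0] == p.zero_point
        assert dequantize(q)[0] == pytest.approx(0.0, abs=p.scale / 2)

    def test_hand_checked_value(self):
        p = QuantParams(0.01, 0, *UNSIGNED)
        assert quantize_tensor(np.array([1.00]), p).q[0] == 100

    def test_saturation(self):
        p = QuantParams(0.01, 0, *UNSIGNED)
        assert quantize_tensor(np.array([1e6]), p).q[0] == 255

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        r_min=st.floats(-10, 0),
        width=st.floats(0.1, 20),
        seed=st.integers(0, 100),
        grid=st.sampled_from([SIGNED, UNSIGNED]),
    )
    def test_round_trip_error_bounded(self, r_min, width, seed, grid):
        """|dequant(quant(r)) - r| <= s/2 for r inside the calibrated range."""
        r_max = r_min + width
        p = affine_qparams(r_min, r_max, grid)
        r = np.random.default_rng(seed).uniform(r_min, r_max, size=50)
        err = np.abs(dequantize(quantize_tensor(r, p)) - r)
        assert err.max() <= p.scale / 2 + 1e-12

    def test_round_trip_symmetric_per_channel(self):
        rng = np.random.default_rng(1)
        W = rng.normal(size=(4, 9))
        p = symmetric_channel_qparams(W)
        err = np.abs(dequantize(quantize_tensor(W, p)) - W)
        assert (err <= p.scale[:, None] / 2 + 1e-12).all()

    def test_monotone_in_r(self):
        p = affine_qparams(-2.0, 2.0, SIGNED)
        r = np.linspace(-3, 3, 401)
        q = quantize_tensor(r, p).q
        assert (np.diff(q) >= 0).all()

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            QuantizedTensor(np.array([300]), QuantParams(1.0, 0, *UNSIGNED))
        with pytest.raises(ValueError):
            QuantParams(0.0, 0, *UNSIGNED)
        with pytest.raises(ValueError):
            QuantParams(1.0, 5, *SIGNED, scheme="symmetric_per_channel")


class TestBatchNormFolding:
    def test_identity_fold(self):
        W = np.random.default_rng(0).normal(size=(3, 2, 3, 3))
        b = np.random.default_rng(1).normal(size=3)
        var = np.abs(np.random.default_rng(2).normal(size=3)) + 0.5
        eps = 1e-5
        bn = BatchNormParams(np.sqrt(var + eps), np.zeros(3), np.zeros(3), var, eps)
        W_f, b_f = fold_batchnorm(W, b, bn)
        np.testing.assert_allclose(W_f, W, rtol=1e-12)
        np.testing.assert_allclose(b_f, b, rtol=1e-12)

    def test_hand_checked_values(self):
        bn = BatchNormParams([1.0], [1.0], [4.0], [1.0], eps=1e-12)
        W_f, b_f = fold_batchnorm(np.array([[2.0]]), np.array([0.0]), bn)
        assert W_f[0, 0] == pytest.approx(2.0)
        assert b_f[0] == pytest.approx(-3.0)

    def test_matches_sequential_evaluation(self):
        """Folded conv reproduces conv -> BN applied in sequence."""
        rng = np.random.default_rng(3)
        conv = nn.Conv2d(2, 4, 3, rng)
        bn = nn.BatchNorm2d(4)
        bn.gamma = rng.normal(size=4).astype(np.float32)
        bn.beta = rng.normal(size=4).astype(np.float32)
        bn.running_mean = rng.normal(size=4).astype(np.float32)
        bn.running_var = (np.abs(rng.normal(size=4)) + 0.3).astype(np.float32)
        x = rng.normal(size=(2, 2, 8, 8)).astype(np.float32)
        y_seq, _ = bn.forward(conv.forward(x)[0])
        fused = fuse_conv_bn([conv, bn])
        assert len(fused) == 1
        y_fold, _ = fused[0].forward(x)
        np.testing.assert_allclose(y_fold, y_seq, rtol=1e-4, atol=1e-5)

    def test_channel_mismatch_raises(self):
        bn = BatchNormParams([1.0, 1.0], [0.0, 0.0], [0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            fold_batchnorm(np.ones((3, 2)), np.zeros(3), bn)

    def test_unfused_bn_is_rejected(self):
        with pytest.raises(ValueError, match="BatchNorm"):
            fuse_conv_bn([nn.BatchNorm2d(4)])


class TestCalibration:
    def test_minmax_exact_range(self):
        obs = Observer()
        obs.update(np.arange(256.0))
        assert obs.range(CalibrationConfig("minmax")) == (0.0, 255.0)

    def test_percentile_excludes_outlier(self):
        rng = np.random.default_rng(0)
        obs = Observer()
        obs.update(rng.uniform(0, 1, size=10000))
        obs.update(np.array([100.0]))
        lo, hi = obs.range(CalibrationConfig("percentile"))
        assert hi <= 1.01
        # sorting oracle on the pooled sample
        pooled = np.sort(obs.pooled())
        assert hi == pytest.approx(np.percentile(pooled, 99.9))

    def test_kl_range_within_observed_and_no_worse_than_minmax(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(0, 1, 20000), rng.uniform(8, 10, 50)])
        r_min, r_max = kl_optimal_range(vals, n_bins=512, n_quant=64)
        assert vals.min() <= r_min <= r_max <= vals.max()
        hist, edges = np.histogram(vals, bins=512, range=(vals.min(), vals.max()))
        # exhaustive-search oracle over all candidate thresholds
        kls = [kl_divergence_for_threshold(hist, i, 64) for i in range(64, 513)]
        best = int(np.argmin(kls)) + 64
        assert r_max == pytest.approx(edges[best])
        assert min(kls) <= kl_divergence_for_threshold(hist, 512, 64)

    def test_empty_calibration_rejected(self):
        model = SiameseNetwork(BackboneSpec.small(32), seed=0)
        with pytest.raises(ValueError):
            calibrate_activations(model, [])

    def test_post_relu_taps_use_unsigned_grid(self):
        model = SiameseNetwork(BackboneSpec.small(32), seed=0)
        x = np.random.default_rng(0).uniform(-1, 1, size=(4, 32, 32))
        input_p, step_p, head_p = calibrate_activations(model, [x])
        assert (input_p.q_min, input_p.q_max) == SIGNED
        layer_params = [p for p in step_p if p is not None]
        # conv blocks and all but the last dense layer are post-ReLU
        for p in layer_params[:-1]:
            assert (p.q_min, p.q_max) == UNSIGNED
        assert (layer_params[-1].q_min, layer_params[-1].q_max) == SIGNED
        for p in head_p:
            assert (p.q_min, p.q_max) == SIGNED


class TestQuantizedForward:
    def test_one_by_one_conv_hand_checked(self):
        x_q = quantize_tensor(np.array([[[[1.0]]]]), QuantParams(0.01, 0, *UNSIGNED))
        W = np.array([[[[2.0]]]])
        W_q = quantize_tensor(W, symmetric_channel_qparams(W))
        out_p = QuantParams(0.01, 0, *UNSIGNED)
        y = quantized_forward(x_q, W_q, np.zeros(1), out_p)
        assert dequantize(y)[0, 0, 0, 0] == pytest.approx(2.0, abs=0.01 / 2)

    def test_zero_weights_give_zero_point_output(self):
        x_q = quantize_tensor(
            np.random.default_rng(0).uniform(-1, 1, (1, 2, 4, 4)),
            affine_qparams(-1, 1, SIGNED),
        )
        W = np.zeros((3, 2, 3, 3))
        W_q = quantize_tensor(W, symmetric_channel_qparams(W))
        out_p = affine_qparams(-1, 1, SIGNED)
        y = quantized_forward(x_q, W_q, np.zeros(3), out_p)
        assert (y.q == out_p.zero_point).all()

    def test_random_conv_matches_fp32_oracle(self):
        """Integer path tracks the FP32 convolution within ~2 output steps."""
        rng = np.random.default_rng(5)
        conv = nn.Conv2d(3, 4, 3, rng)
        x = rng.uniform(-1, 1, size=(2, 3, 8, 8)).astype(np.float32)
        y_ref, _ = conv.forward(x)
        in_p = affine_qparams(float(x.min()), float(x.max()), SIGNED)
        out_p = affine_qparams(float(y_ref.min()), float(y_ref.max()), SIGNED)
        W_q = quantize_tensor(conv.W, symmetric_channel_qparams(conv.W))
        y_q = quantized_forward(quantize_tensor(x, in_p), W_q, conv.b, out_p,
                                kernel_side=3)
        err = np.abs(dequantize(y_q) - y_ref)
        assert err.mean() <= 2 * out_p.scale

    def test_matches_fake_quant_simulation(self):
        """With dequantized weights/inputs and the int32-rounded bias, a float
        simulation reproduces the integer kernel exactly up to rounding of the
        shared multiplier."""
        rng = np.random.default_rng(8)
        W = rng.normal(size=(4, 6)).astype(np.float64)
        b = rng.normal(size=4)
        x = rng.uniform(-2, 2, size=(5, 6))
        in_p = affine_qparams(-2, 2, SIGNED)
        wp = symmetric_channel_qparams(W)
        x_q = quantize_tensor(x, in_p)
        W_q = quantize_tensor(W, wp)
        y_float = dequantize(x_q) @ dequantize(W_q).T
        s_x = in_p.scale
        b32 = round_half_away(b / (wp.scale * s_x))
        y_float = y_float + (wp.scale * s_x) * b32
        out_p = affine_qparams(float(y_float.min()), float(y_float.max()), SIGNED)
        y_int = quantized_forward(x_q, W_q, b, out_p)
        y_sim = np.clip(
            round_half_away(y_float / out_p.scale) + out_p.zero_point,
            out_p.q_min, out_p.q_max,
        )
        np.testing.assert_array_equal(y_int.q, y_sim)

    def test_bias_stored_as_int32(self):
        from sonosiam.quantization import _bias_int32

        b32 = _bias_int32(np.array([0.5]), np.array([0.01]), 0.02)
        assert b32[0] == 2500
        with pytest.raises(ValueError):
            _bias_int32(np.array([1e12]), np.array([1e-6]), 1e-6)


class TestQuantizeModel:
    def test_weights_int8_symmetric(self, trained_model, calibration_batches):
        model, _ = trained_model
        qm = quantize_model(model, calibration_batches[:2])
        for op, layer in qm.steps:
            if op == "layer":
                assert layer.W_q.min() >= -128 and layer.W_q.max() <= 127
                assert (layer.s_w > 0).all()
        assert qm.head_abn.W_q.dtype.kind == "i"

    def test_payload_quarter_of_fp32(self, trained_model, calibration_batches):
        model, _ = trained_model
        qm = quantize_model(model, calibration_batches[:2])
        n_params_w = sum(
            p.size for k, p in model.params().items() if k.endswith(".W")
        )
        assert qm.weight_payload_bytes() == n_params_w
        fp32_payload = 4 * sum(p.size for p in model.params().values())
        assert qm.weight_payload_bytes() <= fp32_payload / 4

    def test_export_load_roundtrip(self, trained_model, calibration_batches,
                                   tmp_path):
        model, _ = trained_model
        qm = quantize_model(model, calibration_batches[:2])
        qm.export(str(tmp_path))
        loaded = QuantizedModel.load(str(tmp_path))
        x = calibration_batches[0][:8]
        la, lb = qm.forward_logits(x)
        la2, lb2 = loaded.forward_logits(x)
        np.testing.assert_array_equal(la, la2)
        np.testing.assert_array_equal(lb, lb2)
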