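"""Network assembly and the analytic efficiency profiler."""

import numpy as np
import pytest

from lwseg import architectures as A


def flop_enumeration_oracle(trace):
    """Count FLOPs by brute-force enumeration of every output element.

    For convolutions this walks output positions and kernel taps one by one
    (2 FLOPs per multiply-accumulate); elementwise entries contribute their
    element count. Only usable at small input sizes.
    """
    total = 0
    for e in trace:
        if e["kind"] == "conv":
            for _ in range(e["hout"] * e["wout"]):
                for _ in range(e["cout"]):
                    total += 2 * e["kh"] * e["kw"] * e["cin_pg"]
        elif e["kind"] == "bn":
            total += e["c"] * e["hout"] * e["wout"]
        else:
            total += e["count"]
    return total


SMALL = dict(encoder_widths=(3, 4, 5, 6), decoder_widths=(8, 6, 5, 4))


class TestSpecs:
    def test_conv_counts_per_stage(self):
        spec = A.default_spec("lw_segnet")
        assert tuple(s.conv_count for s in spec.encoder_stages) == (2, 1, 1, 5)
        assert tuple(s.conv_count for s in spec.decoder_stages) == (5, 1, 1, 2)
        spec = A.default_spec("lw_unet")
        assert tuple(s.conv_count for s in spec.encoder_stages) == (2, 2, 2, 2)
        assert tuple(s.conv_count for s in spec.decoder_stages) == (2, 2, 2, 2)

    def test_input_size_must_be_divisible_by_16(self):
        with pytest.raises(ValueError, match="divisible by 16"):
            A.ArchitectureSpec(name="lw_segnet", input_size=500, **SMALL)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError):
            A.ArchitectureSpec(name="segnet", **SMALL)

    def test_unet_decoder_inputs_concatenate_skips(self):
        spec = A.ArchitectureSpec(name="lw_unet", **SMALL)
        stages = spec.decoder_stages
        e, d = spec.encoder_widths, spec.decoder_widths
        assert stages[0].in_width == e[3]
        assert stages[1].in_width == d[0] + e[3]
        assert stages[2].in_width == d[1] + e[2]
        assert stages[3].in_width == d[2] + e[1]
        assert spec.head_in_width == d[3] + e[0]


class TestProfiler:
    def test_single_dense_conv_parameter_formula(self):
        # lone 3x3 dense conv 5->8 with bias: 5*8*9 + 8 = 368
        entry = A._conv_entry("x", 3, 3, 5, 8, 4, 4, 5 * 8 * 9, 8)
        assert entry["weights"] + entry["bias"] == 368

    def test_single_depthwise_parameter_formula(self):
        # depthwise 3x3 on 5 channels with bias: 5*9 + 5 = 50
        entry = A._conv_entry("x", 3, 3, 1, 5, 4, 4, 5 * 9, 5)
        assert entry["weights"] + entry["bias"] == 50

    def test_dense_conv_flops_formula(self):
        # 3x3 conv 1->1 on 4x4 same-padded: 2*9*16 = 288
        entry = A._conv_entry("x", 3, 3, 1, 1, 4, 4, 9, 0)
        assert A.entry_flops(entry) == 288

    def test_pointwise_flops_formula(self):
        entry = A._conv_entry("x", 1, 1, 5, 8, 7, 9, 40, 8)
        assert A.entry_flops(entry) == 2 * 5 * 8 * 7 * 9

    def test_empty_trace_counts_zero(self):
        assert flop_enumeration_oracle([]) == 0

    @pytest.mark.parametrize("name", ["lw_segnet", "lw_unet"])
    def test_parameter_count_equals_model_tally(self, name):
        for widths in (None, {"encoder": SMALL["encoder_widths"],
                              "decoder": SMALL["decoder_widths"]}):
            spec = A.default_spec(name, input_size=64, widths=widths)
            model = A.build_model(spec, seed=0)
            assert (A.count_parameters(spec).parameter_count
                    == model.parameter_count())

    @pytest.mark.parametrize("name", ["lw_segnet", "lw_unet"])
    @pytest.mark.parametrize("size", [16, 32, 64])
    def test_flops_match_enumeration_oracle(self, name, size):
        spec = A.ArchitectureSpec(name=name, input_size=16, **SMALL)
        trace = A.layer_trace(spec, size)
        assert A.count_flops(spec, size).flop_count == flop_enumeration_oracle(trace)

    @pytest.mark.parametrize("name", ["lw_segnet", "lw_unet"])
    def test_flops_scale_with_area(self, name):
        spec = A.default_spec(name)
        f512 = A.count_flops(spec, 512).flop_count
        f256 = A.count_flops(spec, 256).flop_count
        # exact 4x up to the spatially-invariant channel-attention 1-D convs
        assert f512 / f256 == pytest.approx(4.0, rel=1e-5)
        assert (A.count_parameters(A.default_spec(name, input_size=256)).parameter_count
                == A.count_parameters(spec).parameter_count)

    def test_published_ordering_between_networks(self):
        seg = A.count_flops(A.default_spec("lw_segnet"), 512)
        une = A.count_flops(A.default_spec("lw_unet"), 512)
        assert une.parameter_count < seg.parameter_count
        assert une.flop_count < seg.flop_count

    def test_relative_increase_one_decimal(self):
        assert A.relative_increase(58.7, 32.1) == 82.9
        assert A.relative_increase(32.1, 32.1) == 0.0

    def test_upsampling_carries_no_parameters(self):
        """Bilinear interpolation and unpooling learn nothing."""
        for name in ("lw_segnet", "lw_unet"):
            for e in A.layer_trace(A.default_spec(name), 512):
                if "unpool" in e["name"] or "upsample" in e["name"]:
                    assert e.get("weights", 0) == 0 and e.get("bias", 0) == 0
        model = A.build_model(A.default_spec("lw_unet", input_size=64), seed=0)
        assert all(not up.params() for up in model.ups)


class TestModels:
    @pytest.mark.parametrize("name", ["lw_segnet", "lw_unet"])
    def test_zero_tile_probabilities(self, name):
        spec = A.ArchitectureSpec(name=name, input_size=64, **SMALL)
        model = A.build_model(spec, seed=1)
        p = A.forward_segment(model, np.zeros((64, 64, 5), np.float32))
        assert p.shape == (64, 64)
        assert np.all((p >= 0) & (p <= 1))

    @pytest.mark.parametrize("name", ["lw_segnet", "lw_unet"])
    def test_forward_deterministic(self, name):
        spec = A.ArchitectureSpec(name=name, input_size=64, **SMALL)
        model = A.build_model(spec, seed=1)
        tile = np.random.default_rng(0).random((64, 64, 5)).astype(np.float32)
        np.testing.assert_array_equal(A.forward_segment(model, tile),
                                      A.forward_segment(model, tile))

    def test_softmax_probabilities_normalise(self):
        from lwseg.layers import softmax_channel
        spec = A.ArchitectureSpec(name="lw_unet", input_size=32, **SMALL)
        model = A.build_model(spec, seed=2)
        x = np.random.default_rng(1).random((1, 5, 32, 32)).astype(np.float32)
        prob = softmax_channel(model.forward(x, train=False))
        np.testing.assert_allclose(prob.sum(axis=1), 1.0, rtol=1e-5)

    def test_encoder_halves_resolution_each_stage(self):
        spec = A.ArchitectureSpec(name="lw_segnet", input_size=64, **SMALL)
        model = A.build_model(spec, seed=0)
        x = np.random.default_rng(2).random((1, 5, 64, 64)).astype(np.float32)
        sizes = []
        for stage, pool in zip(model.enc, model.pools):
            x = pool.forward(stage.forward(x, train=False), train=False)
            sizes.append(x.shape[2])
        assert sizes == [32, 16, 8, 4]    # input / 2**k after stage k

    def test_wrong_band_count_rejected(self):
        spec = A.ArchitectureSpec(name="lw_unet", input_size=32, **SMALL)
        model = A.build_model(spec, seed=0)
        with pytest.raises(ValueError, match="expected"):
            A.forward_segment(model, np.zeros((32, 32, 3), np.float32))

    def test_indivisible_input_rejected(self):
        spec = A.ArchitectureSpec(name="lw_segnet", input_size=32, **SMALL)
        model = A.build_model(spec, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 5, 24, 24), np.float32))
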